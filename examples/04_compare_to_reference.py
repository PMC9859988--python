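"""Audit one administration against its stratum's reference level.

Computes a DRLA from a synthetic stratum and checks a new prescription
against it: the ratio activity/DRLA and a strict above-reference flag.
"""

import numpy as np

from nmdrl import drl

rng = np.random.default_rng(2)
stratum_activities = rng.lognormal(np.log(740.0), 0.2, size=120)
drla = drl.third_quartile(stratum_activities)
print(f"stratum DRLA (Q3 of {len(stratum_activities)} administrations): {drla:.0f} MBq")

for activity in (740.0, drla, 1200.0):
    ratio, above = drl.compare_to_reference(activity, drla)
    verdict = "ABOVE reference" if above else "within reference"
    print(f"  {activity:7.0f} MBq -> ratio {ratio:.2f} ({verdict})")
# A ratio > 1 asks for justification or protocol review, not an automatic
# rejection: the DRL is an optimization benchmark, not a limit.
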