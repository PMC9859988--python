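# nmdrl

Diagnostic reference levels in administered activity, organ dosimetry and
lifetime cancer-risk estimation for nuclear-medicine procedures.

Nuclear-medicine services administer radiopharmaceuticals (e.g. 99mTc-MIBI
for myocardial perfusion, 18F-FDG for whole-body PET) whose activity is
prescribed with wide practice variation and few national benchmarks. This
package gives medical physicists and nuclear-medicine staff three connected
tools:

1. **DRLA surveys** — stratify an administration registry by procedure
   protocol, sex, 5-year age bin and BMI class, and report each stratum's
   diagnostic reference level in activity (DRLA): the third quartile
   (75th percentile) of the administered activities, the conventional
   optimization benchmark. Administered activity is prescribed minus
   syringe residual.
2. **Organ dosimetry** — convert an administered activity *A* (MBq) into
   organ absorbed doses via reference dose coefficients *c*(age)
   (mGy/MBq): *D* = *A*·*c*(age). Coefficient tables are anchored at ages
   1, 5, 10, 15 and adult; intermediate ages use a fitted logarithmic
   curve *c*(age) = α + β·ln(age), falling back to an anchor-exact
   piecewise interpolation when the fit is poor (R² < 0.90).
3. **Lifetime attributable risk (LAR)** — transport excess-risk models to
   a target population. The excess relative/absolute risk for site *s* is

       ERR or EAR = β_s · D · exp(γ·e*) · (a/60)^η,

   with dose *D* (Sv), exposure age *e*, attained age *a*,
   e\* = (e−30)/10 for e < 30 (else 0), and DDREF = 1.5 dividing the
   linear term for solid cancers. The excess rate
   M(D,e,a) = ERR·λ_c(a) (ERR transport, with the population's baseline
   incidence or mortality rate λ_c) is summed over the remaining lifetime,

       LAR(D,e) = Σ_{a=e+L}^{100} M(D,e,a) · S(a)/S(e),

   where S is the population survivorship and L the latency (5 y solid,
   2 y leukemia).

## Worked example

A 40-year-old male receives 20 mCi = 740 MBq of 99mTc-MIBI (resting
protocol):

```
$ nmdrl dose -r MIBI-99mTc-rest --activity 740 --age 40 --sex male
           organ  absorbed_dose_mgy  risk_eligible
gallbladder_wall             28.860          False
      heart_wall              4.662          False
         kidneys             26.640           True
           liver              8.140           True
        pancreas              5.698          False
          spleen              4.810          False
         thyroid              3.922           True
 urinary_bladder              8.140           True
effective dose: 6.66 mSv
```

The liver receives 8.14 mGy (740 MBq × 0.011 mGy/MBq). Doses are three
orders of magnitude below deterministic-effect thresholds; the relevant
question is stochastic risk, and the organs marked `True` have risk-model
parameter rows available. Feeding the liver dose to the risk engine
(synthetic Gompertz life table and synthetic baseline rates — swap in your
population's CSVs for real use):

```
$ nmdrl risk --site liver --sex male --age 40 --dose-mgy 8.14
config: {"ddref": 1.5, "latency_leukemia_years": 2.0, "latency_solid_years": 5.0, "transport": "ERR", "upper_age_years": 100}
LAR(8.14 mGy, e=40) = 2.3384e-05 (2.338 per 100000 exposed)
```

i.e. about 2.3 excess liver-cancer cases per 100 000 similarly exposed
40-year-old males over their remaining lifetime, under these synthetic
population tables. `nmdrl report` combines doses, a DRLA comparison and the
three risk curves (ERR(a), M(D,e,a), LAR by exposure age) in one JSON
report; `nmdrl drl` runs the registry survey; `nmdrl synth` writes
synthetic inputs. The `examples/` scripts walk through each capability from
Python.

Shipped coefficient tables cover DMSA-, DTPA-, MDP- and MIBI-99mTc
(rest/stress/parathyroid) and FDG-18F. Adult anchors follow ICRP-series
values; pediatric anchors are age-scaled estimates and each row's source
column says so — replace the tables with full ICRP transcriptions before
any clinical use. The risk-parameter file is editable CSV with per-row
sources.

## Limitations

Dose coefficients describe a reference phantom, not patient-specific
biokinetics: this is a decision-support and audit tool, not individual
clinical dosimetry. Thyroid and leukemia risk rows use the solid-tumor
functional form rather than the committee's special models (see
`docs/methods.md`), and no uncertainty intervals are propagated.
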