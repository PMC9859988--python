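# Methods

## Scope and data flow

`nmdrl` implements a three-stage audit pipeline for diagnostic
nuclear-medicine administrations: (i) reference-level surveys over an
administration registry, (ii) organ dosimetry from dose-per-activity
coefficients, and (iii) population-transported lifetime cancer-risk
estimation. All inputs are delimited text (CSV) and all outputs are flat
CSV/JSON reports; every generator and report is a deterministic function of
its inputs, seeds and configuration.

## Registry and stratification

A registry row carries patient id (opaque), protocol, radiopharmaceutical,
prescribed and residual activity (MBq), sex, age, weight (kg), height (m)
and exam date. Net administered activity = prescribed − residual; rows
violating invariants (residual > prescribed, non-positive anthropometry,
unparseable numbers) are written to a rejects report with a reason rather
than silently dropped — a reference-level tool must be auditable. The
column mapping, separator and decimal mark are configurable
(`RegistryDialect`); comma decimals are normalized because many source
systems emit them.

Stratification axes are protocol, sex, 5-year age bin and BMI class. Age
bins are half-open [5k, 5k+5), lower edge inclusive, with ages ≥ 100 pooled
into a terminal bin — unambiguous and consistent with integer-age life
tables. BMI = weight/height² is classified with WHO cutoffs 18.5/25/30
(lower edge inclusive, configurable): the cutoffs are a reporting
convention, not a model input. Strata always partition the record set;
inactive axes pool under "both"/"all" labels. Activities can optionally be
reported per kilogram of body weight (MBq/kg) for weight-based prescription
protocols; absolute MBq is the primary quantity.

## Reference levels

The DRLA of a stratum is the third quartile of its administered activities.
The default estimator is linear order-statistic interpolation with plotting
position h = (n−1)·0.75 + 1 (the common spreadsheet/NumPy "linear" rule);
a nearest-rank alternative (⌈0.75n⌉-th order statistic) is available for
comparability with surveys that avoid interpolation. Strata below a
configurable minimum size are flagged "insufficient n"; strata below 10
administrations carry an advisory flag because quartiles of tiny samples
are unstable. The above-reference comparison activity/DRLA uses a strict
inequality: exactly at the reference level is not "above".

## Dosimetry

Coefficient tables hold one mGy/MBq value per organ per anchor age
(1, 5, 10, 15, adult) plus an effective-dose row in mSv/MBq. The "adult"
anchor is assigned age 18 for interpolation (configurable); the physical
tables do not attach an age to the adult reference.

Between anchors two modes exist:

* **log_fit** — least squares of c(age) = α + β·ln(age). The logarithmic
  shape reflects organ mass growing with age while absorbed dose varies
  inversely with mass. R² = 1 − SSres/SStot, with the convention that zero
  residual on zero-variance (constant) data is R² = 1. A fitted line can
  undershoot zero outside the data; evaluation floors the result at a tiny
  positive value.
* **piecewise_log** — linear interpolation of ln(c) against ln(age)
  between adjacent anchors: exact at every anchor and positivity-preserving.
  This is the automatic fallback when R² < 0.90 (default threshold), the
  regime seen for organs whose anchors do not follow the logarithmic trend
  (small hollow organs such as the gallbladder).

Ages at or above the adult anchor clamp to the adult coefficient; ages at
or below 1 year clamp to the 1-year coefficient. Dose is then strictly
linear: D = A·c(age). Equivalent dose for the risk engine is taken
numerically equal to absorbed dose (mGy → mSv, radiation weighting factor
1), appropriate for the photon/electron emitters in scope.

Shipped starter tables cover DMSA-, DTPA-, MDP-, MIBI-99mTc
(rest/stress/parathyroid) and FDG-18F with the organs relevant to risk
reporting. Adult anchors follow compiled ICRP-series values (the MIBI-rest
adult liver coefficient is 0.011 mGy/MBq, so 740 MBq → 8.14 mGy);
pediatric anchors are age-scaled estimates and each row's source string
says so. The test suite deliberately never depends on these transcriptions:
correctness tests run on synthetic tables from `synth`.

## Life tables and baseline rates

Survivorship S(a) is tabulated at integer ages 0..100, normalized to
S(0) = 1, floored at 1e-12, and validated non-increasing. From death
probabilities the standard construction S(a+1) = S(a)(1 − q(a)) is used and
round-trips exactly. Conditional survival S(a)/S(e) composes
multiplicatively (Chapman–Kolmogorov), which the suite checks at 1e-12.

Baseline cancer incidence and mortality rates are stored per 100 000
person-years by site, sex and age and divided by 100 000 on lookup. Banded
inputs (5-year atlas bands, half-open [lo, hi)) are expanded
constant-within-band — the simplest convention that preserves the band
averages; no smoothing or graduation is applied.

## Risk engine

For solid cancers the preferred incidence model

ERR or EAR = β_s · D_eff · exp(γ·e\*) · (a/60)^η,  e\* = min((e−30)/10, 0)

is evaluated with site/sex/model parameters from an editable CSV. DDREF
(default 1.5) divides the dose for solid sites only — leukemia risk is not
DDREF-reduced, following the committee convention that the
linear-quadratic leukemia dose response already captures low-dose-rate
curvature. ERR transport multiplies by the target population's baseline
rate λ_c(a) (incidence or mortality endpoint, selectable); EAR transport
converts the absolute excess (shipped units: per 10⁴ person-years per Sv)
to per person-year directly.

LAR sums M(D,e,a)·S(a)/S(e) over integer attained ages from e + L to 100
inclusive (L = 5 y solid, 2 y leukemia); there is no sub-annual
integration. If e + L exceeds the terminal age the LAR is 0 with a logged
note. The engine is linear in dose; truncating the upper age can only
decrease it; and an independent naive summation reproduces it to 1e-12 in
the tests.

Simplifications, stated deliberately: thyroid and leukemia rows are cast
into the same functional form with linear coefficients from the pooled
thyroid analysis and the linear term of the leukemia model — the special
breast/thyroid models and the linear-quadratic leukemia model are out of
scope, as is the weighted ERR/EAR mixture transport and any uncertainty
propagation. Kidney and salivary gland use the residual "other solid
cancer" grouping, as no site-specific rows exist. Risk "eligibility" of an
organ in reports simply means a parameter row exists for its mapped cancer
site, which for the MIBI tables yields liver, kidneys, bladder and thyroid.

## Synthetic data

`synth` generates every input the pipeline consumes, deterministically per
seed, with the generating parameters written into `#` comment headers:

* **Registry** — per-protocol lognormal administered activities (central
  values: DMSA 185, DTPA 370, FDG 370 weight-scaled, MDP 925, MIBI rest
  740, stress 1110, parathyroid 740 MBq; σ = 0.25 on the log scale), a
  Gaussian-bump age mixture over the 5-year bins centred near 57 years
  (nuclear-medicine caseloads are adult-heavy), normal anthropometry by sex
  with a crude pediatric scaling, and a uniform 1–5% residual fraction so
  prescribed = administered + residual always validates. These are test
  scaffolding with plausible magnitudes, not clinical guidance, and they
  make closed-form checks possible (the lognormal Q3 is exp(μ + 0.6745σ)).
* **Life table** — Gompertz survivorship S(a) = exp(−(B/θ)(e^{θa} − 1)),
  defaults B = 1e-4, θ = 0.09 (adult-mortality-law shape; S(80) ≈ 0.226).
* **Rates** — constant or power-law (a/60)^p site rates.
* **Coefficient tables** — exactly log-linear anchors (optionally
  jittered), so interpolation recovery is testable to machine precision.

What the synthetic data does *not* emulate: real registries' missingness
patterns and protocol-dependent demographics, infant/accident mortality
humps in real life tables, and the age structure of real cancer atlases.
Passing tests therefore demonstrate the correctness of the estimators and
the engine, not the realism of any particular population's risk numbers;
real IBGE/INCA-format CSVs drop into the same loaders.

## Numerical choices and degenerate inputs

Empty registries give empty (not failing) reports; empty value lists make
the quantile raise. Quantile ties are handled by stable sorting — no
jitter. Survivorship is floored at 1e-12 so conditional ratios never divide
by zero. The fitted-curve R² is clipped to [0, 1]. Problem sizes in the
test suite (1000 random quantile lists, 100 random LAR oracle triples,
n = 10 000 lognormal recovery) keep the full suite under ~10 s while
leaving the sampling tolerances (2%) comfortably non-binding.
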