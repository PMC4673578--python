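# Methods

## The estimation strategy

Relative GFR (mL/min/1.73 m²) is predicted twice for each patient: from
plasma cystatin C (mg/L) and from plasma creatinine (μmol/L) plus
demographic data.  The pair is then subjected to an internal quality
check.  Writing a for the cystatin-based and b for the creatinine-based
estimate, the agreement statistic is the symmetric relative difference

    d = |a − b| / ((a + b) / 2),

which is dimensionless, symmetric in its arguments and invariant under a
common rescaling of both estimates.  If d ≤ L the pair is concordant:
each estimate corroborates the other, and the arithmetic mean (a + b)/2
is reported (route `USE_MEAN`).  The default limit is L = 0.30 in the
general context and L = 0.10 when the estimate will drive drug dosing;
both are per-call configurable.  The choice of |a−b|/mean as the metric
is a design decision — the strategy only demands "agreement within
specified limits" — made because it matches the ±30% idiom in which
estimator accuracy (P30) is conventionally expressed.

On discordance the clinical flags are consulted:

| flags present                       | route                    |
|-------------------------------------|--------------------------|
| abnormal muscle mass (low or high)  | `USE_CYSTATIN`           |
| moderate/high-dose glucocorticoids  | `USE_CREATININE`         |
| both classes, or none               | `GOLD_STANDARD_REQUIRED` |

Muscle-mass flags invalidate the creatinine estimate because creatinine
production is proportional to muscle mass and every creatinine equation
implicitly assumes the population-mean muscle mass for the patient's age,
sex and ethnicity.  Glucocorticoid treatment invalidates the cystatin
estimate because it raises cystatin C synthesis independently of GFR.
When both markers are compromised, or neither explanation applies, no
single-marker estimate is defensible and an invasive gold-standard
measurement is required — the strategy gives no rule for the doubly
compromised case, so we fail safe.

Flags are consulted only on discordance: a concordant pair is treated as
self-validating, since the two markers' confounders are independent and
simultaneous, compensating errors are improbable.  The
`strict_flags=True` switch makes flags veto the mean even when
concordant, for users who prefer the conservative reading.

### Creatinine-anchored monitoring

A concordant decision connects a trusted GFR value g₀ to the patient's
creatinine c₀ at age t₀.  Follow-up GFR is then estimated from creatinine
alone by scaling along the anchored creatinine equation f (same sex,
population and height):

    g(c, t) = g₀ · f(c, t) / f(c₀, t₀).

For an MDRD-like form this reduces to a pure power law,
g = g₀ · (c/c₀)^e1 · (t/t₀)^e2.  Interpretations fixed here, where the
strategy's description is silent:

* anchoring is permitted **only** after `USE_MEAN` — a flag-resolved
  single-marker decision never creates an anchor;
* the age-range applicability guard is not re-applied inside the
  monitoring ratio (the patient may legitimately age across a boundary
  while anchored);
* a `MUSCLE_MASS_CHANGED` flag permanently invalidates the anchor and
  raises a re-evaluation error; the two-marker strategy must be repeated.

## Prediction equations

Equations are registry data, not code.  Four functional forms are
implemented, each strictly decreasing in its marker and hence exactly
invertible:

* **power_law_cystatin** — GFR = A · cysC^(−B), with an optional
  pediatric multiplier applied for age strictly below a cutoff.
  Shipped default `cystatin_power`: A = 84.69, B = 1.680, ×1.384 below
  age 14, applicable ages 1–120.
* **mdrd_like** — GFR = c0 · (crea/88.4)^e1 · age^e2 · sex · population.
  Shipped defaults: `mdrd` (IDMS-traceable: 175, −1.154, −0.203, female
  ×0.742, black ×1.212) and `mdrd_japanese` (the same with the Japanese
  population coefficient 0.763), ages 18–120.  The population coefficient
  is applied iff the patient's population tag matches the spec's, so sex
  and population coefficients act purely multiplicatively.
* **height_over_creatinine** — GFR = k · height / (crea/88.4).  Shipped
  default `counahan_barratt`: k = 0.43, ages 1–18, requires height.
* **piecewise_loglinear** — ln GFR = X(crea, sex) + c·age + d·ln age with
  X piecewise linear in creatinine and ln creatinine per sex-specific
  segment (the Lund–Malmö shape).  **No default coefficients are
  shipped** for this form: the validated coefficients are not public data
  this package can vouch for, and refusing to invent them beats silently
  wrong defaults.  Supply them via a registry config file.

The shipped coefficient values are defaults sourced from the equations'
original publications and are fully overridable through YAML/JSON config;
the strategy itself is equation-agnostic.  Unit policy: creatinine is
accepted in μmol/L only, and every internal mg/dL conversion uses exactly
88.4; relative↔absolute GFR conversion uses exactly 1.73 m².  Age guards
are inclusive-lower/exclusive-upper (the exact upper endpoint is also
accepted); pediatric cutoffs use strict `<`.  Missing optional fields
never default — they make an equation inapplicable, which the decision
engine reports as an error rather than guessing.

Inversion (marker level from target GFR) is analytic for the power-law,
MDRD-like and height forms, and uses Brent root bracketing on
log-creatinine ∈ [ln 0.01, ln 10⁵] for the piecewise form; round-trip
error is verified below 1e−9 relative over GFR 5–150 for every shipped
equation.

## Body surface area and absolute GFR

absolute = relative × BSA / 1.73.  The DuBois–DuBois formula
0.007184 · height^0.725 · weight^0.425 is the default BSA estimate
(Mosteller is also registered; others are pluggable).  DuBois is a design
choice — the strategy requires the conversion but names no formula.

## Accuracy metrics

P30 (and P10) = percentage of estimates within ±30% (±10%) of the
reference.  The boundary counts as *within* (comparison ≤); this
convention is stated explicitly because published P30 values are
sensitive to it.  `accuracy_report` adds the median bias (est − ref) and
the median absolute relative error.

## Synthetic cohort

The simulator draws, per patient: true relative GFR ~ Uniform(10, 120)
mL/min/1.73 m², age ~ Uniform(18, 90), sex Bernoulli(0.5 female), plus
plausible heights and weights (normal around sex-specific means, used
only for BSA demonstrations).  Marker levels are produced by *exact
inversion* of the chosen equations at the true GFR, then perturbed:

    creatinine = invert_crea(GFR) · M · ε_crea
    cystatin   = invert_cys(GFR)  · G · ε_cys

* **M**, the muscle-mass factor, multiplies creatinine only.  Baseline
  M ~ lognormal(0, σ=0.15); with probability `p_muscle_abnormal` it is
  forced to `muscle_abnormal_factor` (0.5 = severe muscle loss, 2.0 =
  unusually high muscle mass) and the corresponding flag is set.  Under
  an MDRD-like equation M = 0.5 inflates the creatinine estimate by
  exactly 0.5^(−1.154) = 2^1.154 ≈ 2.23×, which the recovery tests check
  analytically.
* **G ≥ 1**, the steroid factor, multiplies cystatin C only, for treated
  patients (probability `p_glucocorticoid`).  No published magnitude
  exists for the glucocorticoid effect, so G is a free scenario parameter
  with default 2.0 — large enough that the induced bias (2^(−1.68) ≈
  0.31×) clearly exceeds the 0.30 agreement limit, i.e. a deliberately
  unambiguous routing scenario rather than a physiological estimate.
  (For scale, cystatin C can run an order of magnitude above normal in
  end-stage renal failure, so a 2× elevation is well inside plausibility.)
* **ε**, assay noise, is multiplicative lognormal with mean-log 0 and
  sd-log = ln(1 + CV) — a first-order approximation to the exact
  CV↔sd-log relation that keeps the median unbiased; at the CVs used
  (≤ 0.15) it differs from the exact mapping by < 1%.  Lognormal noise is
  the simplest positivity-preserving model for skewed, positive marker
  data.  Default assay CVs are 0.05 for both markers, typical of modern
  automated clinical-chemistry assays.
* **Gold-standard measurements** get the same noise model with default
  CV 0.10.  Two simulated repeat measurements therefore agree within
  ±30% with probability Φ(ln 1.3/σ√2) − Φ(ln 0.7/σ√2) ≈ 97% (σ =
  ln 1.1) — a closed form the simulation is tested against, and a
  reminder that no estimator can reach 100% P30 against an imperfect
  reference.

`flags_observed=False` hides the confounder flags from the patient
records while keeping them in the ground truth, modelling an
uninformative clinical context; biased patients then route to
`GOLD_STANDARD_REQUIRED`.  One `numpy` Generator seeded from the
mandatory config seed drives the whole cohort, so generation is
bitwise reproducible.

What the simulator does *not* emulate: correlation between the two
assays' errors, diet/drug/tubular-secretion effects on creatinine,
thyroid effects on cystatin C, within-patient longitudinal GFR
trajectories, or non-lognormal heavy-tailed assay failures.  Passing
recovery tests therefore demonstrate internal consistency of the
strategy and correctness of the implementation under the stated
mechanisms, not clinical performance on real cohorts.

## Problem sizes and numerical choices

The validation suite uses n = 10 000 patients for noise-free recovery,
n = 1 000–2 000 for the confounder routing scenarios (the assertions are
exact per patient, so size only adds coverage), and n = 100 000 draws for
the gold-standard repeatability and combined-vs-single P30 comparisons,
where Monte-Carlo error must sit well below the 0.5-percentage-point
comparison tolerance (binomial s.e. ≈ 0.05 pp at these rates).  Inversion
round-trips are asserted at 1e−9 relative (achieved ~1e−15); noise-free
estimate recovery at 1e−6 absolute (achieved ~1e−13); monitoring identity
at machine precision.  Tie-breaks: age guards inclusive-lower, pediatric
cutoff strict `<`, P30 boundary `≤`, piecewise segments matched
first-fit with `crea_min ≤ c < crea_max`.

## Known limitations

* Shipped coefficients assume IDMS-traceable creatinine and a specific
  cystatin C calibration; mixing equations with markers from a different
  calibrator produces systematic error no registry can detect.
* The decision engine treats flags as authoritative booleans; graded
  muscle-mass deviation or steroid dose–response is out of scope.
* The Lund–Malmö piecewise form is implemented and tested, but users
  must supply its coefficients.
* Absolute-GFR conversion uses adult BSA formulas; pediatric nomograms
  and amputation adjustments are not modelled.
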