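# lundgfr

Non-invasive estimation of glomerular filtration rate (GFR) with a
dual-marker internal quality check.

Measuring GFR correctly requires invasive clearance of an exogenous tracer
(iohexol, ⁵¹Cr-EDTA, …) — slow, expensive and not risk-free — so routine
care relies on prediction equations that estimate relative GFR
(mL/min/1.73 m²) from endogenous plasma markers.  The two markers fail in
complementary ways: creatinine tracks muscle mass as much as kidney
function, while cystatin C is muscle-independent but inflated by
moderate/high-dose glucocorticoid therapy.  `lundgfr` implements the
estimation strategy that exploits this complementarity:

1. Estimate relative GFR twice — once from cystatin C
   (GFR = A·cysC^(−B)), once from creatinine and anthropometric data
   (MDRD-family, pediatric height/creatinine, or piecewise log-linear
   forms).
2. Compare the estimates.  If the relative difference
   |a−b| / mean(a, b) is within the agreement limit (0.30 by default,
   0.10 in the drug-dosing context), both are validated and their
   **arithmetic mean** is reported.
3. On disagreement, consult the clinical context: abnormal muscle mass
   invalidates the creatinine estimate (use the cystatin one),
   glucocorticoid treatment invalidates the cystatin estimate (use the
   creatinine one).  With no explanation — or both markers compromised —
   an invasive gold-standard measurement is required.
4. After a concordant decision the patient's creatinine is **anchored**
   to a trusted GFR value, so follow-up can be monitored from creatinine
   alone until muscle mass changes.

The package also converts relative to absolute GFR via body surface area
(DuBois by default), computes P30/P10 accuracy summaries, and ships a
seeded synthetic-cohort simulator (marker levels by exact equation
inversion plus mechanistic confounders and lognormal assay noise) so that
every decision path is testable end to end without patient data.
Equations are pluggable data: coefficients live in a registry that can be
loaded from and dumped to YAML/JSON config files.

## Worked example

```python
import lundgfr as lg

registry = lg.default_registry()
patient = lg.PatientRecord(
    "pt-001", age=40, sex="female", height=165, weight=62,
    creatinine=80.0,     # μmol/L
    cystatin_c=1.20,     # mg/L
)
decision = lg.lund_decide(patient, registry, "cystatin_power", "mdrd")
print("eGFR (cystatin C):", round(decision.e_cystatin.value, 1))
print("eGFR (creatinine):", round(decision.e_creatinine.value, 1))
print("route:", decision.route.value)
print("final eGFR:", round(decision.final_estimate.value, 1), "mL/min/1.73 m2")

area = lg.bsa(patient.height, patient.weight)
print("absolute:", round(lg.relative_to_absolute(decision.final_estimate.value, area), 1), "mL/min")

anchor = lg.make_anchor(decision, patient, "mdrd")
follow = lg.monitor(anchor, new_creatinine=120.0, new_age=41, flags=set(), registry=registry)
print("follow-up at creatinine 120:", round(follow.value, 1))
```

prints

```
eGFR (cystatin C): 62.3
eGFR (creatinine): 68.9
route: USE_MEAN
final eGFR: 65.6 mL/min/1.73 m2
absolute: 63.8 mL/min
follow-up at creatinine 120: 40.9
```

The two estimates agree within 30% (relative difference 0.10), so the
strategy reports their mean, 65.6 mL/min/1.73 m².  The concordant
creatinine of 80 μmol/L is then anchored to that value: when creatinine
later rises to 120 μmol/L, the follow-up estimate 40.9 is obtained from
creatinine alone by scaling along the anchored equation — no new cystatin
measurement needed.  Had the estimates disagreed, a recorded
`MUSCLE_MASS_LOW` flag would have routed the decision to the cystatin
estimate alone, a glucocorticoid flag to the creatinine estimate, and an
unexplained discrepancy to `GOLD_STANDARD_REQUIRED`.

## Command line

```bash
lundgfr estimate --input panel.csv --output estimates.csv --absolute
lundgfr decide   --input panel.csv --output decisions.jsonl --context dosing
lundgfr simulate --config cohort.yaml --out-panel panel.csv --out-truth truth.csv
lundgfr evaluate --input pairs.csv --output report.json
lundgfr curves   --equation-ids mdrd --creatinine 80 --sex female --output curves.csv
lundgfr registry --output equations.yaml
```

Panels are header-validated CSV (creatinine in μmol/L, cystatin C in mg/L,
clinical flags semicolon-separated); decision reports are JSON lines with
deterministic field order.

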