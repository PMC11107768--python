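# dxval

Validation of diagnosis-code accuracy in electronic health records (EHRs),
built around the stratified two-phase ("verification sampling") design used
to validate pediatric mental, emotional, and behavioral disorder coding —
autism spectrum disorder (ASD), attention-deficit hyperactivity disorder
(ADHD), disruptive behavior disorders (DBD), anxiety disorder, and major
depressive disorder (MDD) — against a chart-review gold standard.

## Who this is for

Pharmacoepidemiology and health-services researchers who need to know
whether ICD-9-CM / ICD-10-CM diagnosis codes in an EHR can stand in for
true case status before using them in downstream studies. The package
implements the whole validation workflow and ships a synthetic EHR cohort
generator with known ground truth, so the pipeline can be developed,
tested, and power-checked with no access to protected records.

## The design and the statistics

For each condition *i*, eligible children (≥ 1 year of enrollment in the
period, ≥ 1 clinical visit, condition-specific age window) are split into
the **Dx** stratum (≥ 1 qualifying diagnosis code) and the **No-Dx**
stratum. A fixed number of records is sampled per condition × period ×
stratum cell (default 40; 120 per stratum over three periods) and chart
review of the sampled records yields the gold standard. Because sampling is
stratified on the code itself, population sensitivity and specificity
require normalized sampling weights

    W_ij = N_ij / (n_ij · N_i)

where *N_ij* is the population size of stratum *j*, *n_ij* the number
sampled from it, and *N_i* the condition's total study population; sampled
weights sum to 1 within each condition. With TP/FP counted in the Dx
stratum and FN/TN in the No-Dx stratum:

    sensitivity = TP·W_dx / (TP·W_dx + FN·W_nodx)
    specificity = TN·W_nodx / (TN·W_nodx + FP·W_dx)
    PPV = TP/(TP+FP)            NPV = TN/(TN+FN)       (weight-free)
    F   = 2·sens·PPV/(sens+PPV) J   = sens + spec − 1

Chart review mechanics are modeled too: blocked-note records are replaced
by same-stratum redraws, "insufficient notes" records are excluded, and a
balanced dual-abstraction subsample (180 records; 36 per condition, 90 per
abstractor) supports a Cohen's κ interrater-reliability estimate.

## Worked example

Simulate a single-condition cohort (500 coded, 5000 non-coded children;
generative PPV 0.95, 1 − NPV 0.01; 3% blocked charts), then run the whole
pipeline sampling 40 records per stratum:

```python
import datetime as dt
import dxval as dv

cfg = dv.SimulationConfig(
    conditions={"anxiety": dv.ConditionSpec(n_dx=500, n_nodx=5000,
                                            ppv_true=0.95, one_minus_npv_true=0.01)},
    periods=[dv.Period(label="2017-2019", start=dt.date(2017, 1, 1),
                       end=dt.date(2019, 12, 31))],
    blocked_rate=0.03, abstractor_error_rate=0.0, seed=1,
)
res = dv.run_pipeline(cfg, per_cell=40, reliability_total=0)
print(res.strata[res.strata.period == "overall"].to_string(index=False))
print(res.metrics[["condition", "sensitivity", "specificity", "ppv", "npv",
                   "f_score", "youden_j"]].to_string(index=False))
```

```
condition stratum  period    N  n_sampled  n_confirmed
  anxiety      Dx overall  500         40           37
  anxiety   No-Dx overall 5000         40            2

condition  sensitivity  specificity  ppv  npv  f_score  youden_j
  anxiety         64.9         99.2 92.5 95.0     76.3      64.1
```

Reading this: 37 of the 40 sampled Dx records were chart-confirmed, so the
estimated PPV is 92.5% (generative value 95%). Two confirmed cases turned
up among the 40 No-Dx records; after weighting by the No-Dx stratum's
population share (W_nodx = 0.0227 vs W_dx = 0.0023), those two missed cases
pull the weighted sensitivity down to 64.9% with a wide bootstrap CI
(42.5–100) — a small FN count carrying a large weight is exactly why
code-negative strata dominate the uncertainty in this design.

The same pipeline is available from the shell:

```bash
dxval run-all --config config.yaml --out-dir out/ --per-cell 40
dxval report --manifest out/manifest.json --out-dir out2/   # byte-identical rerun
```

`dv.default_study_config()` holds the full-scale published study
conditions (five conditions, ~2.3M children, three periods spanning the
ICD-9-CM→ICD-10-CM transition and the COVID-19 pandemic).

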