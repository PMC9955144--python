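# avslat — adrenal venous sampling lateralization analysis

`avslat` implements the index calculus, classification rules, and diagnostic
statistics used to subtype primary aldosteronism (PA) from adrenal venous
sampling (AVS), including a *modified* lateralization index for the common
situation in which the right adrenal vein cannot be catheterized.

## Background

PA is subtyped by sampling aldosterone and cortisol from both adrenal veins
and the inferior vena cava (IVC). The standard workup computes:

- **Selectivity index** `SI = C_AdV / C_IVC` — cortisol in an adrenal-vein
  sample over the lowest IVC cortisol; `SI >= 5` under ACTH stimulation marks
  successful catheterization of that vein.
- **Aldosterone/cortisol ratio** `A/C` at each site (cortisol correction).
- **Conventional lateralization index**
  `LI = max(A/C_left, A/C_right) / min(A/C_left, A/C_right)`; `LI >= 4`
  indicates a unilateral aldosterone-producing adenoma (APA) on the
  higher-ratio side, otherwise idiopathic hyperaldosteronism (IHA).

The right adrenal vein is short and drains directly into the IVC, so right
catheterization frequently fails. The **modified lateralization index**
substitutes a sample drawn from the IVC just above the right adrenal
confluence (the *substitute right* site, S-rt.AdV):

```
mLI = (A/C at left AdV) / (A/C at S-rt.AdV)
```

Because the substitute site sees the pooled output of *both* glands diluted
in caval flow, the index is read against two cutoffs rather than one:
`mLI <= 0.7` calls a right-sided APA, `mLI >= 2.2` calls a left-sided APA,
and intermediate values call IHA (bilateral disease).

A dilution-free "unit model" explains the shape of the rule: give a normal
gland 1 secretory unit and a lesioned gland 10. The left vein sees only the
left gland; the substitute site sees both, so `mLI = left/(left + right)`,
giving 1/11 ≈ 0.1 for a right APA, 10/20 = 0.5 for bilateral disease, and
10/11 ≈ 0.9 for a left APA.

## What the package provides

| module | contents |
|---|---|
| `avslat.indices` | measurement model, SI, A/C, conventional and modified LI, toy unit model |
| `avslat.classify` | thresholds, conventional/modified/fallback subtype rules, eligibility filter |
| `avslat.roc` | empirical ROC, rank/trapezoid AUC, LR+ threshold selection, binormal lognormal AUC, rank-sum test |
| `avslat.synthetic` | lognormal moment matching, a mechanistic two-gland flow model, cohort simulation, calibration |
| `avslat.io` / `avslat.cli` | cohort CSV/YAML I/O, the `avslat` command-line pipeline |

## Worked example

```bash
$ avslat toy
right-sided lesion: left 1 / (left 1 + right 10) = modified LI 0.1
bilateral lesions: left 10 / (left 10 + right 10) = modified LI 0.5
left-sided lesion: left 10 / (left 10 + right 1) = modified LI 0.9

$ avslat simulate --mode mechanistic --seed 4 -o cohort.csv
$ avslat analyze cohort.csv -o report/
$ ls report/
comparisons.csv  exclusions.csv  group_stats.csv  per_patient.csv  pipeline.log  roc_table.csv
```

From Python:

```python
from avslat import CohortSpec, draw_cohort, records_to_table, run_pipeline

records = draw_cohort(CohortSpec(n_rt=8, n_lt=12, n_iha=24, seed=20230))
report = run_pipeline(records_to_table(records))
print(report.group_stats)
```

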