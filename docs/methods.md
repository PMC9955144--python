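# Methods

This note documents the models and numerical choices behind `avslat`: the
index calculus, the classification rules, the two synthetic-data generators,
the calibration procedure and its known structural limit, and the statistics
used to evaluate the modified lateralization index.

## 1. Indices and classification

All indices are computed from paired aldosterone/cortisol measurements at
four sites — left adrenal vein (lt.AdV), right adrenal vein (rt.AdV), the
IVC just above the right adrenal confluence (the substitute right site,
S-rt.AdV), and a low IVC reference — in one ACTH phase (post-stimulation by
default).

- Selectivity index `SI = C_site / C_IVC`; catheterization success is
  `SI >= 5.0`, inclusive.
- Conventional lateralization index
  `LI = max(A/C_lt, A/C_rt) / min(A/C_lt, A/C_rt)`; `LI >= 4.0` (inclusive)
  calls a unilateral APA on the dominant side, else IHA.
- Modified lateralization index `mLI = (A/C_lt) / (A/C_srt)` with the
  tri-class rule `mLI <= 0.7 -> right APA`, `mLI >= 2.2 -> left APA`,
  otherwise IHA. Boundary values attach to the *abnormal* (APA) class,
  consistent with the inclusive convention used for SI and LI. The default
  cutoffs 0.7/2.2 are the primary reading of the rule; all thresholds are
  configurable through `Thresholds` / the YAML config.
- Adjudication: when right catheterization succeeds the conventional rule is
  used; when it fails, the modified rule serves as the fallback
  (`Rule.FALLBACK` in the per-patient report).

The eligibility filter applies, in order, with first-match attribution:
incomplete right-sided sampling, unoperated unilateral disease,
post-operative ARR >= 200, uncontrolled post-operative blood pressure, and
loss to follow-up. On the bundled 58-patient test roster this yields 44
included patients with per-reason tallies (9, 2, 2, 0, 1).

## 2. Toy unit model

The dilution-free unit model assigns 1 secretory unit to a normal gland and
10 to a lesioned gland (both 10 for bilateral disease). The left vein sees
only the left gland while the substitute site sees both, so
`mLI = left/(left + right)`: 1/11 ≈ 0.1 (right APA), 10/20 = 0.5
(bilateral), 10/11 ≈ 0.9 (left APA). This motivates why the modified index
is bounded near 1 for left disease rather than growing like the
conventional LI.

## 3. Distributional generator

`draw_cohort(mode="distributional")` samples modified and conventional LI
values directly from lognormal distributions moment-matched to the
calibration class moments (mean, SD of the modified LI): right APA
(0.37, 0.38), left APA (3.46, 1.97), IHA (1.52, 1.11). Moment matching is
exact: `sigma^2 = ln(1 + (sd/mean)^2)`, `mu = ln(mean) - sigma^2/2`
(`lognormal_from_moments`, round-trips at machine precision).

## 4. Mechanistic generator

`simulate_patient` produces all eight measurements (4 sites × 2 ACTH phases)
from a two-gland flow model:

- Each gland has secretory units (`units_normal = 1`, `units_apa = 10`; IHA
  gives both glands 10), aldosterone flux `units × aldo_flux_per_unit` and a
  fixed cortisol flux per gland.
- Concentration at a site = (flux reaching the site)/(blood flow at the
  site) + a peripheral background. The adrenal veins carry only their own
  gland's flux at `adv_flow`; the substitute right site carries *both*
  glands' flux at `ivc_flow`; the low IVC carries background only.
- ACTH stimulation multiplies aldosterone quantities by
  `acth_aldo_multiplier` and cortisol quantities by
  `acth_cortisol_multiplier`, applied to fluxes *and* backgrounds, so every
  ratio index is exactly phase-invariant at zero noise.
- Every measurement receives independent multiplicative lognormal noise with
  mean 1 and coefficient of variation `noise_cv`:
  factor `exp(N(-s²/2, s²))` with `s² = ln(1 + cv²)`.

Default parameters (fitted once, then frozen as code constants):

| parameter | default | units / rationale |
|---|---|---|
| `units_normal`, `units_apa` | 1, 10 | toy unit model |
| `aldo_flux_per_unit` | 500 | pg·mL⁻¹·(flow unit) per unit |
| `cortisol_flux_per_gland` | 300 | µg·dL⁻¹·(flow unit) |
| `adv_flow`, `ivc_flow` | 1.65, 11.0 | relative flows; caval dilution ≈ 6.7× |
| `peripheral_aldo`, `peripheral_cortisol` | 28, 19 | background concentrations |
| `acth_aldo_multiplier`, `acth_cortisol_multiplier` | 3, 2 | stimulation response |
| `noise_cv` | 0.45 | per-measurement biological + assay variation |

### Closed-form noise propagation

At zero noise the modified LI is a deterministic ratio `R₀(subtype)`
(`predicted_modified_li`). With noise, the index is a ratio of four noisy
measurements, so `mLI = R₀·exp(N(0, 4s²))`, giving

```
mean = R₀·e^{2s²},   sd = mean·sqrt(e^{4s²} − 1)
```

(`predicted_modified_li_moments`). Tests verify the simulator against this
closed form both at zero noise (exact) and at `cv = 0.45` (moment check at
3,000 simulations within 4 standard errors).

### Calibration and its structural limit

`calibrate_mechanistic` fits (`units_apa`, `ivc/adv` flow ratio,
`aldo_flux_per_unit`, `peripheral_aldo`, `noise_cv`) in log-space by
Nelder–Mead with bounds to match the three class means/SDs via the closed
form, with an 8th-power min–max penalty on relative mean error, soft realism
penalties keeping zero-noise selectivity indices plausible (left AdV SI not
too small, substitute-site SI not too large), and a weak ridge toward the
defaults.

The model cannot match the class means exactly. With background ratio `β`,

```
mLI(left APA)/mLI(IHA) = (20 + β)/(11 + β) ≤ 20/11 ≈ 1.82,
```

whereas the target ratio is 3.46/1.52 ≈ 2.28. The min–max compromise lands
all three class means within ~13% of target (right −9.5%, left −11.3%, IHA
+13.1% at the frozen defaults), which the test suite enforces at a 15%
tolerance. The distributional generator, which matches the moments exactly,
is therefore used for the headline AUC computations; the mechanistic
generator is used where full per-site measurements are needed (pipeline and
CLI round-trips). The generator does *not* attempt to emulate assay floors,
catheter cross-contamination, inter-patient flow variability, or
non-lognormal outliers.

## 5. ROC and rank statistics

- Empirical ROC thresholds sit at the distinct observed scores plus ±∞
  endpoints; calls are inclusive (`>=`/`<=` by direction).
- `auc_rank` is the Mann–Whitney concordance via midranks and is provably
  identical to the trapezoidal area of the empirical curve; the suite checks
  equality to 1e−10 over 1,000 random instances and cross-checks both
  against brute-force pair counting and scikit-learn.
- `best_threshold_by_lr` maximizes LR+ = sens/(1 − spec) over admissible
  points (specificity < 1, sensitivity > 0, finite LR); ties break toward
  higher sensitivity, then the less extreme threshold. Note that on large
  continuous samples the LR+ criterion drifts to near-perfect-specificity
  cutoffs; it is intended for the small tied-score cohorts it is applied to.
- `binormal_auc_lognormal` gives the closed-form AUC
  `Φ((μ_p − μ_n)/√(σ_p² + σ_n²))` for lognormal score families and serves
  as the analytic oracle for the large-sample AUCs (one-vs-rest values are
  class-weighted mixtures of pairwise binormal AUCs).
- `rank_sum_test`: for combined `n ≤ 12` the two-sided p-value is computed
  by exhaustive enumeration of all group assignments of the pooled
  *midranks*, which remains exact in the presence of ties (where classical
  exact tables do not apply); larger samples use the tie-corrected normal
  approximation. The cutover at 12 keeps enumeration ≤ C(12,6) = 924
  assignments. The asymptotic approximation alone can deviate from the
  exact value by up to ~0.04 at these sizes, which is why the small-sample
  regime enumerates.

## 6. Problem sizes and reproducibility

All stochastic outputs are driven by `numpy.random.default_rng` seeds
carried in `CohortSpec`/`MechanisticParams`; seeded cohorts are
byte-identical across runs. The acceptance computation uses a 550,000-patient
distributional cohort (100k/150k/300k, preserving the 8:12:24 class mix);
at that size the Monte Carlo spread of the AUCs across seeds is < 0.001.
The class *proportions* matter: the IHA class is the hardest negative for
the left-APA contrast, so equal class sizes would inflate that AUC. These
sizes are the package's own choice, balancing Monte Carlo error against a
few seconds of runtime.
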