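# Methods

## The score

The methylation inflammation score of sample *t* is the weighted sum
S_t = Σ_i M_{t,i} · w_i over a panel of CpGs, where M is the M-value
(log₂(β/(1−β))) and w_i the per-CpG effect size from an external EWAS of
circulating CRP. Scoring happens on the M scale because M-values are
approximately homoscedastic across the methylation range, which is also
why the differential tests run on M-values.

Numerical choices:

* **Beta clamping.** Betas are clamped to [ε, 1−ε], ε = 1e-6, before the
  logit transform: post-normalization array betas can touch 0/1 and the
  M-value must stay finite. ε is exposed as a parameter of `beta_to_m`
  and bounded to (0, 0.5).
* **Partial coverage.** Panel CpGs absent from the matrix contribute
  zero, which is equivalent to dropping them from the panel. The
  fraction found (`coverage`) is always reported and scoring refuses
  below `min_coverage` (default 0.5). Partial coverage is the expected
  regime: real panels lose several percent of probes to array filtering,
  and imputing absent probes would manufacture signal.
* **Standardization** uses the sample SD (n−1 denominator) *within the
  analysis sample*, not against an external reference, so a score is
  only comparable within the cohort it was standardized in.
  Implementation re-centers twice before scaling, which keeps the
  residual mean at O(machine epsilon) even for raw values of magnitude
  1e6; constant vectors raise rather than returning NaN.
* **Random sub-panels** are uniform without-replacement draws of
  `subset_size` entries (default 68) from the parent panel, independent
  across the `count` panels (default 10), governed by one seed. They
  give an empirical null answering "does the specific weighted CpG set
  matter, or would any 68 panel CpGs do?".
* **Refinement** intersects the panel with the CpGs significant at
  q < `q_threshold` (default 0.05) in a differential methylation
  contrast, keeping the original weights. An empty intersection is an
  error carrying diagnostic counts, not an empty panel.

One contract deserves note: the panel constructor rejects all-zero
weights (such a panel scores everyone 0 and cannot be standardized), so
degenerate standardization is exercised through constant inputs instead.

## Frailty

FI = (deficits present) / (deficits answered), with FI set missing when
more than `max_missing` items (default 7 of 76, ~10%) are unanswered.
The denominator excludes missing items — the standard
deficit-accumulation convention — and the missing-item cap bounds the
bias this induces.

Baseline categories use left-closed intervals: low [0, 0.1), mild
[0.1, 0.2), high [0.2, 0.3), severe [0.3, 1]. The source convention
writes strict inequalities on both sides of the interior cut-points,
leaving exact boundary values unassigned; we assign each boundary to the
higher category, except severe which is closed at 0.3 as printed.

Three-year change Δ = FI(follow-up) − FI(baseline) is classed against a
clinically meaningful difference, CMD = 0.03: none (Δ ≤ 0), 1× CMD
(0 < Δ < 0.03), 2× CMD (0.03 ≤ Δ < 0.06), ≥3× CMD (Δ ≥ 0.06). The ≥3×
threshold is the upper edge of the 2× band (0.06 = 2·CMD); `cmd` is a
parameter, so other conventions are one argument away. Missing FI at
either timepoint propagates to a missing class.

## Moderated differential methylation

Only the two-group, no-covariate contrast is implemented (the target
design is mock vs one treatment with four replicates each); the general
linear-model machinery of the published empirical-Bayes framework is out
of scope. Per probe: effect = mean(treatment) − mean(reference), s² =
pooled within-group variance on d = n_t + n_r − 2 df.

Hyperparameters (d₀, s₀²) of the inverse-chi-square variance prior are
estimated by moment matching on e = log s² − ψ(d/2) + log(d/2), using
E[e] = log s₀² + ψ(d₀/2) − log(d₀/2) and Var[e] = ψ′(d₀/2) + ψ′(d/2),
with the trigamma inverse found by bracketed root finding on prior df in
(1e-6, 1e6). When the observed Var[e] does not exceed ψ′(d/2), the data
are consistent with one common variance: d₀ is reported infinite and the
posterior variance is s₀² = mean(s²) everywhere. Zero sample variances
are offset to 1e-5 × median before the log — such probes are kept and
shrunk, which is precisely the case moderation exists for. These two
choices mirror the reference Bioconductor implementation exactly, and
the test suite verifies agreement with `limma::eBayes` (via Rscript) to
1e-6 on t, p and q.

The moderated t is effect / sqrt(s²_post · (1/n_t + 1/n_r)) on d + d₀
df (capped at 1e6 for the t quantile, where it is numerically normal);
p-values are two-sided, with no fold-change filter. Multiplicity uses
Benjamini–Hochberg step-up q-values (delegated to statsmodels).

## Associations

All models are complete-case and report Wald 95% CIs (±1.96 SE);
profile-likelihood intervals are not used. Categorical exposures and
covariates are dummy-coded against a declared (or first-observed)
reference level; rank deficiency raises a collinearity error naming the
dependent columns. Logistic fits use Newton/IRLS (tol 1e-8, 50
iterations); non-convergence with |coef| > 15 is reported as separation.
The multinomial logit is fit by full maximum likelihood with the
reference class "none"; with two classes it reduces to the logistic
model (asserted to 1e-6 in tests), and it accepts joint entry of two
exposures (score and log-CRP together). No multiple-testing correction
is applied across traits — estimates carry nominal p-values. Clock age
acceleration is the standardized residual of clock estimate on
chronological age; an exact linear fit (zero residual variance) raises
rather than standardizing noise.

## What the synthetic data emulate — and what they do not

The cohort generator encodes the causal structure the analysis assumes:
a latent chronic-inflammation exposure L (standardized; loadings 0.35 on
age, 0.20 on smoking burden, remainder independent) drives panel
methylation (M_i = baseline_i + effect_scale · w_i · L + noise),
log-CRP (loading 0.3 plus unit acute-phase noise — CRP is deliberately a
weak readout of L), chronic conditions and outcomes (logistic with
configured ORs per SD of L; intercepts calibrated by root finding so
marginal prevalences hit their targets), and deficits (item logits
rising in L and age, with heterogeneous item frequencies; follow-up adds
a drift increasing in L, so frailty worsens fastest in the most
inflamed).

Defaults are the study conditions: n = 2000; ages 45–85; ~10% current
smokers; five conditions with ORs 1.20–1.67 and prevalences 0.07–0.40;
three outcomes (ED visit, hospitalization, death) with ORs 1.25–1.50;
76 deficits at base rate 0.12; 200-CpG panel with Normal(0, 0.1)
weights standing in for a ~1400-locus EWAS panel (a real panel file is
pluggable via TSV, never required). `effect_scale` = 0.5 with M-noise
SD 0.5 puts the score–L correlation near 0.8: a strong but imperfect
proxy, which is the scientifically interesting regime.

Because the score is an error-laden proxy of L, score-based odds ratios
are attenuated relative to the generating ORs by the coefficient of the
score in E[L | score, age, sex] (~0.76 at r ≈ 0.8) — classical
measurement-error attenuation, asserted quantitatively in the tests.
Recovery of the generating ORs is therefore checked against the
generating exposure itself, and checked as a sampling-distribution
property (unbiasedness and ~95% coverage of ±2 SE intervals across
replicate cohorts) rather than on a single draw, where an 8-trait
all-within-2-SE check would fail by chance about a third of the time
even for a perfect estimator.

The in-vitro generator emulates a 4-treatment × 4-replicate cytokine
exposure on a monocytic cell line: 68 randomly chosen panel CpGs shift
by `shift_m` = 1.5 M-units (scaled 1.0/0.3/0.3 for the primary/other
treatments) in the direction of each CpG's panel weight — so the score
rises under treatment — plus 30 off-panel decoy CpGs shifting in random
directions; replicate noise is N(0, 0.3) on the M scale. Refinement
against the primary contrast recovers the shifted panel CpGs nearly
completely; contamination by unshifted panel CpGs averages ~4%, which
is exactly the false-discovery behavior BH at q < 0.05 implies for this
mix of true and null probes (it fluctuates a few percent either side of
5% across runs).

Deliberately not modeled: array technical artifacts (batch, dye bias,
probe chemistry), comorbidity clustering beyond what L and age induce
(conditions are conditionally independent given both), correlation
between CpGs beyond the shared L component, and survival time (death is
a binary outcome). Passing tests therefore demonstrate the pipeline's
statistical machinery, not robustness to preprocessing artifacts.

Deficit-level frailty change has no closed-form class ORs, so
multinomial recovery is validated against a direct generator
(`simulate_cmd_classes`) that draws CMD classes from a multinomial logit
with known per-class ORs.

All generators split one master seed hierarchically (NumPy
`SeedSequence.spawn`), so identical configs are bit-identical and each
component is independently reproducible.

## Problem sizes

The test suite and the acceptance script run the pipeline at the scales
the package treats as its defaults: cohorts of 1000–5000 samples on the
200-CpG panel, 2000-probe null calibrations over 20 replicates, and
100-replicate coverage batches at n = 2000, which keep a full run in the
low minutes on one CPU.

## Known limitations

* Only the two-group differential contrast is implemented; covariates or
  continuous exposures in the probe-wise model are not supported.
* Wald intervals can misbehave near separation; the package raises on
  detected separation instead of reporting unstable estimates.
* The frailty denominator convention ("answered items") and the category
  boundary assignments are documented choices; cohorts using a fixed
  denominator will differ slightly for participants with missing items.
* Scores standardized within-cohort cannot be compared across cohorts
  without a harmonization step, which is out of scope.
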