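# episcore

Weighted-sum DNA methylation inflammation scoring and the epidemiological
analysis that surrounds it, with synthetic ground-truth data for every
stage.

## The problem

Chronic low-grade inflammation ("inflammaging") is a driver of age-related
decline, but the standard blood marker, C-reactive protein (CRP), is an
acute-phase reactant: a single measurement is a noisy snapshot. DNA
methylation at CRP-associated CpG sites integrates inflammatory exposure
over time, so a methylation-based score can serve as a more stable marker
of chronic inflammation in aging cohorts.

`episcore` implements that analysis as a reusable pipeline:

* **Scoring** (`episcore.panels`). Given a panel of CpGs with
  EWAS-derived effect sizes *w<sub>i</sub>*, the per-sample score is the
  weighted sum over M-values,
  *S<sub>t</sub> = Σ<sub>i</sub> M<sub>t,i</sub> · w<sub>i</sub>*,
  standardized within the analysis sample (mean 0, SD 1). Beta values are
  converted with *M = log₂(β/(1−β))*. Panel CpGs absent from the matrix
  contribute zero, with coverage reported and a refusal threshold.
  Random sub-panels provide an empirical null for panel specificity.
* **Frailty** (`episcore.frailty`). Deficit-accumulation frailty index
  (proportion of deficits present among those answered, missing above a
  missing-item cap), the low/mild/high/severe categories, and 3-year
  change binned against a clinically meaningful difference (CMD = 0.03):
  none / 1× / 2× / ≥3× CMD.
* **Differential methylation** (`episcore.diffmeth`). Probe-wise
  two-group comparison with empirical-Bayes variance moderation
  (posterior variance (d₀s₀² + d·s²)/(d₀ + d), moderated t on d₀ + d df)
  and Benjamini–Hochberg q-values — the machinery needed to refine the
  panel against an in-vitro exposure experiment (tested against
  Bioconductor limma to 1e-6).
* **Associations** (`episcore.associations`). Pearson correlations;
  age/sex-adjusted linear models for categorical exposures; logistic
  models reporting the OR per 1-SD of the score; multinomial models of
  frailty-change class adjusted for baseline frailty; epigenetic-clock
  age acceleration as standardized residuals of clock on age.
* **Synthetic data** (`episcore.simulate`). A cohort generator in which
  methylation at panel CpGs, CRP, chronic conditions, outcomes and
  deficits are all driven by a latent inflammation exposure with
  configurable effect sizes, and a 4-treatment × 4-replicate in-vitro
  generator with known shifted CpGs — so every stage can be validated
  against ground truth.

## Worked example

```python
import pandas as pd
from episcore import (
    CohortSimConfig, InvitroSimConfig, beta_to_m, compute_score,
    default_panel, differential_methylation, frailty_index, logistic_assoc,
    pearson_corr, refine_panel, simulate_cohort, simulate_invitro,
)

panel = default_panel()                      # 200 CpGs, Normal(0, 0.1) weights
meth, pheno, deficits, _, truth = simulate_cohort(CohortSimConfig(panel=panel))

score = compute_score(beta_to_m(meth), panel)
print(round(pearson_corr(score.standardized, pheno["age"].to_numpy()), 3))
# 0.266  -- the score rises with age, as a chronic-inflammation marker should

pheno["score"] = pd.Series(score.standardized, index=score.sample_ids)
est = logistic_assoc(pheno, outcome="chronic_lung_disease", exposure="score")
print(f"OR {est.estimate:.2f} (95% CI {est.ci_low:.2f}-{est.ci_high:.2f})")
# OR 1.75 (95% CI 1.46-2.10)  -- odds of chronic lung disease per 1-SD score

fi = frailty_index(deficits)
print(round(fi.fi.mean(), 3), fi.table["category"].value_counts().idxmax())
# 0.119 low  -- mean frailty index and modal category

# refine the panel against the in-vitro exposure experiment
experiment, vitro_truth = simulate_invitro(InvitroSimConfig(panel=panel))
diff = differential_methylation(experiment, treatment="CRP", reference="mock")
refined = refine_panel(panel, diff, q_threshold=0.05)
hits = set(refined.cpg_ids) & set(vitro_truth.shifted_panel_cpgs)
print(len(refined), len(hits))
# 69 68  -- the refined panel recovers all 68 truly shifted CpGs
```

Or from the shell:

```bash
episcore report --out-dir run1 --seed 1 --n-samples 2000
# pipeline done: score-age r = 0.261, score-CRP r = 0.240, refined panel size = 73
```

which writes every stage table (scores, frailty, differential
methylation, refined panel, association estimates for the full panel, the
refined panel and ten random 68-CpG sub-panels) plus a log of seeds and
parameters under `run1/`. Individual stages are available as
`simulate-cohort`, `simulate-invitro`, `score`, `frailty`, `diffmeth`,
`refine`, `associate`.

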