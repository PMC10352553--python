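"""Synthetic cohort and in-vitro data with known ground truth.

The cohort generator emulates an aging-cohort study in which methylation at
a panel of CpGs is driven by a latent chronic-inflammation exposure ``L``:

* ``L`` is a standardized mix of age (positive loading), smoking burden and
  an independent residual;
* the M-value of panel CpG *i* in sample *t* is
  ``baseline_i + effect_scale * w_i * L_t + noise``, so the panel's weighted
  sum recovers ``L`` up to noise by construction;
* circulating log-CRP loads on ``L`` plus a large acute-phase noise term
  (CRP is an acute marker, so it tracks chronic inflammation only weakly);
* chronic conditions and clinical outcomes are Bernoulli draws from
  logistic models with configured odds ratios per SD of ``L``, with
  intercepts calibrated so marginal prevalences hit their targets;
* health deficits are Bernoulli items whose logit rises with ``L`` and age;
  follow-up items receive an extra positive drift proportional to ``L``,
  so frailty worsens fastest in the most inflamed.

The in-vitro generator emulates a cytokine-exposure experiment on a
monocytic cell line (four treatments x four replicate plates): treated
wells shift a designated subset of panel CpGs in the direction of each
CpG's panel weight (so the panel score rises under treatment), plus a set
of off-panel decoy CpGs that shift regardless of the panel.

Everything is driven by one master seed, hierarchically split per
component, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import ValidationError
from .frailty import DeficitTable
from .diffmeth import ExperimentMatrix
from .panels import BETA, MVALUE, CpGPanel, MethylationMatrix

SMOKING_LEVELS = ["never", "former_lt10py", "former_ge10py", "current_lt10py", "current_ge10py"]
BMI_LEVELS = ["normal_under", "overweight", "obese"]

#: Marginal probabilities of the smoking-history categories (never / former
#: by pack-years / current by pack-years), chosen to give ~10% current smokers.
SMOKING_PROBS = (0.50, 0.22, 0.18, 0.04, 0.06)
BMI_PROBS = (0.35, 0.33, 0.32)

DEFAULT_CONDITION_ORS = {
    "hypertension": 1.30,
    "heart_disease": 1.45,
    "chronic_lung_disease": 1.67,
    "depression": 1.25,
    "osteoarthritis": 1.20,
}
DEFAULT_CONDITION_PREVALENCE = {
    "hypertension": 0.40,
    "heart_disease": 0.12,
    "chronic_lung_disease": 0.07,
    "depression": 0.15,
    "osteoarthritis": 0.30,
}
DEFAULT_OUTCOME_ORS = {"ed_visit": 1.25, "hospitalization": 1.30, "death": 1.50}
DEFAULT_OUTCOME_PREVALENCE = {"ed_visit": 0.15, "hospitalization": 0.10, "death": 0.03}
DEFAULT_CLOCK_LOADINGS = {"horvath": 0.5, "phenoage": 1.0}


def default_panel(n_cpgs: int = 200, weight_sd: float = 0.1, seed: int = 12345) -> CpGPanel:
    """A stand-in CpG panel with weights drawn Normal(0, weight_sd).

    A compact stand-in for an EWAS-derived panel of ~1400 loci; real panel
    files are pluggable via :meth:`CpGPanel.from_tsv` but never required.
    """
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, weight_sd, size=n_cpgs)
    if np.all(weights == 0):  # vanishingly unlikely; keep panel valid
        weights[0] = weight_sd
    ids = tuple(f"cg{i:08d}" for i in range(1, n_cpgs + 1))
    return CpGPanel(cpg_ids=ids, weights=weights, name=f"synthetic{n_cpgs}")


@dataclass
class CohortSimConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``effect_scale`` is the M-value shift per SD of latent exposure per
    unit panel weight; with the default 200-CpG panel and M noise 0.5 it
    puts the panel score's correlation with the latent exposure around 0.8.
    """

    n_samples: int = 2000
    panel: CpGPanel = field(default_factory=default_panel)
    effect_scale: float = 0.5
    age_range: tuple[float, float] = (45.0, 85.0)
    or_conditions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_ORS)
    )
    condition_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCE)
    )
    or_outcomes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_ORS)
    )
    outcome_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PREVALENCE)
    )
    frailty_items: int = 76
    frailty_base_rate: float = 0.12
    followup_drift: float = 0.30
    noise_sd_m: float = 0.5
    crp_loading: float = 0.3
    clock_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLOCK_LOADINGS)
    )
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_samples < 10:
            bad.append("n_samples (must be >= 10)")
        if not self.age_range[0] < self.age_range[1]:
            bad.append("age_range (min must be < max)")
        for name, o in {**self.or_conditions, **self.or_outcomes}.items():
            if o <= 0:
                bad.append(f"odds ratio for '{name}' (must be > 0)")
        for name, p in {
            **self.condition_prevalence,
            **self.outcome_prevalence,
        }.items():
            if not 0 < p < 1:
                bad.append(f"prevalence for '{name}' (must be in (0,1))")
        if not 0 < self.frailty_base_rate < 1:
            bad.append("frailty_base_rate (must be in (0,1))")
        if self.frailty_items < 1:
            bad.append("frailty_items (must be >= 1)")
        if self.noise_sd_m < 0 or self.effect_scale < 0:
            bad.append("noise_sd_m / effect_scale (must be >= 0)")
        if set(self.or_conditions) != set(self.condition_prevalence):
            bad.append("or_conditions / condition_prevalence (names must match)")
        if set(self.or_outcomes) != set(self.outcome_prevalence):
            bad.append("or_outcomes / outcome_prevalence (names must match)")
        if bad:
            raise ValidationError(f"invalid cohort config: {bad}", fields=bad)


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort."""

    latent: pd.Series  # standardized latent inflammation exposure per sample
    cpg_baselines: pd.Series  # per-CpG baseline M-value
    condition_ors: dict[str, float]
    outcome_ors: dict[str, float]
    config: CohortSimConfig

    def to_tsv(self, path) -> None:
        pd.DataFrame({"latent": self.latent}).to_csv(
            path, sep="\t", index_label="sample_id"
        )


@dataclass
class InvitroTruth:
    """Ground truth of one simulated in-vitro experiment."""

    shifted_panel_cpgs: list[str]
    decoy_cpgs: list[str]
    config: "InvitroSimConfig"


def _calibrate_intercept(linear_term: np.ndarray, target: float) -> float:
    """Intercept c such that mean(expit(c + linear_term)) == target."""
    return brentq(
        lambda c: expit(c + linear_term).mean() - target, -30.0, 30.0, xtol=1e-10
    )


def simulate_cohort(
    cfg: CohortSimConfig | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame, DeficitTable, DeficitTable, CohortTruth]:
    """Generate (beta matrix, phenotypes, baseline deficits, follow-up
    deficits, truth record) for one synthetic cohort."""
    cfg = cfg or CohortSimConfig()
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_pheno, rng_latent, rng_meth, rng_crp, rng_cond, rng_def, rng_clock, rng_out = (
        np.random.default_rng(s) for s in streams
    )
    n = cfg.n_samples
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    age = rng_pheno.uniform(*cfg.age_range, size=n)
    sex = rng_pheno.choice(["F", "M"], size=n, p=[0.51, 0.49])
    smoking = rng_pheno.choice(SMOKING_LEVELS, size=n, p=SMOKING_PROBS)
    bmi = rng_pheno.choice(BMI_LEVELS, size=n, p=BMI_PROBS)

    # latent chronic inflammation: loads on age and smoking burden
    z_age = (age - age.mean()) / age.std(ddof=1)
    smoke_idx = np.array([SMOKING_LEVELS.index(s) for s in smoking], dtype=float)
    z_smoke = (smoke_idx - smoke_idx.mean()) / max(smoke_idx.std(ddof=1), 1e-12)
    a_age, a_smoke = 0.35, 0.20
    resid_sd = np.sqrt(max(1 - a_age**2 - a_smoke**2, 0.0))
    L_raw = a_age * z_age + a_smoke * z_smoke + resid_sd * rng_latent.normal(size=n)
    L = (L_raw - L_raw.mean()) / L_raw.std(ddof=1)

    # methylation: panel CpG M-values driven by L, then mapped to betas
    w = cfg.panel.weights
    baselines = rng_meth.uniform(-3.0, 3.0, size=len(cfg.panel))
    m = (
        baselines[None, :]
        + cfg.effect_scale * np.outer(L, w)
        + rng_meth.normal(0.0, cfg.noise_sd_m, size=(n, len(cfg.panel)))
    )
    betas = expit(m * np.log(2.0))  # inverse of M = log2(b/(1-b))
    meth = MethylationMatrix(
        values=pd.DataFrame(betas, index=sample_ids, columns=list(cfg.panel.cpg_ids)),
        scale=BETA,
    )

    log_crp_raw = cfg.crp_loading * L + rng_crp.normal(0.0, 1.0, size=n)
    log_crp = (log_crp_raw - log_crp_raw.mean()) / log_crp_raw.std(ddof=1)

    pheno = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoking5": smoking,
            "bmi3": bmi,
            "log_crp": log_crp,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for name, loading in cfg.clock_loadings.items():
        pheno[f"clock_{name}"] = age + loading * L + rng_clock.normal(0, 4.0, size=n)

    for name, oratio in cfg.or_conditions.items():
        term = np.log(oratio) * L
        c = _calibrate_intercept(term, cfg.condition_prevalence[name])
        pheno[name] = (rng_cond.uniform(size=n) < expit(c + term)).astype(int)
    for name, oratio in cfg.or_outcomes.items():
        term = np.log(oratio) * L
        c = _calibrate_intercept(term, cfg.outcome_prevalence[name])
        pheno[name] = (rng_out.uniform(size=n) < expit(c + term)).astype(int)

    # deficits: heterogeneous item frequencies, logit rising in L and age
    item_spread = rng_def.normal(0.0, 0.8, size=cfg.frailty_items)
    lin = 0.4 * L[:, None] + 0.03 * (age[:, None] - age.mean()) + item_spread[None, :]
    c0 = _calibrate_intercept(lin.ravel(), cfg.frailty_base_rate)
    p_base = expit(c0 + lin)
    deficits_base = (rng_def.uniform(size=p_base.shape) < p_base).astype(float)
    drift = cfg.followup_drift * (0.5 + 0.5 * L)[:, None]
    p_fu = expit(c0 + lin + drift)
    deficits_fu = (rng_def.uniform(size=p_fu.shape) < p_fu).astype(float)
    item_cols = [f"deficit_{j:02d}" for j in range(1, cfg.frailty_items + 1)]
    table_base = DeficitTable(
        values=pd.DataFrame(deficits_base, index=sample_ids, columns=item_cols)
    )
    table_fu = DeficitTable(
        values=pd.DataFrame(deficits_fu, index=sample_ids, columns=item_cols)
    )

    truth = CohortTruth(
        latent=pd.Series(L, index=sample_ids, name="latent"),
        cpg_baselines=pd.Series(baselines, index=list(cfg.panel.cpg_ids)),
        condition_ors=dict(cfg.or_conditions),
        outcome_ors=dict(cfg.or_outcomes),
        config=cfg,
    )
    return meth, pheno, table_base, table_fu, truth


@dataclass
class InvitroSimConfig:
    """Knobs of the synthetic in-vitro methylation experiment.

    Defaults emulate a 4-treatment x 4-replicate cytokine exposure where
    the primary treatment shifts 68 panel CpGs by 1.5 M-units (scaled per
    treatment) plus 30 off-panel decoy CpGs.
    """

    panel: CpGPanel = field(default_factory=default_panel)
    n_replicates: int = 4
    treatments: tuple[str, ...] = ("mock", "CRP", "TNF", "IL6")
    n_shifted_panel: int = 68
    n_decoys: int = 30
    shift_m: float = 1.5
    per_treatment_scale: dict[str, float] = field(
        default_factory=lambda: {"CRP": 1.0, "TNF": 0.3, "IL6": 0.3}
    )
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if "mock" not in self.treatments:
            bad.append("treatments (must include 'mock')")
        if self.n_replicates < 2:
            bad.append("n_replicates (must be >= 2)")
        if not 0 < self.n_shifted_panel <= len(self.panel):
            bad.append("n_shifted_panel (must be in [1, panel size])")
        if self.n_decoys < 0:
            bad.append("n_decoys (must be >= 0)")
        if self.noise_sd <= 0:
            bad.append("noise_sd (must be > 0)")
        unknown = set(self.per_treatment_scale) - set(self.treatments)
        if unknown:
            bad.append(f"per_treatment_scale (unknown treatments {sorted(unknown)})")
        if bad:
            raise ValidationError(f"invalid in-vitro config: {bad}", fields=bad)


def simulate_invitro(
    cfg: InvitroSimConfig | None = None,
) -> tuple[ExperimentMatrix, InvitroTruth]:
    """Generate an M-value experiment matrix plus its ground truth.

    Treated wells shift each designated panel CpG by
    ``per_treatment_scale[t] * shift_m`` in the direction of that CpG's
    panel weight, so the panel score increases under treatment; decoy
    (off-panel) CpGs shift by the same magnitude in a random fixed
    direction.  Replicate noise is iid Normal(0, noise_sd) on the M scale.
    """
    cfg = cfg or InvitroSimConfig()
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_design, rng_base, rng_noise = (np.random.default_rng(s) for s in streams)

    shifted_idx = np.sort(
        rng_design.choice(len(cfg.panel), size=cfg.n_shifted_panel, replace=False)
    )
    shifted_panel = [cfg.panel.cpg_ids[i] for i in shifted_idx]
    decoys = [f"decoy{j:05d}" for j in range(1, cfg.n_decoys + 1)]
    decoy_dir = rng_design.choice([-1.0, 1.0], size=cfg.n_decoys)

    cpgs = list(cfg.panel.cpg_ids) + decoys
    baselines = rng_base.uniform(-3.0, 3.0, size=len(cpgs))

    shift_dir = np.zeros(len(cpgs))
    panel_w = cfg.panel.weights
    for i in shifted_idx:
        shift_dir[i] = 1.0 if panel_w[i] >= 0 else -1.0
    shift_dir[len(cfg.panel) :] = decoy_dir

    rows, labels, ids = [], [], []
    for t in cfg.treatments:
        scale = 0.0 if t == "mock" else cfg.per_treatment_scale.get(t, 1.0)
        for r in range(1, cfg.n_replicates + 1):
            noise = rng_noise.normal(0.0, cfg.noise_sd, size=len(cpgs))
            rows.append(baselines + scale * cfg.shift_m * shift_dir + noise)
            labels.append(t)
            ids.append(f"{t}_rep{r}")
    mvalues = pd.DataFrame(np.vstack(rows), index=ids, columns=cpgs)
    x = ExperimentMatrix(mvalues=mvalues, group=pd.Series(labels, index=ids, name="group"))
    truth = InvitroTruth(shifted_panel_cpgs=shifted_panel, decoy_cpgs=decoys, config=cfg)
    return x, truth


def simulate_cmd_classes(
    exposure: np.ndarray,
    class_ors: dict[str, float],
    base_probs: dict[str, float],
    seed: int = 0,
    reference: str = "none",
) -> pd.Series:
    """Draw frailty-change classes from a multinomial logit with known ORs.

    ``class_ors[k]`` is the odds ratio of class ``k`` vs the reference per
    1 SD of ``exposure``; ``base_probs`` are the class probabilities at
    exposure 0 (must include the reference and sum to 1).  Used to give
    class-membership models an exact ground truth, which the deficit-level
    cohort generator cannot provide in closed form.
    """
    if reference not in base_probs:
        raise ValidationError(f"base_probs must include reference '{reference}'")
    if abs(sum(base_probs.values()) - 1.0) > 1e-8:
        raise ValidationError("base_probs must sum to 1")
    if set(class_ors) != set(base_probs) - {reference}:
        raise ValidationError("class_ors must cover exactly the non-reference classes")
    x = np.asarray(exposure, dtype=float)
    classes = [reference] + sorted(class_ors)
    eta = np.zeros((x.size, len(classes)))
    for j, k in enumerate(classes[1:], start=1):
        eta[:, j] = np.log(base_probs[k] / base_probs[reference]) + np.log(
            class_ors[k]
        ) * x
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=x.size)
    idx = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
    return pd.Series([classes[i] for i in idx], name="cmd_class")
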