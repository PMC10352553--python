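"""End-to-end pipeline: simulate, score, frailty, test, refine, associate.

``run_pipeline`` strings the stages together on a synthetic cohort and a
synthetic in-vitro experiment, writing every intermediate table as TSV plus
a run log (seeds, parameters) and a summary comparing association estimates
across the full panel, the refined panel, and the random sub-panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    estimates_frame,
    linear_assoc,
    logistic_assoc,
    multinomial_assoc,
    pearson_corr,
)
from .diffmeth import differential_methylation
from .frailty import delta_frailty, frailty_index
from .panels import CpGPanel, beta_to_m, compute_score, random_subpanels, refine_panel
from .simulate import (
    CohortSimConfig,
    InvitroSimConfig,
    default_panel,
    simulate_cohort,
    simulate_invitro,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: Path
    seed: int = 0
    n_samples: int = 2000
    q_threshold: float = 0.05
    cmd: float = 0.03
    min_coverage: float = 0.5
    with_subpanels: bool = True
    n_subpanels: int = 10
    subpanel_size: int = 68
    panel: CpGPanel | None = None

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)


def _score_battery(
    score_std: pd.Series, pheno: pd.DataFrame, cmd_class: pd.Series, fi_base: pd.Series
) -> pd.DataFrame:
    """Association battery for one standardized score column."""
    data = pheno.copy()
    data["score"] = score_std
    data["cmd_class"] = cmd_class
    data["fi_baseline"] = fi_base
    frames = []
    binary_traits = [
        c
        for c in data.columns
        if data[c].dropna().isin([0, 1]).all()
        and c not in ("score",)
        and pd.api.types.is_numeric_dtype(data[c])
    ]
    for trait in binary_traits:
        est = logistic_assoc(data, outcome=trait, exposure="score")
        frames.append(estimates_frame([est], model=f"logistic:{trait}"))
    mn = multinomial_assoc(
        data,
        outcome="cmd_class",
        exposures="score",
        covariates=["age", "sex", "fi_baseline"],
    )
    frames.append(estimates_frame(mn, model="multinomial:delta_frailty"))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic analysis; returns a dict of output paths and
    headline numbers."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31)
    panel = cfg.panel or default_panel()

    # --- cohort ---------------------------------------------------------
    cohort_cfg = CohortSimConfig(
        n_samples=cfg.n_samples, panel=panel, seed=int(seeds[0])
    )
    meth, pheno, def_base, def_fu, truth = simulate_cohort(cohort_cfg)
    meth.to_tsv(out / "cohort_betas.tsv")
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", na_rep="NA")
    def_base.to_tsv(out / "deficits_baseline.tsv")
    def_fu.to_tsv(out / "deficits_followup.tsv")
    truth.to_tsv(out / "truth.tsv")

    mvals = beta_to_m(meth)
    eis = compute_score(mvals, panel, min_coverage=cfg.min_coverage)
    eis.to_tsv(out / "score_full.tsv")

    fi_base = frailty_index(def_base)
    fi_fu = frailty_index(def_fu)
    change = delta_frailty(fi_base, fi_fu, cmd=cfg.cmd)
    fi_base.to_tsv(out / "frailty_baseline.tsv")
    fi_fu.to_tsv(out / "frailty_followup.tsv")
    change.to_tsv(out / "frailty_change.tsv")

    # --- in-vitro, refinement -------------------------------------------
    invitro_cfg = InvitroSimConfig(panel=panel, seed=int(seeds[1]))
    experiment, invitro_truth = simulate_invitro(invitro_cfg)
    diff = differential_methylation(experiment, treatment="CRP", reference="mock")
    diff.to_tsv(out / "diffmeth_crp_vs_mock.tsv")
    refined = refine_panel(panel, diff, q_threshold=cfg.q_threshold)
    refined.to_tsv(out / "panel_refined.tsv")
    refined_score = compute_score(mvals, refined, min_coverage=cfg.min_coverage)
    refined_score.to_tsv(out / "score_refined.tsv")

    # --- association battery across panels ------------------------------
    panels_scores = {"full": eis, "refined": refined_score}
    if cfg.with_subpanels:
        subs = random_subpanels(
            panel, subset_size=cfg.subpanel_size, count=cfg.n_subpanels,
            seed=int(seeds[2]),
        )
        for sp in subs:
            panels_scores[sp.name] = compute_score(
                mvals, sp, min_coverage=cfg.min_coverage
            )
    batteries = []
    for name, sv in panels_scores.items():
        tab = _score_battery(
            pd.Series(sv.standardized, index=sv.sample_ids),
            pheno,
            change.cmd_class,
            fi_base.fi,
        )
        tab.insert(0, "panel", name)
        batteries.append(tab)
    summary = pd.concat(batteries, ignore_index=True)
    summary.to_csv(out / "associations.tsv", sep="\t", index=False, na_rep="NA")

    r_age = pearson_corr(eis.standardized, pheno["age"].to_numpy())
    r_crp = pearson_corr(eis.standardized, pheno["log_crp"].to_numpy())

    log = {
        "version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": {
            "cohort": int(seeds[0]),
            "invitro": int(seeds[1]),
            "subpanels": int(seeds[2]),
        },
        "n_samples": cfg.n_samples,
        "panel": panel.name,
        "panel_size": len(panel),
        "q_threshold": cfg.q_threshold,
        "cmd": cfg.cmd,
        "min_coverage": cfg.min_coverage,
        "refined_panel_size": len(refined),
        "score_age_correlation": float(r_age),
        "score_crp_correlation": float(r_crp),
        "diffmeth_d0": float(diff.d0) if np.isfinite(diff.d0) else "inf",
        "diffmeth_s0_sq": float(diff.s0_sq),
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    logger.info("pipeline complete: %s", out)
    return {
        "out_dir": out,
        "summary": summary,
        "score_age_correlation": r_age,
        "score_crp_correlation": r_crp,
        "refined_panel_size": len(refined),
        "log": log,
    }
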