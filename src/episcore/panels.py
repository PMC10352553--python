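"""CpG panels and weighted-sum methylation scoring.

The central object is a *panel*: an ordered set of CpG probes, each carrying a
signed effect-size weight taken from an external epigenome-wide association
study.  A per-sample score is the weighted sum of M-values over the panel,

    score_t = sum_i  M_{t,i} * w_i,

standardized within the analysis sample to mean 0, SD 1.  Panels can be
refined by intersecting with the significant probes of a differential
methylation experiment, or resampled into random sub-panels to provide an
empirical null for the panel's specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    CoverageError,
    EmptyInputError,
    EmptyPanelError,
    ParameterError,
    ScaleError,
    SchemaError,
    ZeroVarianceError,
)

logger = logging.getLogger(__name__)

BETA = "beta"
MVALUE = "mvalue"


@dataclass(frozen=True)
class CpGPanel:
    """An ordered CpG panel with signed effect-size weights.

    Parameters
    ----------
    cpg_ids
        Unique probe identifiers.
    weights
        Effect size per unit M-value for each probe; finite, not all zero.
    name
        Label used in score outputs.
    """

    cpg_ids: tuple[str, ...]
    weights: np.ndarray
    name: str = "panel"

    def __post_init__(self):
        ids = tuple(str(c) for c in self.cpg_ids)
        w = np.asarray(self.weights, dtype=float)
        if len(ids) == 0:
            raise SchemaError("panel must contain at least one CpG")
        if len(set(ids)) != len(ids):
            raise SchemaError("panel CpG identifiers must be unique")
        if w.shape != (len(ids),):
            raise SchemaError(
                f"weights shape {w.shape} does not match {len(ids)} CpGs"
            )
        if not np.all(np.isfinite(w)):
            raise SchemaError("panel weights must be finite")
        if np.all(w == 0):
            raise SchemaError("panel weights must not all be zero")
        object.__setattr__(self, "cpg_ids", ids)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.cpg_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.cpg_ids), name=self.name)

    def subset(self, cpg_ids, name: str | None = None) -> "CpGPanel":
        """Return the sub-panel restricted to ``cpg_ids`` (order preserved)."""
        keep = set(cpg_ids)
        idx = [i for i, c in enumerate(self.cpg_ids) if c in keep]
        if not idx:
            raise EmptyPanelError(f"no CpGs of panel '{self.name}' in subset")
        return CpGPanel(
            cpg_ids=tuple(self.cpg_ids[i] for i in idx),
            weights=self.weights[idx].copy(),
            name=name or self.name,
        )

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "CpGPanel":
        """Read a panel from a two-column TSV ``cpg_id<TAB>weight``."""
        df = pd.read_csv(path, sep="\t")
        if not {"cpg_id", "weight"}.issubset(df.columns):
            raise SchemaError(
                f"panel file {path} must have columns 'cpg_id' and 'weight'"
            )
        return cls(
            cpg_ids=tuple(df["cpg_id"].astype(str)),
            weights=df["weight"].to_numpy(dtype=float),
            name=name or "panel",
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame({"cpg_id": list(self.cpg_ids), "weight": self.weights}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class MethylationMatrix:
    """Samples x CpGs methylation values on a declared scale.

    ``values`` is a DataFrame indexed by sample id with CpG-id columns.
    Beta values must lie strictly in (0, 1); M-values are unconstrained.
    """

    values: pd.DataFrame
    scale: str = BETA

    def __post_init__(self):
        if self.scale not in (BETA, MVALUE):
            raise ScaleError(f"unknown scale '{self.scale}'")
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate sample ids in methylation matrix")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate CpG ids in methylation matrix")
        if self.scale == BETA:
            arr = self.values.to_numpy()
            if arr.size and not ((arr > 0) & (arr < 1)).all():
                raise ScaleError("beta values must lie strictly in (0, 1)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_file(cls, path, scale: str, sep: str = "\t") -> "MethylationMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        return cls(values=df, scale=scale)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class ScoreVector:
    """Per-sample raw and standardized panel scores plus coverage metadata."""

    sample_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray
    panel_name: str
    coverage: float
    used_cpgs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw": self.raw,
                "standardized": self.standardized,
                "panel": self.panel_name,
                "coverage": self.coverage,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def beta_to_m(matrix: MethylationMatrix, epsilon: float = 1e-6) -> MethylationMatrix:
    """Convert beta values to M-values, M = log2(beta / (1 - beta)).

    Betas are clamped to [epsilon, 1 - epsilon] first so that values at the
    numeric boundary stay finite after the logit transform.
    """
    if matrix.scale != BETA:
        raise ScaleError("beta_to_m requires a beta-scale matrix")
    if not 0 < epsilon < 0.5:
        raise ParameterError(f"epsilon must be in (0, 0.5), got {epsilon}")
    clipped = matrix.values.clip(lower=epsilon, upper=1 - epsilon)
    m = np.log2(clipped / (1 - clipped))
    return MethylationMatrix(values=m, scale=MVALUE)


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    if matrix.scale != MVALUE:
        raise ScaleError("m_to_beta requires an M-value matrix")
    p = np.exp2(matrix.values)
    return MethylationMatrix(values=p / (1 + p), scale=BETA)


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (n - 1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ParameterError("standardize expects a 1-D vector")
    if x.size < 2:
        raise EmptyInputError("standardize requires at least two values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("cannot standardize a constant vector")
    z = x - x.mean()
    z -= z.mean()  # second pass kills the O(eps * |x|/sd) residual mean
    return z / z.std(ddof=1)


def compute_score(
    matrix: MethylationMatrix,
    panel: CpGPanel,
    min_coverage: float = 0.5,
) -> ScoreVector:
    """Weighted-sum panel score per sample on the M-value scale.

    Panel CpGs absent from the matrix contribute zero (equivalent to
    dropping them); the fraction found is reported as ``coverage`` and the
    call refuses when it drops below ``min_coverage``.
    """
    if matrix.scale != MVALUE:
        raise ScaleError("compute_score requires an M-value matrix")
    if len(matrix.sample_ids) == 0:
        raise EmptyInputError("methylation matrix has no samples")
    weights = panel.as_series()
    present = weights.index.intersection(matrix.values.columns)
    coverage = len(present) / len(panel)
    if len(present) == 0:
        raise CoverageError(
            f"no CpGs of panel '{panel.name}' ({len(panel)} probes) found in matrix"
        )
    if coverage < min_coverage:
        raise CoverageError(
            f"panel '{panel.name}' coverage {coverage:.3f} "
            f"({len(present)}/{len(panel)}) below min_coverage={min_coverage}"
        )
    missing = len(panel) - len(present)
    if missing:
        logger.info(
            "panel '%s': %d of %d CpGs absent from matrix, contributing zero",
            panel.name,
            missing,
            len(panel),
        )
    raw = matrix.values[present].to_numpy() @ weights[present].to_numpy()
    standardized = standardize(raw)
    return ScoreVector(
        sample_ids=matrix.sample_ids,
        raw=raw,
        standardized=standardized,
        panel_name=panel.name,
        coverage=coverage,
        used_cpgs=len(present),
    )


def random_subpanels(
    panel: CpGPanel,
    subset_size: int = 68,
    count: int = 10,
    seed: int = 0,
) -> list[CpGPanel]:
    """Draw ``count`` random sub-panels of ``subset_size`` CpGs each.

    Each sub-panel is an independent uniform without-replacement draw from
    the parent panel; weights are carried along.  The whole batch is
    reproducible from a single seed.
    """
    if subset_size > len(panel):
        raise ParameterError(
            f"subset_size {subset_size} exceeds panel size {len(panel)}"
        )
    if subset_size < 1 or count < 1:
        raise ParameterError("subset_size and count must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(count):
        idx = np.sort(rng.choice(len(panel), size=subset_size, replace=False))
        out.append(
            CpGPanel(
                cpg_ids=tuple(panel.cpg_ids[i] for i in idx),
                weights=panel.weights[idx].copy(),
                name=f"{panel.name}_random{k + 1}",
            )
        )
    return out


def refine_panel(panel: CpGPanel, diff, q_threshold: float = 0.05) -> CpGPanel:
    """Restrict a panel to CpGs differentially methylated at q < threshold.

    ``diff`` is a :class:`~episcore.diffmeth.DiffMethResult` (anything with a
    ``q_by_cpg()`` mapping works).  Weights of retained CpGs are unchanged;
    the name gains a ``_refined`` suffix.
    """
    q = diff.q_by_cpg()
    hits = {c for c, qv in q.items() if qv < q_threshold}
    kept = [c for c in panel.cpg_ids if c in hits]
    if not kept:
        raise EmptyPanelError(
            f"refinement of '{panel.name}' is empty: {len(panel)} panel CpGs, "
            f"{len(hits)} significant at q<{q_threshold}, intersection 0"
        )
    return panel.subset(kept, name=f"{panel.name}_refined")
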