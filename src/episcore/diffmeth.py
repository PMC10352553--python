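"""Two-group differential methylation with empirical-Bayes moderation.

Probe-wise two-sample comparison of M-values (treatment vs reference) in the
style of a moderated t-test: per-probe pooled variances are shrunk toward a
common prior variance estimated from all probes, and the t statistic gains
the prior degrees of freedom.  The hierarchical model is

    s2_g | sigma2_g  ~  sigma2_g * chi2_{d_g} / d_g
    1 / sigma2_g     ~  chi2_{d0} / (d0 * s0^2),

with (d0, s0^2) estimated by moment matching on log s2 via digamma /
trigamma identities.  The posterior variance is

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d),

and the moderated t uses d0 + d degrees of freedom.  Multiplicity is handled
with Benjamini-Hochberg step-up q-values.

With only four replicates per treatment arm, this moderation is what makes
probe-level inference workable at all: the per-probe variance on 2 + 2
degrees of freedom is far too noisy on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateVarianceError,
    DomainError,
    EmptyInputError,
    InsufficientReplicationError,
    SchemaError,
)

#: d0 above this is reported as infinite shrinkage (complete pooling).
_D0_CAP = 1e6


@dataclass
class ExperimentMatrix:
    """Samples x CpGs M-value matrix with a per-sample treatment label."""

    mvalues: pd.DataFrame
    group: pd.Series

    def __post_init__(self):
        if not self.mvalues.index.equals(self.group.index):
            self.group = self.group.reindex(self.mvalues.index)
            if self.group.isna().any():
                raise SchemaError("every sample needs a group label")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.mvalues.columns)

    def samples_in(self, label: str) -> pd.DataFrame:
        return self.mvalues.loc[self.group == label]


@dataclass
class DiffMethResult:
    """Per-CpG differential methylation statistics for one contrast.

    ``table`` columns: effect (treatment - reference mean M), s2 (pooled
    variance), t (moderated), df_total, p, q.  ``d0`` / ``s0_sq`` are the
    estimated prior degrees of freedom and prior variance; ``d0`` is
    ``inf`` when the variances are consistent with a single common value.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    treatment: str = ""
    reference: str = ""

    def q_by_cpg(self) -> dict[str, float]:
        return self.table["q"].to_dict()

    def significant(self, q_threshold: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["q"] < q_threshold])

    def to_tsv(self, path) -> None:
        out = self.table.sort_values("p")
        out.to_csv(path, sep="\t", index_label="cpg_id")


def probewise_fit(
    x: ExperimentMatrix, treatment: str, reference: str
) -> tuple[pd.Series, pd.Series, int, int, int]:
    """Per-CpG mean difference and pooled within-group variance.

    Returns ``(effect, s2, df, n_treatment, n_reference)`` where
    ``effect = mean(treatment) - mean(reference)`` and ``s2`` is the pooled
    two-sample variance on ``df = n_t + n_r - 2`` degrees of freedom.
    """
    for label in (treatment, reference):
        n = int((x.group == label).sum())
        if n < 2:
            raise InsufficientReplicationError(
                f"group '{label}' has {n} samples; at least 2 required"
            )
    xt = x.samples_in(treatment)
    xr = x.samples_in(reference)
    n_t, n_r = len(xt), len(xr)
    effect = xt.mean(axis=0) - xr.mean(axis=0)
    ss = (xt - xt.mean(axis=0)).pow(2).sum(axis=0) + (
        xr - xr.mean(axis=0)
    ).pow(2).sum(axis=0)
    df = n_t + n_r - 2
    s2 = ss / df
    return effect, s2, df, n_t, n_r


def _trigamma_inv(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0); bracketed root finding."""
    lo, hi = 5e-7, 5e5  # x = d0/2 for d0 in (1e-6, 1e6)
    if y >= special.polygamma(1, lo):
        return lo
    if y <= special.polygamma(1, hi):
        return hi
    return optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi, xtol=1e-12)


def ebayes_moderate(s2: pd.Series, df: int) -> tuple[float, float, pd.Series]:
    """Estimate (d0, s0^2) and return posterior variances.

    Moment matching on e = log s2 - digamma(df/2) + log(df/2):
    E[e] = log s0^2 + digamma(d0/2) - log(d0/2) and
    Var[e] = trigamma(d0/2) + trigamma(df/2).  When the observed variance
    of e does not exceed trigamma(df/2), the data are consistent with a
    single common variance and d0 is reported as infinite, with
    s2_post = s0^2 everywhere.

    Probes with s2 = 0 are offset to a tiny fraction of the median variance
    before taking logs, then shrunk like any other probe — zero sample
    variance is exactly the case moderation is for.
    """
    s2 = pd.Series(s2, dtype=float)
    if df <= 0:
        raise InsufficientReplicationError("residual df must be positive")
    if len(s2) < 10:
        raise EmptyInputError(
            f"need >= 10 CpGs to estimate the prior; got {len(s2)}"
        )
    x = np.maximum(s2.to_numpy(), 0.0)
    med = np.median(x)
    if med == 0:
        raise EmptyInputError(
            "more than half of the residual variances are exactly zero; "
            "the variance prior cannot be estimated"
        )
    x = np.maximum(x, 1e-5 * med)
    e = np.log(x) - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        half_d0 = _trigamma_inv(evar)
        d0 = 2 * half_d0
        s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s0_sq = float(x.mean())
    if d0 >= _D0_CAP:
        d0 = np.inf
        s2_post = pd.Series(s0_sq, index=s2.index)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, s2_post


def moderated_test(
    effect: pd.Series,
    s2_post: pd.Series,
    n_t: int,
    n_r: int,
    df_total: float,
) -> tuple[pd.Series, pd.Series]:
    """Moderated t statistic and two-sided p-value.

    t = effect / sqrt(s2_post * (1/n_t + 1/n_r)), referred to a t
    distribution with ``df_total`` (residual plus prior) degrees of freedom.
    """
    if (s2_post <= 0).any():
        raise DegenerateVarianceError("posterior variances must be positive")
    se = np.sqrt(s2_post * (1 / n_t + 1 / n_r))
    t = effect / se
    dfc = min(df_total, _D0_CAP)  # t with huge df is numerically normal
    p = pd.Series(
        2 * stats.t.sf(np.abs(t.to_numpy()), df=dfc), index=t.index
    )
    return t, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def differential_methylation(
    x: ExperimentMatrix, treatment: str, reference: str
) -> DiffMethResult:
    """Full contrast: probe-wise fit, moderation, moderated test, BH."""
    effect, s2, df, n_t, n_r = probewise_fit(x, treatment, reference)
    d0, s0_sq, s2_post = ebayes_moderate(s2, df)
    df_total = df + d0
    t, p = moderated_test(effect, s2_post, n_t, n_r, df_total)
    q = bh_adjust(p.to_numpy())
    table = pd.DataFrame(
        {
            "effect": effect,
            "s2": s2,
            "t": t,
            "df_total": df_total,
            "p": p,
            "q": q,
        }
    )
    return DiffMethResult(
        table=table, d0=d0, s0_sq=s0_sq, treatment=treatment, reference=reference
    )
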