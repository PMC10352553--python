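"""Deficit-accumulation frailty index and its change over follow-up.

The frailty index (FI) of a person is the proportion of health deficits
present out of those assessed (here 76 by default, configurable), ranging
from 0 to 1.  The denominator counts only answered items; a person missing
more than ``max_missing`` items (default 7, roughly 10% of 76) receives a
missing FI.  Baseline FI is binned into low / mild / high / severe
categories, and the change from baseline to follow-up is binned against a
clinically meaningful difference (CMD) of 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DomainError, ParameterError, SchemaError

CATEGORY_LEVELS = ["low", "mild", "high", "severe"]
CMD_LEVELS = ["none", "cmd1x", "cmd2x", "cmd3x_plus"]

#: Lower edges of the baseline frailty categories (left-closed intervals;
#: severe is closed at 0.3 and runs to 1).
CATEGORY_EDGES = {"low": 0.0, "mild": 0.1, "high": 0.2, "severe": 0.3}


@dataclass
class DeficitTable:
    """Samples x deficits binary table; entries 0, 1 or missing (NaN)."""

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.shape[1] == 0:
            raise SchemaError("deficit table must declare at least one deficit")
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | (arr == 0) | (arr == 1)
        if not ok.all():
            bad = np.unique(arr[~ok])
            raise SchemaError(f"deficit entries must be 0/1/missing; found {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_deficits(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path, na_token: str = "NA") -> "DeficitTable":
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[na_token], keep_default_na=False
        )
        df.index = df.index.astype(str)
        return cls(values=df.astype(float))

    def to_tsv(self, path, na_token: str = "NA") -> None:
        self.values.astype("Int64").to_csv(
            path, sep="\t", index_label="sample_id", na_rep=na_token
        )


@dataclass
class FrailtyResult:
    """Per-sample frailty index, missing-item count, and category."""

    table: pd.DataFrame  # columns: fi, n_missing, category; index sample_id

    @property
    def fi(self) -> pd.Series:
        return self.table["fi"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


@dataclass
class FrailtyChange:
    """Follow-up minus baseline FI, binned against the CMD grid."""

    table: pd.DataFrame  # columns: delta_fi, cmd_class; index sample_id

    @property
    def delta_fi(self) -> pd.Series:
        return self.table["delta_fi"]

    @property
    def cmd_class(self) -> pd.Series:
        return self.table["cmd_class"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def frailty_index(table: DeficitTable, max_missing: int = 7) -> FrailtyResult:
    """FI = (deficits present) / (deficits answered), per sample.

    FI is set to missing for any sample with more than ``max_missing``
    unanswered items.
    """
    if max_missing < 0:
        raise ParameterError("max_missing must be >= 0")
    vals = table.values
    n_missing = vals.isna().sum(axis=1)
    answered = vals.notna().sum(axis=1)
    present = vals.sum(axis=1, skipna=True)
    fi = present / answered.replace(0, np.nan)
    fi[n_missing > max_missing] = np.nan
    category = fi.map(categorize_frailty)
    out = pd.DataFrame(
        {"fi": fi, "n_missing": n_missing.astype(int), "category": category},
        index=vals.index,
    )
    return FrailtyResult(table=out)


def categorize_frailty(fi) -> str | float:
    """Bin an FI value: low [0, 0.1), mild [0.1, 0.2), high [0.2, 0.3),
    severe [0.3, 1].  Missing passes through."""
    if fi is None or (isinstance(fi, float) and np.isnan(fi)):
        return np.nan
    if not 0 <= fi <= 1:
        raise DomainError(f"frailty index {fi} outside [0, 1]")
    if fi < 0.1:
        return "low"
    if fi < 0.2:
        return "mild"
    if fi < 0.3:
        return "high"
    return "severe"


def classify_delta(delta, cmd: float = 0.03) -> str | float:
    """Bin a FI change: none (d <= 0), cmd1x (0 < d < cmd),
    cmd2x (cmd <= d < 2 cmd), cmd3x_plus (d >= 2 cmd)."""
    if delta is None or (isinstance(delta, float) and np.isnan(delta)):
        return np.nan
    if delta <= 0:
        return "none"
    if delta < cmd:
        return "cmd1x"
    if delta < 2 * cmd:
        return "cmd2x"
    return "cmd3x_plus"


def delta_frailty(
    baseline: FrailtyResult, followup: FrailtyResult, cmd: float = 0.03
) -> FrailtyChange:
    """Follow-up minus baseline FI with CMD classification.

    The two results must cover the same samples; missing FI at either
    timepoint propagates to a missing change.
    """
    if cmd <= 0:
        raise ParameterError("cmd must be positive")
    if set(baseline.sample_ids) != set(followup.sample_ids):
        only_b = set(baseline.sample_ids) - set(followup.sample_ids)
        only_f = set(followup.sample_ids) - set(baseline.sample_ids)
        raise AlignmentError(
            f"sample universes differ: {len(only_b)} baseline-only, "
            f"{len(only_f)} follow-up-only"
        )
    fu = followup.fi.reindex(baseline.fi.index)
    delta = fu - baseline.fi
    cls = delta.map(lambda d: classify_delta(d, cmd=cmd))
    out = pd.DataFrame({"delta_fi": delta, "cmd_class": cls}, index=delta.index)
    return FrailtyChange(table=out)
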