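"""RPPA fold-change z-scoring and protein selection.

Reverse-phase protein arrays quantify (phospho)proteins across lysates;
after the array facility's quantification and quantile normalization, the
analysis here starts from fold changes (treated over vehicle). Each
column's fold changes are log2-transformed and standardized against the
mean and standard deviation of all proteins on that array:

    z = (log2 fc - mean of all log2 fc) / sd of all log2 fc

and proteins exceeding a cutoff (|z| > 1.96, i.e. the two-sided 5% normal
tail) in *every* required column — both cell lines — are selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateColumnError, DomainError

DEFAULT_Z_CUTOFF = 1.96
DEFAULT_SIGNAL_THRESHOLD = 100.0  # arbitrary-intensity floor; a convention, tunable


@dataclass(frozen=True)
class FoldChangeTable:
    """Strictly positive fold changes (treated / vehicle), proteins x columns."""

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.shape[0] == 0:
            return
        if (self.values <= 0).any().any():
            raise DomainError("fold changes must be strictly positive ratios")
        if self.values.isna().any().any():
            raise DomainError("fold-change table contains missing values")

    @classmethod
    def from_csv(cls, path) -> "FoldChangeTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="protein")


@dataclass(frozen=True)
class ZScoreSelection:
    """Per-column z-scores with (optionally) the proteins they select."""

    z: pd.DataFrame
    cutoff: float = DEFAULT_Z_CUTOFF
    selected: tuple[str, ...] = ()


def filter_low_signal(
    raw: pd.DataFrame,
    threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    signal_column: str = "signal",
) -> tuple[FoldChangeTable, int]:
    """Drop proteins with insufficient signal; returns (table, n_removed).

    ``raw`` carries the fold-change columns plus one signal column; rows
    whose signal falls below ``threshold`` are removed and the signal
    column is stripped from the result.
    """
    if signal_column not in raw.columns:
        raise ConfigurationError(f"signal column {signal_column!r} not present")
    keep = raw[signal_column] >= threshold
    table = raw.loc[keep].drop(columns=[signal_column])
    return FoldChangeTable(table), int((~keep).sum())


def compute_zscores(
    table: FoldChangeTable,
    ddof: int = 1,
    pooled_groups: list[list[str]] | None = None,
) -> ZScoreSelection:
    """Within-array z-scores of log2 fold changes.

    By default each column is standardized against its own mean and sample
    (n-1) standard deviation; ``ddof=0`` switches to the population form.
    ``pooled_groups`` (experimental) standardizes the listed column groups
    against the group's pooled mean/sd instead — e.g. all treatments of one
    cell line sharing one array-level reference distribution.
    """
    df = table.values
    if df.shape[0] < 3:
        raise DomainError("z-scores need at least 3 proteins per column")
    log2fc = np.log2(df)
    z = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    groups = pooled_groups or [[c] for c in df.columns]
    covered = [c for g in groups for c in g]
    if sorted(covered) != sorted(df.columns):
        raise ConfigurationError("pooled_groups must partition the table columns")
    for group in groups:
        block = log2fc[group]
        mean = float(block.to_numpy().mean())
        sd = float(block.to_numpy().std(ddof=ddof))
        if sd == 0:
            raise DegenerateColumnError(
                f"zero standard deviation in column(s) {group}: z undefined"
            )
        z[group] = (block - mean) / sd
    return ZScoreSelection(z=z)


def select_proteins(
    selection: ZScoreSelection,
    required_columns: list[str],
    cutoff: float = DEFAULT_Z_CUTOFF,
) -> list[str]:
    """Proteins with |z| > cutoff in every required column.

    Ordered by descending minimum |z| across the required columns, so the
    most consistently extreme proteins come first.
    """
    missing = [c for c in required_columns if c not in selection.z.columns]
    if missing:
        raise KeyError(f"unknown column(s): {missing}")
    if not required_columns:
        raise ConfigurationError("required_columns must not be empty")
    sub = selection.z[list(required_columns)].abs()
    min_abs = sub.min(axis=1)
    hits = min_abs[min_abs > cutoff]
    return list(hits.sort_values(ascending=False, kind="stable").index)


def long_format(selection: ZScoreSelection, table: FoldChangeTable) -> pd.DataFrame:
    """Heatmap-ready long format: one row per (protein, column) observation."""
    z_long = selection.z.reset_index(names="protein").melt(
        id_vars="protein", var_name="column", value_name="z"
    )
    fc_long = table.values.reset_index(names="protein").melt(
        id_vars="protein", var_name="column", value_name="fold_change"
    )
    out = z_long.merge(fc_long, on=["protein", "column"])
    out["log2_fc"] = np.log2(out["fold_change"])
    return out
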