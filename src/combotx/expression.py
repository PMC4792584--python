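"""Count-level RNA-seq processing.

The chain implemented here takes a genes x samples count matrix to the
ranked list a preranked GSEA consumes: low-count filtering (genes with
fewer than 5 counts in total dropped), upper-quartile normalization
(per-sample scaling so the 75th percentiles of expressed genes agree
across samples, expressed on a counts-per-million-like scale), fold
changes against the vehicle condition, and the symmetric 1.5-fold
regulation threshold. A small fold-vs-control utility covers simple
plate-assay readouts (e.g. caspase activation as fold of DMSO control).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, NormalizationError
from .gsea import RankedList

DEFAULT_MIN_TOTAL = 5  # genes with fewer total counts are excluded
DEFAULT_MIN_FOLD = 1.5  # symmetric regulation threshold (>= 1.5 or <= 1/1.5)
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class CountMatrix:
    """Integer counts with a condition label per sample."""

    counts: pd.DataFrame  # genes x samples
    conditions: pd.Series  # sample -> condition

    def __post_init__(self):
        if self.counts.columns.duplicated().any():
            raise ConfigurationError("sample labels must be unique")
        if self.counts.index.duplicated().any():
            raise ConfigurationError("gene identifiers must be unique")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ConfigurationError(f"samples without a condition: {sorted(missing)}")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise DomainError("counts must be non-negative integers")

    @classmethod
    def from_tsv(cls, path, conditions: dict | pd.Series | None = None) -> "CountMatrix":
        """Read a tab-delimited genes x samples matrix with a header row.

        Without an explicit sample -> condition mapping, conditions are
        inferred from sample names of the form ``<condition>_<replicate>``.
        """
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if conditions is None:
            conditions = pd.Series(
                {c: c.rsplit("_", 1)[0] for c in counts.columns}, name="condition"
            )
        else:
            conditions = pd.Series(conditions, name="condition")
        return cls(counts, conditions)


@dataclass(frozen=True)
class NormalizedExpression:
    """Upper-quartile normalized expression values with their scale factors."""

    values: pd.DataFrame
    scale_factors: pd.Series
    conditions: pd.Series


def filter_low_counts(matrix: CountMatrix, min_total: int = DEFAULT_MIN_TOTAL) -> CountMatrix:
    """Drop genes whose summed counts across all samples fall below ``min_total``."""
    keep = matrix.counts.sum(axis=1) >= min_total
    return CountMatrix(matrix.counts.loc[keep], matrix.conditions)


def upper_quartile_normalize(matrix: CountMatrix) -> NormalizedExpression:
    """Scale samples so their upper-quartile counts agree.

    The 75th percentile (linear-interpolation quantile) is taken per sample
    over genes with a nonzero count in at least one sample — the standard
    upper-quartile convention, since all-zero genes carry no depth
    information. Scale factor = sample p75 / geometric mean of the p75s;
    values are counts divided by their factor, then put on a per-million
    scale with a single global constant so cross-sample comparability is
    untouched.
    """
    counts = matrix.counts
    expressed = counts.loc[counts.sum(axis=1) > 0]
    if expressed.empty:
        raise NormalizationError("no expressed genes to normalize on")
    p75 = expressed.quantile(0.75, axis=0, interpolation="linear")
    if (p75 <= 0).any():
        bad = list(p75.index[p75 <= 0])
        raise NormalizationError(f"zero 75th percentile in samples: {bad}")
    factors = p75 / stats.gmean(p75)
    scaled = counts / factors
    per_million = 1e6 / scaled.sum(axis=0).mean()
    return NormalizedExpression(
        values=scaled * per_million,
        scale_factors=factors,
        conditions=matrix.conditions,
    )


def fold_change_vs_reference(
    expr: NormalizedExpression,
    condition: str,
    reference: str = "vehicle",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene fold change of ``condition`` over ``reference``.

    Sample values are averaged within each condition (single-sample
    conditions degenerate to that sample), then
    ``fc = (mean_cond + pseudocount) / (mean_ref + pseudocount)``.
    Returns a table with ``fold_change`` and ``log2_fc`` columns.
    """
    cond_samples = expr.conditions.index[expr.conditions == condition]
    ref_samples = expr.conditions.index[expr.conditions == reference]
    for label, samples in ((condition, cond_samples), (reference, ref_samples)):
        if len(samples) == 0:
            raise KeyError(f"no samples with condition {label!r}")
    mean_c = expr.values[list(cond_samples)].mean(axis=1)
    mean_r = expr.values[list(ref_samples)].mean(axis=1)
    fc = (mean_c + pseudocount) / (mean_r + pseudocount)
    return pd.DataFrame({"fold_change": fc, "log2_fc": np.log2(fc)})


def threshold_and_rank(
    fold_changes: pd.DataFrame, min_fold: float = DEFAULT_MIN_FOLD
) -> RankedList:
    """Keep regulated genes and rank them by log2 fold change, descending.

    "Regulated" is the symmetric linear rule: fold change >= ``min_fold``
    or <= ``1/min_fold``. Ties are broken by gene identifier so the output
    is invariant to input row order. An empty result is allowed (with a
    warning) and yields an empty ranked list.
    """
    if min_fold <= 1:
        raise ConfigurationError("min_fold must exceed 1")
    fc = fold_changes["fold_change"]
    keep = (fc >= min_fold) | (fc <= 1.0 / min_fold)
    if not keep.any():
        warnings.warn("no genes pass the fold-change threshold", stacklevel=2)
        return RankedList((), np.array([]))
    sel = fold_changes.loc[keep, "log2_fc"]
    return RankedList.from_scores(sel)


def fold_vs_control(values: pd.Series, groups: pd.Series, control_label: str) -> pd.Series:
    """Each group's mean readout as a fold of the control group's mean.

    ``values`` are raw per-well readouts, ``groups`` the parallel group
    labels. The control fold is 1 by construction.
    """
    if control_label not in set(groups):
        raise KeyError(f"control group {control_label!r} not present")
    means = values.groupby(groups).mean()
    control = means[control_label]
    if control == 0:
        raise DomainError("control group mean is zero; folds undefined")
    return means / control


def write_normalized_tsv(expr: NormalizedExpression, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def write_fold_changes_csv(fold_changes: pd.DataFrame, path) -> None:
    fold_changes.to_csv(path, index_label="gene")
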