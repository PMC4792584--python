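"""Preranked and two-class gene-set enrichment analysis.

A from-scratch implementation of the weighted Kolmogorov-Smirnov-like
running-sum statistic: walking down a ranked gene list, the sum rises by
``|score|^p / sum(|score|^p over set members)`` at each set member and
falls by ``1/(N - k)`` at each non-member; the enrichment score (ES) is the
signed maximum deviation from zero. Significance comes from permutation:

* **preranked mode** — the null re-draws random gene sets of the same size
  from the ranked universe (gene-label permutation), the only null
  available once the data are reduced to a ranked list;
* **phenotype mode** — two-class expression data are re-ranked by a
  signal-to-noise metric ``(mu_A - mu_B)/(sigma_A + sigma_B)`` after
  shuffling the class labels; when fewer distinct label splits exist than
  requested permutations they are enumerated exhaustively.

NES normalizes ES by the mean |null ES| of matching sign (separate
positive/negative null means); the FDR q value compares pooled normalized
null tails against the observed NES tails, clipped to [0, 1] and made
monotone in |NES|.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, NoOverlapError

DEFAULT_MIN_OVERLAP = 5
DEFAULT_MAX_OVERLAP = 500
FDR_SIGNIFICANCE = 0.25  # conventional preranked-GSEA significance level


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise DomainError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise DomainError(f"gene set {self.name!r} has duplicate members")


@dataclass(frozen=True)
class RankedList:
    """Genes sorted by score, descending, with a deterministic tie-break.

    Scores are typically log2 fold changes (preranked mode) or
    signal-to-noise ratios (phenotype mode).
    """

    genes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != scores.size:
            raise DomainError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise DomainError("ranked list contains duplicate genes")
        if np.any(np.diff(scores) > 1e-12):
            raise DomainError("scores must be sorted in descending order")
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, scores: pd.Series | dict) -> "RankedList":
        """Build from an unsorted gene -> score mapping (ties broken by id)."""
        s = pd.Series(scores, dtype=float)
        s = s.sort_index().sort_values(ascending=False, kind="stable")
        return cls(tuple(s.index), s.to_numpy())

    def to_rnk(self, path) -> None:
        """Write the standard two-column RNK file (gene TAB score, no header)."""
        pd.DataFrame({"gene": self.genes, "score": self.scores}).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_rnk(cls, path) -> "RankedList":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise DomainError(f"{path}: RNK files need two tab-separated columns")
        return cls.from_scores(pd.Series(df[1].to_numpy(float), index=df[0].astype(str)))


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    n_overlap: int
    direction: str  # "up" (toward the top of the list) or "down"


@dataclass(frozen=True)
class EsProfile:
    es: float
    running_sum: np.ndarray
    hit_indices: np.ndarray


# ---------------------------------------------------------------------------
# GMT input/output
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, name TAB description TAB members."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DomainError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {name!r} removed",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, tuple(uniq)))
    return sets


def write_gmt(sets, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for s in sets:
            desc = descriptions.get(s.name, "na")
            fh.write("\t".join([s.name, desc, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0, min_overlap: int = 1
) -> EsProfile:
    """Weighted running-sum enrichment score with its full profile.

    Raises ``NoOverlapError`` below ``min_overlap`` and ``DomainError`` when
    the set covers the entire list (no misses: the decrement is undefined).
    If every member has score exactly 0 under ``weight_p > 0`` the hit
    weights degrade gracefully to uniform.
    """
    members = frozenset(gene_set.members)
    hit_mask = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    n_hits = int(hit_mask.sum())
    if n_hits < max(min_overlap, 1):
        raise NoOverlapError(
            f"set {gene_set.name!r} overlaps the ranked list in {n_hits} genes "
            f"(minimum {min_overlap})"
        )
    n = len(ranked)
    if n_hits == n:
        raise DomainError(
            f"set {gene_set.name!r} covers the entire ranked list; ES is undefined"
        )
    weights = np.abs(ranked.scores) ** weight_p if weight_p != 0 else np.ones(n)
    hit_w = np.where(hit_mask, weights, 0.0)
    total_w = hit_w.sum()
    if total_w == 0:  # all member scores are exactly zero
        hit_w = hit_mask.astype(float)
        total_w = hit_w.sum()
    steps = hit_w / total_w - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return EsProfile(es=es, running_sum=running, hit_indices=np.flatnonzero(hit_mask))


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray, n: int
) -> np.ndarray:
    """Batch ES from hit positions, one row of ``positions`` per permutation.

    The running sum only attains its extrema immediately after a hit
    increment (positive side) or immediately before one, after the
    preceding run of misses (negative side), so ES is computable from the
    k hit positions alone in O(k log k) per row.
    """
    positions = np.sort(positions, axis=1)
    k = positions.shape[1]
    w = weights[positions]
    cum = np.cumsum(w, axis=1)
    total = cum[:, -1:]
    degenerate = total[:, 0] == 0
    if np.any(degenerate):
        w = np.where(degenerate[:, None], 1.0, w)
        cum = np.cumsum(w, axis=1)
        total = cum[:, -1:]
    miss_before = positions - np.arange(k)
    dec = miss_before / (n - k)
    after = cum / total - dec
    before = (cum - w) / total - dec
    pos_max = after.max(axis=1)
    neg_min = before.min(axis=1)
    return np.where(pos_max >= -neg_min, pos_max, neg_min)


# ---------------------------------------------------------------------------
# Permutation significance machinery (shared by both modes)
# ---------------------------------------------------------------------------


def _normalize_by_sign(es: np.ndarray, null: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NES for observed and null ES, normalizing each sign separately.

    Each set's null distribution provides a positive mean and a negative
    mean; every ES (observed or null) is divided by the same-sign mean of
    its own set's null.
    """
    n_sets = es.size
    nes = np.zeros(n_sets)
    null_nes = np.zeros_like(null)
    for i in range(n_sets):
        pos = null[i][null[i] > 0]
        neg = null[i][null[i] < 0]
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg).mean() if neg.size else np.nan
        with np.errstate(invalid="ignore"):
            null_nes[i] = np.where(null[i] >= 0, null[i] / pos_mean, null[i] / neg_mean)
        if es[i] >= 0:
            nes[i] = es[i] / pos_mean if pos.size else 0.0
        else:
            nes[i] = es[i] / neg_mean if neg.size else 0.0
    null_nes = np.nan_to_num(null_nes, nan=0.0)
    return nes, null_nes


def _nominal_p(es: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Tail probability of each observed ES against its same-sign null."""
    p = np.ones(es.size)
    for i in range(es.size):
        same = null[i][null[i] >= 0] if es[i] >= 0 else null[i][null[i] < 0]
        if same.size == 0:
            p[i] = 1.0
        elif es[i] >= 0:
            p[i] = float(np.mean(same >= es[i]))
        else:
            p[i] = float(np.mean(same <= es[i]))
    return p


def _fdr_q(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR q: pooled null tail fraction over observed tail fraction."""
    pooled = null_nes.ravel()
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled < 0]
    obs_pos = nes[nes >= 0]
    obs_neg = nes[nes < 0]
    q = np.ones(nes.size)
    for i, v in enumerate(nes):
        if v >= 0:
            num = np.mean(pooled_pos >= v) if pooled_pos.size else 1.0
            den = np.mean(obs_pos >= v) if obs_pos.size else 1.0
        else:
            num = np.mean(pooled_neg <= v) if pooled_neg.size else 1.0
            den = np.mean(obs_neg <= v) if obs_neg.size else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    # monotone adjustment: a set's q is the best (smallest) raw FDR over the
    # thresholds that would still call it, i.e. over same-sign sets with
    # |NES| at most its own — so q never increases as |NES| grows.
    for sign_mask in (nes >= 0, nes < 0):
        idx = np.flatnonzero(sign_mask)
        if idx.size == 0:
            continue
        order = idx[np.argsort(np.abs(nes[idx]), kind="stable")]
        best = np.inf
        for j in order:
            best = min(best, q[j])
            q[j] = best
    return q


def _summarize(
    sets: list[GeneSet],
    overlaps: list[int],
    es: np.ndarray,
    null: np.ndarray,
) -> list[GseaResult]:
    nes, null_nes = _normalize_by_sign(es, null)
    p = _nominal_p(es, null)
    q = _fdr_q(nes, null_nes)
    return [
        GseaResult(
            set_name=s.name,
            es=float(es[i]),
            nes=float(nes[i]),
            p_nominal=float(p[i]),
            fdr_q=float(q[i]),
            n_overlap=overlaps[i],
            direction="up" if es[i] >= 0 else "down",
        )
        for i, s in enumerate(sets)
    ]


def _filter_sets(ranked: RankedList, sets, min_overlap: int, max_overlap: int):
    universe = set(ranked.genes)
    kept, overlaps = [], []
    for s in sets:
        k = len(universe.intersection(s.members))
        if min_overlap <= k <= max_overlap:
            kept.append(s)
            overlaps.append(k)
    return kept, overlaps


def preranked_gsea(
    ranked: RankedList,
    sets,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[GseaResult]:
    """Preranked GSEA with a gene-label permutation null.

    For each retained set the null ES distribution comes from ``n_perm``
    random same-size gene sets drawn from the ranked universe. Deterministic
    given ``seed``.
    """
    if n_perm < 10:
        raise ConfigurationError("n_perm must be >= 10")
    if len(ranked) == 0:
        raise DomainError("ranked list is empty")
    kept, overlaps = _filter_sets(ranked, sets, min_overlap, max_overlap)
    if not kept:
        raise NoOverlapError(
            "no gene set overlaps the ranked list within the size bounds"
        )
    n = len(ranked)
    weights = np.abs(ranked.scores) ** weight_p if weight_p != 0 else np.ones(n)
    rng = np.random.default_rng(seed)

    es = np.array(
        [enrichment_score(ranked, s, weight_p, min_overlap).es for s in kept]
    )
    null = np.zeros((len(kept), n_perm))
    for i, k in enumerate(overlaps):
        # k smallest entries of random keys = uniform sample without replacement
        keys = rng.random((n_perm, n))
        positions = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[i] = _es_from_positions(weights, positions, n)
    return _summarize(kept, overlaps, es, null)


# ---------------------------------------------------------------------------
# Two-class (phenotype permutation) mode
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoClassExpression:
    """Normalized expression with a binary phenotype per sample."""

    values: pd.DataFrame  # genes x samples
    phenotypes: pd.Series  # sample -> label; exactly two distinct labels

    def __post_init__(self):
        labels = self.phenotypes.unique()
        if len(labels) != 2:
            raise ConfigurationError(
                f"exactly two phenotype classes required, got {list(labels)}"
            )
        missing = set(self.values.columns) - set(self.phenotypes.index)
        if missing:
            raise ConfigurationError(f"samples without phenotype labels: {sorted(missing)}")

    @property
    def classes(self) -> tuple[str, str]:
        # first label encountered in column order is the positive class
        seen = list(dict.fromkeys(self.phenotypes[self.values.columns]))
        return seen[0], seen[1]


def _s2n_scores(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene with the conventional sd floors for tiny n."""
    a = values[:, mask_a]
    b = values[:, ~mask_a]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = a.std(axis=1, ddof=1) if a.shape[1] > 1 else np.zeros(values.shape[0])
    sd_b = b.std(axis=1, ddof=1) if b.shape[1] > 1 else np.zeros(values.shape[0])

    def floored(sd, mean):
        floor = np.where(mean != 0, 0.2 * np.abs(mean), 0.2)
        return np.maximum(sd, floor)

    return (mean_a - mean_b) / (floored(sd_a, mean_a) + floored(sd_b, mean_b))


def signal_to_noise_ranking(
    expr: TwoClassExpression, positive_class: str | None = None
) -> RankedList:
    """Rank genes by (mu_A - mu_B)/(sigma_A + sigma_B), descending.

    Standard deviations are floored at 20% of |mean| (0.2 absolute when the
    mean is 0) so tiny-sample classes do not produce unbounded scores; a
    warning flags classes with fewer than 3 samples.
    """
    pos = positive_class or expr.classes[0]
    labels = expr.phenotypes[expr.values.columns]
    mask_a = (labels == pos).to_numpy()
    if mask_a.sum() == 0 or (~mask_a).sum() == 0:
        raise ConfigurationError("both phenotype classes need at least one sample")
    if mask_a.sum() < 3 or (~mask_a).sum() < 3:
        warnings.warn(
            "fewer than 3 samples in a class: sd floors dominate the ranking",
            stacklevel=2,
        )
    scores = _s2n_scores(expr.values.to_numpy(float), mask_a)
    return RankedList.from_scores(pd.Series(scores, index=expr.values.index))


def phenotype_permutation_gsea(
    expr: TwoClassExpression,
    sets,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[GseaResult]:
    """GSEA with class-label permutation of a two-class expression matrix.

    When the number of distinct label splits is at most ``n_perm`` they are
    enumerated exhaustively (with a warning), which fixes the attainable
    p-value granularity. With both classes of size 1 no informative label
    shuffle exists, so the call falls back to preranked (gene-label) GSEA
    on the observed ranking, with a warning.
    """
    if n_perm < 10:
        raise ConfigurationError("n_perm must be >= 10")
    ranked = signal_to_noise_ranking(expr)
    labels = expr.phenotypes[expr.values.columns]
    pos = expr.classes[0]
    mask_obs = (labels == pos).to_numpy()
    n_samples = mask_obs.size
    n_a = int(mask_obs.sum())
    if n_a == 1 and n_samples - n_a == 1:
        warnings.warn(
            "both classes have a single sample: falling back to gene-set permutation",
            stacklevel=2,
        )
        return preranked_gsea(
            ranked, sets, n_perm, weight_p, seed, min_overlap, max_overlap
        )

    kept, overlaps = _filter_sets(ranked, sets, min_overlap, max_overlap)
    if not kept:
        raise NoOverlapError(
            "no gene set overlaps the expression genes within the size bounds"
        )
    values = expr.values.to_numpy(float)
    genes = expr.values.index
    rng = np.random.default_rng(seed)

    n_distinct = math.comb(n_samples, n_a)
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label splits exist; enumerating all "
            f"(p-value granularity 1/{n_distinct})",
            stacklevel=2,
        )
        masks = []
        for combo in itertools.combinations(range(n_samples), n_a):
            m = np.zeros(n_samples, bool)
            m[list(combo)] = True
            masks.append(m)
    else:
        masks = []
        for _ in range(n_perm):
            idx = rng.choice(n_samples, size=n_a, replace=False)
            m = np.zeros(n_samples, bool)
            m[idx] = True
            masks.append(m)

    member_sets = [frozenset(s.members) for s in kept]
    es = np.array(
        [enrichment_score(ranked, s, weight_p, min_overlap).es for s in kept]
    )
    null = np.zeros((len(kept), len(masks)))
    for j, mask in enumerate(masks):
        scores = _s2n_scores(values, mask)
        perm_ranked = RankedList.from_scores(pd.Series(scores, index=genes))
        n = len(perm_ranked)
        weights = (
            np.abs(perm_ranked.scores) ** weight_p if weight_p != 0 else np.ones(n)
        )
        gene_pos = {g: i for i, g in enumerate(perm_ranked.genes)}
        for i, members in enumerate(member_sets):
            positions = np.array(
                [[gene_pos[g] for g in members if g in gene_pos]]
            )
            null[i, j] = _es_from_positions(weights, positions, n)[0]
    return _summarize(kept, overlaps, es, null)


def results_table(results: list[GseaResult], fdr_cutoff: float = FDR_SIGNIFICANCE) -> pd.DataFrame:
    """Tabular view of GSEA results with a significance flag."""
    df = pd.DataFrame([r.__dict__ for r in results])
    df["significant"] = df["fdr_q"] < fdr_cutoff
    return df.sort_values(["fdr_q", "p_nominal", "set_name"]).reset_index(drop=True)
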