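"""Dose-matrix synergy scoring.

Two orthogonal synergy statistics over a two-agent dose matrix:

* **Bliss independence** — the expected combined inhibition of two
  non-interacting agents is ``A + B - A*B`` of the single-agent fractional
  inhibitions. The per-cell Bliss score is observed minus expected; the
  Bliss sum totals the scores over the matrix, positive values marking
  greater-than-additive regions.
* **Chou-Talalay combination index** — ``CI = D1/Dx1 + D2/Dx2`` where
  ``Dx_i`` is the dose of agent *i* alone that would, per its median-effect
  fit, reach the fractional effect observed for the combination. CI < 1
  indicates synergy, CI = 1 additivity, CI > 1 antagonism. The two-term
  (mutually exclusive) form is used, matching the CompuSyn default.

The matrix layout convention: row index = agent-A doses, column index =
agent-B doses, both grids starting at dose 0, so row 0 and column 0 hold
the monotherapy responses and cell (0, 0) the untreated reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import FA_EPS, MedianEffectFit, dose_for_effect
from .errors import DomainError, NoEvaluableCellsError, StructureError

#: fractional-effect window used for CI summaries (20-90% growth inhibition).
FA_WINDOW = (0.2, 0.9)


@dataclass(frozen=True)
class CombinationMatrix:
    """Observed fractional growth inhibition on a two-agent dose grid."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self):
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        inh = np.asarray(self.inhibition, dtype=float)
        if inh.shape != (da.size, db.size):
            raise StructureError(
                f"inhibition shape {inh.shape} does not match grid "
                f"({da.size} x {db.size})"
            )
        for name, grid in (("doses_a", da), ("doses_b", db)):
            if grid[0] != 0:
                raise StructureError(f"{name} must start at dose 0 (monotherapy axis)")
            if np.any(np.diff(grid) <= 0):
                raise StructureError(f"{name} must be strictly increasing")
        if np.any(inh < -1e-9) or np.any(inh > 1 + 1e-9):
            raise DomainError("inhibition values must lie in [0, 1]")
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)
        object.__setattr__(self, "inhibition", np.clip(inh, 0.0, 1.0))

    @property
    def monotherapy_a(self) -> np.ndarray:
        """Agent-A monotherapy response (column at dose_b = 0)."""
        return self.inhibition[:, 0]

    @property
    def monotherapy_b(self) -> np.ndarray:
        """Agent-B monotherapy response (row at dose_a = 0)."""
        return self.inhibition[0, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.inhibition, index=self.doses_a, columns=self.doses_b)

    def to_csv(self, path, viability: bool = False) -> None:
        """Write the grid as CSV (first row = B doses, first column = A doses).

        ``viability=True`` writes ``1 - fa`` instead of growth inhibition.
        """
        values = 1.0 - self.inhibition if viability else self.inhibition
        pd.DataFrame(values, index=self.doses_a, columns=self.doses_b).to_csv(
            path, index_label="dose_a\\dose_b"
        )

    @classmethod
    def from_csv(cls, path) -> "CombinationMatrix":
        df = pd.read_csv(path, index_col=0)
        try:
            doses_a = df.index.to_numpy(dtype=float)
            doses_b = df.columns.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise StructureError(f"{path}: dose labels must be numeric") from exc
        return cls(doses_a, doses_b, df.to_numpy(dtype=float))


@dataclass(frozen=True)
class BlissAnalysis:
    """Bliss expectation, per-cell scores and their matrix total.

    ``expectation`` and ``scores`` cover only the combination cells (both
    doses > 0), aligned with ``doses_a[1:]`` x ``doses_b[1:]``.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    expectation: np.ndarray
    scores: np.ndarray
    bliss_sum: float

    def scores_frame(self, percent: bool = False) -> pd.DataFrame:
        s = self.scores * 100.0 if percent else self.scores
        return pd.DataFrame(s, index=self.doses_a[1:], columns=self.doses_b[1:])

    def bliss_sum_percent(self) -> float:
        """Bliss sum on the 0-100 inhibition scale (sum of scores x 100)."""
        return float(self.bliss_sum * 100.0)


@dataclass(frozen=True)
class CombinationIndexProfile:
    """Per-cell combination indices with an FA-binned summary and verdict."""

    entries: pd.DataFrame  # columns: dose_a, dose_b, fa_observed, ci
    fa_bin_summary: pd.DataFrame  # columns: fa_low, fa_high, n_cells, median_ci
    median_ci: float
    verdict: str
    n_excluded: int


def bliss_expectation(fa_a, fa_b):
    """Bliss-independent expected inhibition ``A + B - A*B``.

    Accepts scalars or arrays; inputs outside [0, 1] raise ``DomainError``.
    """
    a = np.asarray(fa_a, dtype=float)
    b = np.asarray(fa_b, dtype=float)
    if np.any(a < 0) or np.any(a > 1) or np.any(b < 0) or np.any(b > 1):
        raise DomainError("fractional inhibitions must lie in [0, 1]")
    out = a + b - a * b
    return float(out) if out.ndim == 0 else out


def bliss_score_matrix(matrix: CombinationMatrix) -> BlissAnalysis:
    """Score every combination cell against the Bliss expectation.

    The expectation for cell (i, j) uses the monotherapy inhibitions read
    from column 0 (agent A at dose ``doses_a[i]``) and row 0 (agent B at
    dose ``doses_b[j]``). Monotherapy cells contribute only as reference;
    the Bliss sum runs over cells with both doses > 0.
    """
    if matrix.doses_a.size < 2 or matrix.doses_b.size < 2:
        raise StructureError("matrix needs at least one non-zero dose per agent")
    mono_a = matrix.monotherapy_a[1:]
    mono_b = matrix.monotherapy_b[1:]
    expectation = bliss_expectation(mono_a[:, None], mono_b[None, :])
    observed = matrix.inhibition[1:, 1:]
    scores = observed - expectation
    return BlissAnalysis(
        doses_a=matrix.doses_a,
        doses_b=matrix.doses_b,
        expectation=expectation,
        scores=scores,
        bliss_sum=float(scores.sum()),
    )


def _verdict(median_ci: float, tol: float = 1e-6) -> str:
    # Aggregation over a matrix: synergy iff the median CI over evaluable
    # cells in the FA window is < 1; a narrow band above 1 is additive. The
    # tolerance keeps exactly-additive data (CI = 1 to rounding) off the
    # synergy side of the knife edge.
    if median_ci < 1.0 - tol:
        return "synergy"
    if median_ci < 1.1:
        return "additive"
    return "antagonism"


def combination_index(
    matrix: CombinationMatrix,
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fa_window: tuple[float, float] = FA_WINDOW,
    eps: float = FA_EPS,
) -> CombinationIndexProfile:
    """Chou-Talalay CI per combination cell, summarized over the FA window.

    Each cell (D1, D2) with observed fa strictly inside (0, 1 - eps)
    contributes ``CI = D1/Dx1(fa) + D2/Dx2(fa)``. Cells at fa <= 0 or at
    the upper clamp boundary are excluded (Dx would be 0 or infinite), and
    the exclusion count is reported. The verdict is taken from the median
    CI over cells with fa inside ``fa_window`` (the 20-90% effect range by
    default); the matrix is not a fixed-ratio design, so the CI-vs-FA view
    bins cells into FA deciles across the window.
    """
    lo, hi = fa_window
    rows = []
    n_excluded = 0
    for i in range(1, matrix.doses_a.size):
        for j in range(1, matrix.doses_b.size):
            fa = matrix.inhibition[i, j]
            if fa <= eps or fa >= 1.0 - eps:
                n_excluded += 1
                continue
            ci = (
                matrix.doses_a[i] / dose_for_effect(fit_a, fa)
                + matrix.doses_b[j] / dose_for_effect(fit_b, fa)
            )
            rows.append((matrix.doses_a[i], matrix.doses_b[j], fa, ci))
    if not rows:
        raise NoEvaluableCellsError("no combination cell has fa inside (0, 1)")
    entries = pd.DataFrame(rows, columns=["dose_a", "dose_b", "fa_observed", "ci"])

    in_window = entries[(entries.fa_observed >= lo) & (entries.fa_observed <= hi)]
    if in_window.empty:
        raise NoEvaluableCellsError(
            f"no combination cell has fa inside the summary window [{lo}, {hi}]"
        )
    bin_edges = np.linspace(lo, hi, 8)  # FA deciles 0.2-0.9 by default
    bins = []
    for k in range(len(bin_edges) - 1):
        blo, bhi = bin_edges[k], bin_edges[k + 1]
        sel = in_window[
            (in_window.fa_observed >= blo)
            & (in_window.fa_observed < bhi if k < 6 else in_window.fa_observed <= bhi)
        ]
        bins.append(
            (blo, bhi, len(sel), float(sel.ci.median()) if len(sel) else np.nan)
        )
    summary = pd.DataFrame(bins, columns=["fa_low", "fa_high", "n_cells", "median_ci"])
    median_ci = float(in_window.ci.median())
    return CombinationIndexProfile(
        entries=entries,
        fa_bin_summary=summary,
        median_ci=median_ci,
        verdict=_verdict(median_ci),
        n_excluded=n_excluded,
    )
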