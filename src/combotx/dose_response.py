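"""Single-agent dose-response fitting.

Two complementary fits of monotherapy growth-inhibition data:

* the median-effect linearization of Chou and Talalay, which turns the
  Hill-type relation ``fa/fu = (D/Dm)^m`` into a straight line on
  ``(log D, log(fa/fu))`` coordinates and yields the slope ``m`` and the
  median-effect dose ``Dm`` (the dose giving 50% effect) that the
  combination-index calculation requires;
* a 3-parameter logistic (bottom fixed at 0) for IC50 estimation, the
  conventional potency readout for a viability curve.

``fa`` throughout is the fraction affected (fractional growth inhibition,
1 = fully inhibited); ``fu = 1 - fa`` is the unaffected fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateFitError,
    DomainError,
    FitFailureError,
    InsufficientDataError,
)

#: fa values are clamped into [FA_EPS, 1 - FA_EPS] before the log-odds
#: transform; cells at exactly 0 (dose 0) are excluded rather than clamped.
FA_EPS = 1e-4


@dataclass(frozen=True)
class DoseResponsePoints:
    """Paired (dose, fraction affected) observations for one agent."""

    doses: np.ndarray
    fa: np.ndarray

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        if doses.shape != fa.shape or doses.ndim != 1:
            raise DomainError("doses and fa must be 1-D arrays of equal length")
        if not np.all(np.isfinite(doses)) or np.any(doses < 0):
            raise DomainError("doses must be finite and non-negative")
        if np.any(fa < -FA_EPS) or np.any(fa > 1 + FA_EPS):
            raise DomainError("fraction affected must lie in [0, 1]")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "fa", np.clip(fa, 0.0, 1.0))

    @classmethod
    def from_csv(cls, path) -> "DoseResponsePoints":
        """Read a two-column (dose, fraction_affected) CSV."""
        import pandas as pd

        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise DomainError(f"{path}: expected two columns (dose, fraction_affected)")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters: fa/fu = (D/Dm)^m.

    ``r_squared`` is reported on the linearized (log D, log odds)
    coordinates, mirroring the "r" quality statistic CompuSyn-style
    analyses print for the median-effect plot.
    """

    slope_m: float
    median_dose_dm: float
    r_squared: float
    n_points_used: int

    def fa_at_dose(self, dose):
        """Fraction affected predicted at ``dose`` (0 at dose 0)."""
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, (dose / self.median_dose_dm) ** self.slope_m, 0.0)
        return ratio / (1.0 + ratio)


@dataclass(frozen=True)
class LogisticFit3P:
    """3-parameter logistic fit fa = top / (1 + (ic50/D)^hill), bottom = 0."""

    top: float
    hill_slope: float
    ic50: float
    rss: float
    n_restarts: int = 0

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(
                dose > 0,
                self.top / (1.0 + (self.ic50 / np.maximum(dose, 1e-300)) ** self.hill_slope),
                0.0,
            )
        return out


def _usable_points(points: DoseResponsePoints, eps: float = FA_EPS):
    """Positive-dose points with fa clamped strictly inside (0, 1).

    Dose-0 cells (fa defined as exactly 0) are excluded, not clamped.
    """
    mask = points.doses > 0
    d = points.doses[mask]
    fa = np.clip(points.fa[mask], eps, 1.0 - eps)
    return d, fa


def fit_median_effect(points: DoseResponsePoints, eps: float = FA_EPS) -> MedianEffectFit:
    """Least-squares median-effect fit on linearized coordinates.

    Regresses ``log10(fa/(1-fa))`` on ``log10(D)``; the slope is ``m`` and
    the intercept is ``-m log10(Dm)``. Exact (to machine precision) on
    noise-free Hill data, which is the oracle property the test suite
    leans on.
    """
    d, fa = _usable_points(points, eps)
    if d.size < 3:
        raise InsufficientDataError(
            f"median-effect fit needs >= 3 positive-dose points, got {d.size}"
        )
    y = np.log10(fa / (1.0 - fa))
    x = np.log10(d)
    if np.ptp(y) < 1e-12:
        raise DegenerateFitError("all fa values identical: slope is undefined")
    if np.ptp(x) < 1e-12:
        raise DegenerateFitError("all doses identical: slope is undefined")
    res = stats.linregress(x, y)
    m = res.slope
    if m <= 0:
        raise DegenerateFitError(f"non-positive median-effect slope m={m:.4g}")
    dm = 10.0 ** (-res.intercept / m)
    return MedianEffectFit(
        slope_m=float(m),
        median_dose_dm=float(dm),
        r_squared=float(res.rvalue**2),
        n_points_used=int(d.size),
    )


def _logistic3p(d, top, hill, log_ic50):
    return top / (1.0 + np.exp(hill * (log_ic50 - np.log(d))))


def fit_logistic_3p(points: DoseResponsePoints, max_restarts: int = 5) -> LogisticFit3P:
    """Bounded least-squares 3PL fit with deterministic jittered restarts.

    Initialization: top = max observed fa, ic50 = dose nearest the
    half-maximal response, hill = 1. Up to ``max_restarts`` restarts jitter
    the start point with a fixed-seed generator, keeping the fit
    deterministic. The bottom asymptote is fixed at 0 by convention.
    """
    mask = points.doses > 0
    d = points.doses[mask]
    fa = points.fa[mask]
    if d.size < 4:
        raise InsufficientDataError("3PL fit needs >= 4 positive-dose points")
    if np.max(d) / np.min(d) < 10.0:
        raise InsufficientDataError("3PL fit needs doses spanning at least one decade")

    # a viability-inhibition curve must trend upward with dose; a negative
    # dose-response association cannot be represented with hill > 0
    if stats.pearsonr(np.log(d), fa).statistic < 0:
        raise FitFailureError(
            "response decreases with dose; 3PL with positive hill slope cannot fit",
            diagnostics={"trend": float(stats.pearsonr(np.log(d), fa).statistic)},
        )

    top0 = max(float(np.max(fa)), 0.05)
    half = top0 / 2.0
    ic50_0 = float(d[np.argmin(np.abs(fa - half))])
    logd = np.log(d)
    bounds = ([1e-6, 1e-3, logd.min() - 7.0], [1.05, 20.0, logd.max() + 7.0])
    x0 = np.array([top0, 1.0, np.log(ic50_0)])

    rng = np.random.default_rng(20240117)
    best = None
    n_used = 0
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.7, 1.3, 3)
        start = np.clip(start, bounds[0], bounds[1])
        try:
            sol = optimize.least_squares(
                lambda p: _logistic3p(d, *p) - fa, start, bounds=bounds, method="trf"
            )
        except Exception:  # noqa: BLE001 - optimizer can raise on bad starts
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
            n_used = attempt
        if best is not None and best.cost < 1e-12:
            break
    if best is None or not best.success:
        raise FitFailureError(
            "3PL optimizer failed to converge",
            diagnostics={"n_points": int(d.size), "restarts": max_restarts},
        )
    top, hill, log_ic50 = best.x
    if hill <= bounds[0][1] * (1 + 1e-6):
        raise FitFailureError(
            "hill slope pinned at lower bound: response does not increase with dose",
            diagnostics={"hill": float(hill)},
        )
    return LogisticFit3P(
        top=float(top),
        hill_slope=float(hill),
        ic50=float(np.exp(log_ic50)),
        rss=float(2.0 * best.cost),
        n_restarts=n_used,
    )


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose Dx achieving fractional effect ``fa``: Dx = Dm (fa/(1-fa))^(1/m)."""
    if not 0.0 < fa < 1.0:
        raise DomainError(f"fa must lie strictly inside (0, 1), got {fa}")
    return float(fit.median_dose_dm * (fa / (1.0 - fa)) ** (1.0 / fit.slope_m))


def fit_report(fit) -> dict:
    """Flat key-value report of a fit, ready for CSV/JSON serialization."""
    return {k: getattr(fit, k) for k in fit.__dataclass_fields__}
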