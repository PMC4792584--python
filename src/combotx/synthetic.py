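"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis chain consumes can be generated here: Hill-type
monotherapy curves with multiplicative lognormal noise, two-agent dose
matrices under explicit interaction null/alternative models, negative-
binomial count matrices with planted regulated gene sets, and RPPA-style
log2 fold-change tables with planted outlier proteins.

All stochastic operations take explicit integer seeds; there is no global
random state anywhere in the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .combination import CombinationMatrix
from .errors import ConfigurationError, DomainError
from .gsea import GeneSet

# ---------------------------------------------------------------------------
# Default study conditions
#
# The dose design mirrors a 384-well combination screen: agent A sampled on a
# 10-point two-fold series (dasatinib-like, 0-400 nM) and agent B on a
# 5-point series (CYT387-like, 0-3.5 uM), a 10 x 5 matrix. Hill slopes of 2
# reflect the steep sigmoidal viability curves typical of multi-day
# proliferation assays with kinase inhibitors; Dm sits mid-grid. Plate-reader
# noise is scale-proportional, hence multiplicative lognormal with a 5% CV.
# ---------------------------------------------------------------------------

DOSES_A_DEFAULT = (0.0, 1.5625, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0)
DOSES_B_DEFAULT = (0.0, 0.4375, 0.875, 1.75, 3.5)
DEFAULT_NOISE_CV = 0.05

INTERACTION_MODELS = (
    "bliss_independent",
    "loewe_additive",
    "synergy_potency_shift",
    "antagonism_potency_shift",
)


@dataclass(frozen=True)
class HillModelSpec:
    """Parameters of one agent's median-effect (Hill) curve.

    ``fa(D) = (D/Dm)^m / (1 + (D/Dm)^m)``, so fa(Dm) = 0.5 exactly.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal noise applied to generated fractions (0 = noise-free).
    """

    slope_m: float
    median_dose_dm: float
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.slope_m <= 0 or self.median_dose_dm <= 0:
            raise DomainError("slope_m and median_dose_dm must be positive")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")

    def fa(self, dose):
        """Noise-free fraction affected; exactly 0 at dose 0."""
        dose = np.asarray(dose, dtype=float)
        ratio = np.where(dose > 0, (dose / self.median_dose_dm) ** self.slope_m, 0.0)
        out = ratio / (1.0 + ratio)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class InteractionSpec:
    """How the two agents combine.

    ``bliss_independent`` and ``loewe_additive`` are the two classical null
    models; the potency-shift alternatives multiply each agent's Dm by
    ``shift_factor`` inside the combination (only), so shift < 1 makes the
    combination more potent than independence predicts (synergy) and
    shift > 1 less potent (antagonism).
    """

    model: str = "bliss_independent"
    shift_factor: float = 1.0

    def __post_init__(self):
        if self.model not in INTERACTION_MODELS:
            raise ConfigurationError(
                f"unknown interaction model {self.model!r}; "
                f"expected one of {INTERACTION_MODELS}"
            )
        if self.shift_factor <= 0:
            raise ConfigurationError("shift_factor must be > 0")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def generate_monotherapy(spec: HillModelSpec, doses) -> pd.DataFrame:
    """Simulate a single-agent curve at the given doses.

    Returns a (dose, fraction_affected) table; noisy values are clamped to
    [0, 1] and dose 0 always maps to fa = 0.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise DomainError("doses must be non-negative")
    fa = spec.fa(doses)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        fa = np.clip(fa * _lognormal_noise(rng, spec.noise_cv, doses.shape), 0.0, 1.0)
        fa = np.where(doses == 0, 0.0, fa)
    return pd.DataFrame({"dose": doses, "fraction_affected": fa})


def _loewe_fa(da: float, db: float, spec_a: HillModelSpec, spec_b: HillModelSpec) -> float:
    """Combined effect under Loewe additivity: solve d1/D1(fa) + d2/D2(fa) = 1."""
    if da == 0 and db == 0:
        return 0.0
    if db == 0:
        return float(spec_a.fa(da))
    if da == 0:
        return float(spec_b.fa(db))

    def dx(fa, spec):
        return spec.median_dose_dm * (fa / (1.0 - fa)) ** (1.0 / spec.slope_m)

    def g(fa):
        return da / dx(fa, spec_a) + db / dx(fa, spec_b) - 1.0

    return float(brentq(g, 1e-12, 1.0 - 1e-12, xtol=1e-15, rtol=8.9e-16))


def generate_combination_matrix(
    spec_a: HillModelSpec,
    spec_b: HillModelSpec,
    interaction: InteractionSpec,
    grid_a=DOSES_A_DEFAULT,
    grid_b=DOSES_B_DEFAULT,
) -> CombinationMatrix:
    """Simulate a full dose matrix under the chosen interaction model.

    Row 0 and column 0 carry the (noisy) monotherapies; the noise CV applied
    to the whole matrix is the larger of the two agents' ``noise_cv`` and the
    noise generator is seeded from both agents' seeds. Cell (0, 0) is always
    exactly 0.
    """
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if grid_a[0] != 0 or grid_b[0] != 0:
        raise ConfigurationError("dose grids must include 0 as their first element")

    clean = np.zeros((grid_a.size, grid_b.size))
    model = interaction.model
    if model in ("bliss_independent", "synergy_potency_shift", "antagonism_potency_shift"):
        shift = 1.0 if model == "bliss_independent" else interaction.shift_factor
        shifted_a = HillModelSpec(spec_a.slope_m, shift * spec_a.median_dose_dm)
        shifted_b = HillModelSpec(spec_b.slope_m, shift * spec_b.median_dose_dm)
        fa_a = shifted_a.fa(grid_a)
        fa_b = shifted_b.fa(grid_b)
        clean = fa_a[:, None] + fa_b[None, :] - fa_a[:, None] * fa_b[None, :]
    else:  # loewe_additive
        for i, j in itertools.product(range(grid_a.size), range(grid_b.size)):
            clean[i, j] = _loewe_fa(grid_a[i], grid_b[j], spec_a, spec_b)
    # monotherapy edges always follow the agents' own (unshifted) curves
    clean[:, 0] = spec_a.fa(grid_a)
    clean[0, :] = spec_b.fa(grid_b)
    clean[0, 0] = 0.0

    cv = max(spec_a.noise_cv, spec_b.noise_cv)
    if cv > 0:
        rng = np.random.default_rng([spec_a.seed, spec_b.seed])
        noisy = np.clip(clean * _lognormal_noise(rng, cv, clean.shape), 0.0, 1.0)
        noisy[0, 0] = 0.0
        clean = noisy
    return CombinationMatrix(grid_a, grid_b, clean)


# ---------------------------------------------------------------------------
# Expression counts with planted regulated gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """A gene set regulated in one condition relative to vehicle."""

    name: str
    direction: str  # "up" or "down"
    log2_effect: float
    condition: str = "combination"
    members: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ConfigurationError("direction must be 'up' or 'down'")
        if self.log2_effect < 0:
            raise ConfigurationError("log2_effect must be >= 0 (direction gives sign)")


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Design of a synthetic count matrix.

    Non-planted genes share an expected fold change of 1 between all
    conditions; each planted set's genes carry the specified |log2 fold
    change| in its condition. ``dispersion`` is the negative-binomial
    dispersion (variance = mu + dispersion * mu^2); 0 gives Poisson counts.
    """

    n_genes: int = 2000
    n_samples_per_condition: int = 3
    planted_sets: tuple[PlantedEffect, ...] = ()
    dispersion: float = 0.1
    seed: int = 0
    conditions: tuple[str, ...] = ("vehicle", "combination")
    genes_per_set: int = 30
    mean_log_expression: float = np.log(100.0)
    sd_log_expression: float = 1.0

    def __post_init__(self):
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if "vehicle" not in self.conditions:
            raise ConfigurationError("conditions must include 'vehicle'")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def generate_expression_counts(
    spec: SyntheticExpressionSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a genes x samples count matrix with planted effects.

    Returns ``(counts, sample_conditions, truth)`` where ``truth`` lists
    every planted gene with its set, direction, log2 effect and condition.
    Planted sets are assigned disjoint gene blocks unless explicit members
    are given; overlapping explicit sets raise ``ConfigurationError``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]

    # resolve planted membership
    assigned: dict[str, tuple[str, ...]] = {}
    used: set[str] = set()
    cursor = 0
    for ps in spec.planted_sets:
        if ps.members is not None:
            members = tuple(ps.members)
            if set(members) & used:
                raise ConfigurationError(f"planted set {ps.name!r} overlaps another set")
        else:
            members = tuple(genes[cursor : cursor + spec.genes_per_set])
            cursor += spec.genes_per_set
        if len(set(members) | used) > spec.n_genes:
            raise ConfigurationError("planted sets exceed the gene universe")
        used |= set(members)
        assigned[ps.name] = members
    if len(used) > spec.n_genes:
        raise ConfigurationError("n_genes must cover the total planted-set size")

    base_mu = rng.lognormal(spec.mean_log_expression, spec.sd_log_expression, spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    columns, data = [], []
    for cond in spec.conditions:
        mu = base_mu.copy()
        for ps in spec.planted_sets:
            if ps.condition != cond:
                continue
            sign = 1.0 if ps.direction == "up" else -1.0
            idx = [gene_index[g] for g in assigned[ps.name]]
            mu[idx] = mu[idx] * 2.0 ** (sign * ps.log2_effect)
        for r in range(spec.n_samples_per_condition):
            columns.append(f"{cond}_{r + 1}")
            data.append(_nb_counts(rng, mu, spec.dispersion))
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    conditions = pd.Series(
        {c: c.rsplit("_", 1)[0] for c in columns}, name="condition"
    )

    truth_rows = [
        (g, ps.name, ps.direction, ps.log2_effect, ps.condition)
        for ps in spec.planted_sets
        for g in assigned[ps.name]
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "set", "direction", "log2_effect", "condition"]
    )
    return counts, conditions, truth


def planted_gene_sets(
    spec: SyntheticExpressionSpec,
    truth: pd.DataFrame,
    n_decoys: int = 5,
    decoy_size: int = 30,
    seed: int | None = None,
) -> list[GeneSet]:
    """Planted sets plus random decoy sets drawn from the unplanted genes."""
    sets = [
        GeneSet(name, tuple(grp.gene))
        for name, grp in truth.groupby("set", sort=True)
    ]
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    unplanted = genes[~np.isin(genes, truth.gene.to_numpy() if len(truth) else [])]
    for k in range(n_decoys):
        members = rng.choice(unplanted, size=min(decoy_size, unplanted.size), replace=False)
        sets.append(GeneSet(f"DECOY_{k + 1}", tuple(sorted(members))))
    return sets


# ---------------------------------------------------------------------------
# RPPA-style fold-change tables with planted outliers
# ---------------------------------------------------------------------------

#: background spread of log2 fold changes on a synthetic array
RPPA_BACKGROUND_SD = 0.5
#: residual jitter on planted outlier displacements, as a fraction of the sd
RPPA_OUTLIER_JITTER = 0.1


def generate_rppa_table(
    n_proteins: int,
    n_outliers: int,
    outlier_z: float,
    seed: int,
    cell_lines: tuple[str, ...] = ("ACHN", "SN12C"),
    treatments: tuple[str, ...] = ("dasatinib", "cyt387", "combination"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a proteins x (cell line : treatment) fold-change table.

    Background log2 fold changes are N(0, 0.5). Each planted outlier is
    displaced by ``sign * outlier_z * sd`` in every column (same sign in
    all columns) with a small jitter, so its expected within-array z-score
    reaches ``outlier_z`` in both cell lines. Values are returned as fold
    changes (ratios over vehicle, always > 0); the truth table lists the
    outlier proteins and their directions.
    """
    if n_outliers >= n_proteins:
        raise ConfigurationError("n_outliers must be smaller than n_proteins")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    columns = [f"{cl}:{tr}" for cl in cell_lines for tr in treatments]
    log2fc = rng.normal(0.0, RPPA_BACKGROUND_SD, size=(n_proteins, len(columns)))

    signs = np.where(rng.random(n_outliers) < 0.5, -1.0, 1.0)
    for k in range(n_outliers):
        displacement = signs[k] * outlier_z * RPPA_BACKGROUND_SD
        jitter = rng.normal(0.0, RPPA_OUTLIER_JITTER * RPPA_BACKGROUND_SD, len(columns))
        log2fc[k, :] = displacement + jitter

    table = pd.DataFrame(2.0**log2fc, index=proteins, columns=columns)
    truth = pd.DataFrame(
        {
            "protein": proteins[:n_outliers],
            "direction": np.where(signs > 0, "up", "down"),
            "planted_z": outlier_z,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# Writers (plain-text formats consumed by the pipeline)
# ---------------------------------------------------------------------------


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    """Tab-delimited genes x samples matrix with a header row."""
    counts.to_csv(path, sep="\t", index_label="gene")


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
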