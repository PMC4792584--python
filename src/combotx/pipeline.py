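"""Pipeline orchestration: three independent analysis arms plus simulation.

* **synergy arm** — dose-matrix CSVs -> median-effect and 3PL fits on the
  monotherapy edges, Bliss score matrix and Bliss sum, per-cell
  combination indices and a synergy verdict per matrix;
* **transcriptome arm** — count matrix -> low-count filter, upper-quartile
  normalization, per-treatment fold changes vs vehicle, 1.5-fold ranked
  lists (RNK) and preranked GSEA tables with FDR q < 0.25 flags;
* **protein arm** — RPPA fold-change table -> within-array z-scores and
  the |z| > 1.96 both-cell-lines selection.

Every run writes a manifest (config snapshot, seed, package version,
input/output checksums) sufficient to verify a byte-identical rerun. Arms
never read each other's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combination import (
    FA_WINDOW,
    CombinationMatrix,
    bliss_score_matrix,
    combination_index,
)
from .dose_response import (
    DoseResponsePoints,
    fit_logistic_3p,
    fit_median_effect,
)
from .errors import CombotxError, ConfigurationError, InputError, NoOverlapError
from .expression import (
    DEFAULT_MIN_FOLD,
    DEFAULT_MIN_TOTAL,
    DEFAULT_PSEUDOCOUNT,
    CountMatrix,
    filter_low_counts,
    fold_change_vs_reference,
    threshold_and_rank,
    upper_quartile_normalize,
    write_normalized_tsv,
)
from .gsea import FDR_SIGNIFICANCE, preranked_gsea, read_gmt, results_table
from .rppa import (
    DEFAULT_Z_CUTOFF,
    FoldChangeTable,
    ZScoreSelection,
    compute_zscores,
    long_format,
    select_proteins,
)
from .synthetic import (
    DEFAULT_NOISE_CV,
    DOSES_A_DEFAULT,
    HillModelSpec,
    InteractionSpec,
    PlantedEffect,
    SyntheticExpressionSpec,
    generate_combination_matrix,
    generate_expression_counts,
    generate_rppa_table,
    planted_gene_sets,
    write_counts_tsv,
)
from .gsea import write_gmt

logger = logging.getLogger("combotx")


# ---------------------------------------------------------------------------
# Configuration
#
# Defaults are the study's printed analysis parameters: low-count filter at
# 5 total counts, 1.5-fold regulation threshold, z cutoff +-1.96, CI summary
# window FA 0.2-0.9, 1000 permutations, FDR significance 0.25.
# ---------------------------------------------------------------------------


@dataclass
class SynergyConfig:
    matrices: list[str] = field(default_factory=list)
    fa_window: tuple[float, float] = FA_WINDOW
    percent_scale: bool = False


@dataclass
class TranscriptomeConfig:
    counts: str | None = None
    gene_sets: str | None = None
    conditions: dict | None = None  # sample -> condition; inferred if omitted
    reference: str = "vehicle"
    min_total: int = DEFAULT_MIN_TOTAL
    min_fold: float = DEFAULT_MIN_FOLD
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    n_perm: int = 1000
    fdr_cutoff: float = FDR_SIGNIFICANCE


@dataclass
class ProteinConfig:
    table: str | None = None
    required_columns: list[str] = field(default_factory=list)
    z_cutoff: float = DEFAULT_Z_CUTOFF


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "combotx_out"
    synergy: SynergyConfig = field(default_factory=SynergyConfig)
    transcriptome: TranscriptomeConfig = field(default_factory=TranscriptomeConfig)
    protein: ProteinConfig = field(default_factory=ProteinConfig)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "combotx_out")),
            synergy=SynergyConfig(**raw.get("synergy", {})),
            transcriptome=TranscriptomeConfig(**raw.get("transcriptome", {})),
            protein=ProteinConfig(**raw.get("protein", {})),
        )
        cfg.synergy.fa_window = tuple(cfg.synergy.fa_window)
        if base_dir is not None:
            cfg._resolve_paths(Path(base_dir))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except OSError as exc:
            raise InputError(f"cannot read config file {path}: {exc}") from exc
        return cls.from_dict(raw, base_dir=path.parent)

    def _resolve_paths(self, base: Path) -> None:
        def resolve(p):
            return str((base / p).resolve()) if p and not Path(p).is_absolute() else p

        self.synergy.matrices = [resolve(m) for m in self.synergy.matrices]
        self.transcriptome.counts = resolve(self.transcriptome.counts)
        self.transcriptome.gene_sets = resolve(self.transcriptome.gene_sets)
        self.protein.table = resolve(self.protein.table)
        if not Path(self.output_dir).is_absolute():
            self.output_dir = str((base / self.output_dir).resolve())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synergy"]["fa_window"] = list(self.synergy.fa_window)
        return d


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run and verify its outputs."""

    config: dict
    seed: int
    package_version: str
    inputs: dict
    outputs: dict
    created: str

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _build_manifest(config: PipelineConfig, inputs: list[str], out_dir: Path) -> RunManifest:
    output_files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "run_manifest.json"
    )
    return RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        package_version=__version__,
        inputs={str(p): _sha256(Path(p)) for p in inputs if p},
        outputs={str(p.relative_to(out_dir)): _sha256(p) for p in output_files},
        created=datetime.now(timezone.utc).isoformat(),
    )


def rerun_from_manifest(manifest: RunManifest, out_dir) -> RunManifest:
    """Re-execute the run a manifest describes, writing into ``out_dir``.

    Returns the new manifest; output checksums matching the original's
    verify byte-identical reproduction.
    """
    config = PipelineConfig.from_dict(manifest.config)
    config.output_dir = str(out_dir)
    return run_all(config)


# ---------------------------------------------------------------------------
# Arms
# ---------------------------------------------------------------------------


def run_synergy_arm(config: PipelineConfig, out_dir: Path | None = None) -> pd.DataFrame:
    """Bliss + CI reports for every configured dose matrix."""
    out = Path(out_dir or Path(config.output_dir) / "synergy")
    out.mkdir(parents=True, exist_ok=True)
    if not config.synergy.matrices:
        raise ConfigurationError("synergy arm: no dose matrices configured")
    rows = []
    for mpath in config.synergy.matrices:
        mpath = Path(mpath)
        if not mpath.exists():
            raise InputError(f"dose matrix not found: {mpath}")
        matrix = CombinationMatrix.from_csv(mpath)
        stem = mpath.stem

        fit_a = fit_median_effect(
            DoseResponsePoints(matrix.doses_a, matrix.monotherapy_a)
        )
        fit_b = fit_median_effect(
            DoseResponsePoints(matrix.doses_b, matrix.monotherapy_b)
        )
        ic50_a = _try_ic50(matrix.doses_a, matrix.monotherapy_a)

        bliss = bliss_score_matrix(matrix)
        ci = combination_index(matrix, fit_a, fit_b, config.synergy.fa_window)

        bliss.scores_frame(percent=config.synergy.percent_scale).to_csv(
            out / f"{stem}_bliss_scores.csv", index_label="dose_a\\dose_b"
        )
        ci.entries.to_csv(out / f"{stem}_ci.csv", index=False)
        bliss_sum = (
            bliss.bliss_sum_percent() if config.synergy.percent_scale else bliss.bliss_sum
        )
        rows.append(
            {
                "matrix": stem,
                "bliss_sum": bliss_sum,
                "median_ci": ci.median_ci,
                "verdict": ci.verdict,
                "n_ci_cells": len(ci.entries),
                "n_ci_excluded": ci.n_excluded,
                "m_a": fit_a.slope_m,
                "dm_a": fit_a.median_dose_dm,
                "r2_a": fit_a.r_squared,
                "m_b": fit_b.slope_m,
                "dm_b": fit_b.median_dose_dm,
                "r2_b": fit_b.r_squared,
                "ic50_a": ic50_a,
            }
        )
        logger.info(
            "synergy %s: bliss_sum=%.4f median_ci=%.3f verdict=%s (%d CI cells, %d excluded)",
            stem, bliss_sum, ci.median_ci, ci.verdict, len(ci.entries), ci.n_excluded,
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "synergy_summary.csv", index=False)
    return summary


def _try_ic50(doses, fa) -> float:
    try:
        return fit_logistic_3p(DoseResponsePoints(doses, fa)).ic50
    except CombotxError:
        return float("nan")


def run_transcriptome_arm(
    config: PipelineConfig, out_dir: Path | None = None
) -> dict[str, pd.DataFrame]:
    """Normalization, ranked lists and GSEA tables, one per non-vehicle treatment."""
    tc = config.transcriptome
    out = Path(out_dir or Path(config.output_dir) / "transcriptome")
    out.mkdir(parents=True, exist_ok=True)
    if tc.counts is None:
        raise ConfigurationError("transcriptome arm: no count matrix configured")
    cpath = Path(tc.counts)
    if not cpath.exists():
        raise InputError(f"count matrix not found: {cpath}")
    matrix = CountMatrix.from_tsv(cpath, conditions=tc.conditions)
    if tc.reference not in set(matrix.conditions):
        raise ConfigurationError(
            f"reference condition {tc.reference!r} missing from the count matrix"
        )
    n_before = matrix.counts.shape[0]
    filtered = filter_low_counts(matrix, tc.min_total)
    logger.info(
        "transcriptome: %d/%d genes retained after low-count filter (< %d total)",
        filtered.counts.shape[0], n_before, tc.min_total,
    )
    norm = upper_quartile_normalize(filtered)
    write_normalized_tsv(norm, out / "normalized.tsv")

    sets = read_gmt(tc.gene_sets) if tc.gene_sets else []
    tables = {}
    treatments = [c for c in dict.fromkeys(matrix.conditions) if c != tc.reference]
    if not treatments:
        raise ConfigurationError("transcriptome arm: only the reference condition present")
    for treatment in treatments:
        fc = fold_change_vs_reference(norm, treatment, tc.reference, tc.pseudocount)
        ranked = threshold_and_rank(fc, tc.min_fold)
        ranked.to_rnk(out / f"{treatment}.rnk")
        logger.info(
            "transcriptome %s: %d regulated genes (>= %.2g-fold)",
            treatment, len(ranked), tc.min_fold,
        )
        if sets and len(ranked):
            try:
                results = preranked_gsea(
                    ranked, sets, n_perm=tc.n_perm, seed=config.seed
                )
            except NoOverlapError:
                logger.warning(
                    "transcriptome %s: no gene set overlaps the %d regulated genes; "
                    "GSEA skipped", treatment, len(ranked),
                )
                continue
            table = results_table(results, tc.fdr_cutoff)
            table.to_csv(out / f"gsea_{treatment}.tsv", sep="\t", index=False)
            tables[treatment] = table
    return tables


def run_protein_arm(
    config: PipelineConfig, out_dir: Path | None = None
) -> tuple[ZScoreSelection, list[str]]:
    """Z-score table, selection and heatmap-ready export for the RPPA arm."""
    pc = config.protein
    out = Path(out_dir or Path(config.output_dir) / "protein")
    out.mkdir(parents=True, exist_ok=True)
    if pc.table is None:
        raise ConfigurationError("protein arm: no fold-change table configured")
    tpath = Path(pc.table)
    if not tpath.exists():
        raise InputError(f"fold-change table not found: {tpath}")
    table = FoldChangeTable.from_csv(tpath)
    required = pc.required_columns or list(table.values.columns)
    cell_lines = {c.split(":")[0] for c in required}
    if len(cell_lines) < 2:
        raise ConfigurationError(
            "the both-cell-lines selection rule needs required columns from "
            f"at least two cell lines, got {sorted(cell_lines)}"
        )
    selection = compute_zscores(table)
    selected = select_proteins(selection, required, pc.z_cutoff)
    selection.z.to_csv(out / "zscores.csv", index_label="protein")
    (out / "selected_proteins.txt").write_text("".join(p + "\n" for p in selected))
    long_format(selection, table).to_csv(out / "long_format.csv", index=False)
    logger.info(
        "protein: %d/%d proteins selected at |z| > %.3g in %s",
        len(selected), table.values.shape[0], pc.z_cutoff, required,
    )
    return ZScoreSelection(selection.z, pc.z_cutoff, tuple(selected)), selected


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every configured arm and write the manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: list[str] = []
    if config.synergy.matrices:
        run_synergy_arm(config)
        inputs += config.synergy.matrices
    if config.transcriptome.counts:
        run_transcriptome_arm(config)
        inputs.append(config.transcriptome.counts)
        if config.transcriptome.gene_sets:
            inputs.append(config.transcriptome.gene_sets)
    if config.protein.table:
        run_protein_arm(config)
        inputs.append(config.protein.table)
    manifest = _build_manifest(config, inputs, out_dir)
    manifest.write(out_dir / "run_manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Synthetic bundle
# ---------------------------------------------------------------------------


def simulate_bundle(out_dir, seed: int = 0) -> PipelineConfig:
    """Write a complete synthetic input bundle plus a ready-to-run config.

    The bundle holds four dose matrices (Bliss-independent null, sham
    Loewe-additive self-combination, synergy at potency shift 0.5,
    antagonism at shift 2), a count matrix with one gene set up-regulated
    2-fold in the combination condition only, matching GMT gene sets, and
    an RPPA table with three planted outlier proteins.
    """
    out = Path(out_dir).resolve()
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    (out / "expression").mkdir(exist_ok=True)
    (out / "rppa").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=8)

    def spec_a(s, cv=DEFAULT_NOISE_CV):
        return HillModelSpec(2.0, 50.0, cv, int(s))

    def spec_b(s, cv=DEFAULT_NOISE_CV):
        return HillModelSpec(2.0, 0.875, cv, int(s))

    matrices = {
        "bliss_null": (spec_a(sub[0]), spec_b(sub[1]), InteractionSpec("bliss_independent")),
        "synergy": (
            spec_a(sub[2]), spec_b(sub[3]), InteractionSpec("synergy_potency_shift", 0.5)
        ),
        "antagonism": (
            spec_a(sub[4]), spec_b(sub[5]), InteractionSpec("antagonism_potency_shift", 2.0)
        ),
    }
    matrix_paths = []
    for name, (sa, sb, inter) in matrices.items():
        m = generate_combination_matrix(sa, sb, inter)
        path = out / "matrices" / f"{name}.csv"
        m.to_csv(path)
        matrix_paths.append(str(path))
    # sham: an agent combined with itself under Loewe additivity (noise-free)
    sham_spec = HillModelSpec(2.0, 50.0, 0.0, 0)
    sham = generate_combination_matrix(
        sham_spec, sham_spec, InteractionSpec("loewe_additive"),
        DOSES_A_DEFAULT, DOSES_A_DEFAULT,
    )
    sham_path = out / "matrices" / "sham_additive.csv"
    sham.to_csv(sham_path)
    matrix_paths.append(str(sham_path))

    expr_spec = SyntheticExpressionSpec(
        n_genes=2000,
        n_samples_per_condition=3,
        planted_sets=(PlantedEffect("YAP1_SIGNATURE_UP", "up", 1.0, "combination"),),
        dispersion=0.1,
        seed=int(sub[6]),
        conditions=("vehicle", "dasatinib", "cyt387", "combination"),
    )
    counts, _conditions, truth = generate_expression_counts(expr_spec)
    write_counts_tsv(counts, out / "expression" / "counts.tsv")
    truth.to_csv(out / "expression" / "truth.csv", index=False)
    write_gmt(
        planted_gene_sets(expr_spec, truth, n_decoys=5, decoy_size=30),
        out / "expression" / "gene_sets.gmt",
    )

    rppa_table, rppa_truth = generate_rppa_table(
        n_proteins=200, n_outliers=3, outlier_z=3.0, seed=int(sub[7])
    )
    FoldChangeTable(rppa_table).to_csv(out / "rppa" / "fold_changes.csv")
    rppa_truth.to_csv(out / "rppa" / "truth.csv", index=False)

    config = PipelineConfig(
        seed=seed,
        output_dir=str(out / "results"),
        synergy=SynergyConfig(matrices=matrix_paths),
        transcriptome=TranscriptomeConfig(
            counts=str(out / "expression" / "counts.tsv"),
            gene_sets=str(out / "expression" / "gene_sets.gmt"),
        ),
        protein=ProteinConfig(
            table=str(out / "rppa" / "fold_changes.csv"),
            required_columns=["ACHN:combination", "SN12C:combination"],
        ),
    )
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return config
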