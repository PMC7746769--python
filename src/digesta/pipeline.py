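"""Orchestration of the three clustering analyses from a single run config.

``run_proteomic_analysis`` takes per-replicate ion tables through the
filter → blank-subtraction → benchmark-matching → characteristics →
standardize → model-selection chain. ``run_biological_analysis`` screens the
read-out table for outliers, averages replicates, and clusters the seven
assay variables, also emitting the benchmark-comparison test table.
``run_combined_analysis`` joins four proteomic characteristics with the
seven biological variables (an intentional 7:4 ≈ 2:1 weighting of biology
over proteomics in the standardized feature space) and clusters the joined
matrix.

Every analysis writes CSV/JSON outputs plus a provenance record (config
echo, package version, seed, input checksums) when an output directory is
configured, and is byte-deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bio_stats import compare_to_benchmark, screen_outliers
from .digest_features import FEATURE_NAMES, SizeClassRule, compute_features, export_overlap_tables
from .ion_io import BIO_VARIABLES, BioReadoutTable, IonTable, read_bio_table, read_ion_table
from .mixtures import (
    FAMILY_CODES,
    FeatureMatrix,
    ModelSelection,
    build_feature_matrix,
    select_model,
    standardize,
    two_component_plot_data,
)
from .peak_matching import (
    DEFAULT_ABUNDANCE_THRESHOLD,
    MatchTolerances,
    MatchingPipelineResult,
    run_matching_pipeline,
)

logger = logging.getLogger(__name__)

#: Feature presets. The proteomic clustering uses five characteristics:
#: frac_oligo is omitted because it is exactly 1 − frac_ditri, and a pair of
#: perfectly anticorrelated columns double-counts one dimension of evidence
#: under the diagonal covariance families (and is singular under the full
#: ones). Both fractions are still computed and exported. The combined
#: clustering uses the four benchmark-relative characteristics.
PROTEOMIC_FEATURES = (
    "frac_ditri", "total_abundance", "n_unique", "pct_overlap", "pct_abundance_overlap",
)
COMBINED_PROTEOMIC_FEATURES = (
    "total_abundance", "n_unique", "pct_overlap", "pct_abundance_overlap",
)
BIOLOGICAL_FEATURES = BIO_VARIABLES


@dataclass
class ClusteringConfig:
    families: tuple = FAMILY_CODES
    k_min: int = 1
    k_max: int = 9
    n_restarts: int = 10
    seed: int = 0

    def k_range(self, n_rows: int) -> range:
        return range(self.k_min, min(self.k_max, n_rows - 1) + 1)


@dataclass
class RunConfig:
    """Everything needed to run the full analysis from files on disk."""

    ion_tables: list = field(default_factory=list)  # dicts: path, source_id, replicate_id
    bio_table: str | None = None
    benchmark_source: str = "WPC"
    blank_source: str = "Blank"
    mz_tol: float = 0.003
    rt_tol: float = 0.5
    abundance_threshold: float = DEFAULT_ABUNDANCE_THRESHOLD
    ditri_max_neutral_mass: float = 425.0
    include_benchmark_row: bool = True
    grubbs_alpha: float = 0.05
    proteomic_features: tuple = PROTEOMIC_FEATURES
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    ion_columns: dict | None = None
    rt_in_seconds: bool = False
    output_dir: str | None = None

    @property
    def tolerances(self) -> MatchTolerances:
        return MatchTolerances(mz_tol=self.mz_tol, rt_tol=self.rt_tol)

    @property
    def size_rule(self) -> SizeClassRule:
        return SizeClassRule(ditri_max_neutral_mass=self.ditri_max_neutral_mass)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cluster_raw = raw.pop("clustering", {})
        cfg = cls(**raw)
        cfg.clustering = ClusteringConfig(**{
            k: tuple(v) if k == "families" else v for k, v in cluster_raw.items()
        })
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["proteomic_features"] = list(self.proteomic_features)
        out["clustering"]["families"] = list(self.clustering.families)
        return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(cfg: RunConfig, outdir: Path, stage: str, inputs: list) -> None:
    record = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.clustering.seed,
        "config": cfg.to_dict(),
        "input_checksums": {str(p): _sha256(p) for p in inputs},
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=1, default=str)


def load_ion_tables(cfg: RunConfig) -> tuple[list[IonTable], IonTable, IonTable]:
    """Load digest tables plus pooled blank and benchmark references.

    Benchmark and blank replicates are pooled (ion union, ids prefixed by
    replicate) into single reference tables; digests stay per replicate.
    """
    digests, blank_parts, bench_parts = [], [], []
    for entry in cfg.ion_tables:
        table = read_ion_table(
            entry["path"], entry["source_id"], entry["replicate_id"],
            columns=cfg.ion_columns, rt_in_seconds=cfg.rt_in_seconds,
        )
        if table.source_id == cfg.blank_source:
            blank_parts.append(table)
        elif table.source_id == cfg.benchmark_source:
            bench_parts.append(table)
        else:
            digests.append(table)
    if not bench_parts:
        raise ValueError(f"benchmark source {cfg.benchmark_source!r} absent from ion tables")
    blank = _pool(blank_parts, cfg.blank_source) if blank_parts else IonTable(cfg.blank_source, "pooled", ())
    benchmark = _pool(bench_parts, cfg.benchmark_source)
    return digests, blank, benchmark


def _pool(tables: list[IonTable], source_id: str) -> IonTable:
    if len(tables) == 1:
        return tables[0]
    ions = []
    for t in tables:
        for ion in t:
            ions.append(dataclasses.replace(ion, ion_id=f"{t.replicate_id}:{ion.ion_id}"))
    return IonTable(source_id=source_id, replicate_id="pooled", ions=tuple(ions))


@dataclass
class ProteomicResult:
    features: pd.DataFrame          # long: source_id, replicate_id, feature, value
    audits: pd.DataFrame
    matrix: FeatureMatrix           # standardized
    selection: ModelSelection
    assignments: pd.DataFrame
    matching: MatchingPipelineResult


def proteomic_features_from_matching(
    matching: MatchingPipelineResult, rule: SizeClassRule
) -> pd.DataFrame:
    rows = []
    for (src, rep), record in matching.records.items():
        feats = compute_features(record.table, record.match, rule)
        for name, value in feats.to_dict().items():
            rows.append({"source_id": src, "replicate_id": rep, "feature": name, "value": value})
    return pd.DataFrame(rows)


def _cluster(matrix_raw: FeatureMatrix, cfg: RunConfig):
    matrix = standardize(matrix_raw)
    cc = cfg.clustering
    selection = select_model(
        matrix, families=cc.families, k_range=cc.k_range(len(matrix.sources)),
        n_restarts=cc.n_restarts, seed=cc.seed,
    )
    assignments = pd.DataFrame({
        "source_id": matrix.sources,
        "cluster": selection.best.assignments + 1,
    })
    return matrix, selection, assignments


def _write_cluster_outputs(outdir: Path, matrix, selection, assignments):
    matrix.frame.to_csv(outdir / "feature_matrix.csv")
    selection.table.to_csv(outdir / "model_selection.csv", index=False)
    selection.to_json(outdir / "best_model.json")
    assignments.to_csv(outdir / "assignments.csv", index=False)
    pairs_dir = outdir / "pairs"
    pairs_dir.mkdir(exist_ok=True)
    for (fi, fj), frame in two_component_plot_data(matrix, selection).items():
        frame.to_csv(pairs_dir / f"{fi}__{fj}.csv", index=False)


def run_proteomic_analysis(
    cfg: RunConfig,
    digests: list[IonTable] | None = None,
    blank: IonTable | None = None,
    benchmark: IonTable | None = None,
) -> ProteomicResult:
    """Full proteomic chain: filter, subtract, match, characterize, cluster.

    Tables may be passed in memory (synthetic runs) or loaded from the
    config's paths. The benchmark participates as a data row (its own
    100%-overlap corner) unless ``include_benchmark_row`` is off; the blank
    is never a row here — it is the subtraction reference.
    """
    inputs = []
    if digests is None:
        digests, blank, benchmark = load_ion_tables(cfg)
        inputs = [e["path"] for e in cfg.ion_tables]
    if cfg.include_benchmark_row:
        digests = list(digests) + [dataclasses.replace(
            benchmark,
            ions=tuple(dataclasses.replace(i, ion_id=f"self:{i.ion_id}") for i in benchmark),
        )]
    matching = run_matching_pipeline(
        digests, blank, benchmark, tol=cfg.tolerances, threshold=cfg.abundance_threshold,
    )
    features = proteomic_features_from_matching(matching, cfg.size_rule)
    audits = pd.DataFrame([
        {"source_id": src, "replicate_id": rep, **record.audit.to_dict()}
        for (src, rep), record in matching.records.items()
    ])
    matrix_raw = build_feature_matrix(features, cfg.proteomic_features)
    matrix, selection, assignments = _cluster(matrix_raw, cfg)

    if cfg.output_dir:
        outdir = Path(cfg.output_dir) / "proteomic"
        outdir.mkdir(parents=True, exist_ok=True)
        features.to_csv(outdir / "features.csv", index=False)
        audits.to_csv(outdir / "audits.csv", index=False)
        _write_cluster_outputs(outdir, matrix, selection, assignments)
        overlap_dir = outdir / "overlap"
        overlap_dir.mkdir(exist_ok=True)
        for (src, rep), record in matching.records.items():
            tile, comparison = export_overlap_tables(
                record.match, record.table, matching.benchmark, cfg.size_rule)
            tile.to_csv(overlap_dir / f"{src}_{rep}_tiles.csv", index=False)
            comparison.to_csv(overlap_dir / f"{src}_{rep}_abundance.csv", index=False)
        _write_provenance(cfg, outdir, "proteomic", inputs)
    return ProteomicResult(features, audits, matrix, selection, assignments, matching)


@dataclass
class BiologicalResult:
    cleaned: BioReadoutTable
    outlier_flags: pd.DataFrame
    tests: pd.DataFrame
    anova: pd.DataFrame
    matrix: FeatureMatrix
    selection: ModelSelection
    assignments: pd.DataFrame


def run_biological_analysis(cfg: RunConfig, bio: BioReadoutTable | None = None) -> BiologicalResult:
    """Grubbs screening → replicate means → standardize → model selection.

    The blank digest participates as an ordinary sample row here. The
    benchmark-comparison t-test/ANOVA table is emitted alongside.
    """
    inputs = []
    if bio is None:
        if not cfg.bio_table:
            raise ValueError("no biological read-out table configured")
        bio = read_bio_table(cfg.bio_table)
        inputs = [cfg.bio_table]
    cleaned, flags = screen_outliers(bio, alpha=cfg.grubbs_alpha)
    comparison = compare_to_benchmark(cleaned, cfg.benchmark_source, alpha=cfg.grubbs_alpha) \
        if cfg.benchmark_source in cleaned.sources else None

    records = cleaned.data.rename(columns={"variable": "feature"})
    matrix_raw = build_feature_matrix(records, cleaned.variables)
    matrix, selection, assignments = _cluster(matrix_raw, cfg)

    if cfg.output_dir:
        outdir = Path(cfg.output_dir) / "biological"
        outdir.mkdir(parents=True, exist_ok=True)
        cleaned.data.to_csv(outdir / "cleaned_bio_table.csv", index=False)
        flags.to_csv(outdir / "outlier_flags.csv", index=False)
        if comparison is not None:
            comparison.t_tests.to_csv(outdir / "benchmark_t_tests.csv", index=False)
            comparison.anova.to_csv(outdir / "anova.csv", index=False)
        _write_cluster_outputs(outdir, matrix, selection, assignments)
        _write_provenance(cfg, outdir, "biological", inputs)
    return BiologicalResult(
        cleaned, flags,
        comparison.t_tests if comparison else pd.DataFrame(),
        comparison.anova if comparison else pd.DataFrame(),
        matrix, selection, assignments,
    )


@dataclass
class CombinedResult:
    matrix: FeatureMatrix
    selection: ModelSelection
    assignments: pd.DataFrame


def run_combined_analysis(
    cfg: RunConfig,
    proteomic: ProteomicResult,
    biological: BiologicalResult,
) -> CombinedResult:
    """Join proteomic and biological features by source and cluster jointly.

    Four proteomic characteristics meet the seven biological variables
    (11 columns); sources present on only one side are dropped with a
    warning, and an empty intersection is an error. Standardization is
    applied jointly on the joined matrix.
    """
    prot = build_feature_matrix(proteomic.features, COMBINED_PROTEOMIC_FEATURES).frame
    bio_raw = build_feature_matrix(
        biological.cleaned.data.rename(columns={"variable": "feature"}),
        biological.cleaned.variables,
    ).frame

    shared = [s for s in prot.index if s in bio_raw.index]
    dropped = sorted(set(prot.index).symmetric_difference(bio_raw.index))
    if not shared:
        raise ValueError("no sources shared between proteomic and biological feature tables")
    if dropped:
        logger.warning("sources missing from one side dropped from combined analysis: %s", dropped)
    joined = prot.loc[shared].join(bio_raw.loc[shared])
    matrix_raw = FeatureMatrix(frame=joined, standardized=False)
    matrix, selection, assignments = _cluster(matrix_raw, cfg)

    if cfg.output_dir:
        outdir = Path(cfg.output_dir) / "combined"
        outdir.mkdir(parents=True, exist_ok=True)
        _write_cluster_outputs(outdir, matrix, selection, assignments)
        _write_provenance(cfg, outdir, "combined", [])
    return CombinedResult(matrix, selection, assignments)


@dataclass
class StudyResult:
    proteomic: ProteomicResult
    biological: BiologicalResult
    combined: CombinedResult


def run_all(
    cfg: RunConfig,
    digests=None, blank=None, benchmark=None, bio=None,
) -> StudyResult:
    """Run the proteomic, biological, and combined analyses in order."""
    proteomic = run_proteomic_analysis(cfg, digests=digests, blank=blank, benchmark=benchmark)
    biological = run_biological_analysis(cfg, bio=bio)
    combined = run_combined_analysis(cfg, proteomic, biological)
    return StudyResult(proteomic, biological, combined)
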