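"""Seeded generators for ion tables and biological read-outs with known ground truth.

The generators emulate the structure of an in vitro digestion LC-MS study:
a benchmark ion table; digest tables sharing a controlled fraction of the
benchmark's ions (perturbed by sub-tolerance m/z and RT jitter) plus unique
ions; an enzyme-only blank table whose ions can contaminate digests; raw
abundances drawn log-normally so that a tunable share of peaks falls below
the noise-filter threshold; and a biological read-out table with planted
multivariate-Gaussian cluster structure and optional injected outliers.

Ground truth is unambiguous by construction: benchmark, blank, and unique
digest ions are mutually separated by more than twice the tolerance radius
in the weighted (m/z, RT) metric, so a planted overlap ion has exactly one
admissible reference. All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .ion_io import BIO_VARIABLES, BioReadoutTable, IonTable, PeptideIon
from .peak_matching import MatchTolerances, eq1_distance

import pandas as pd


@dataclass(frozen=True)
class IonTableSimConfig:
    """Parameters of the ion-table generators.

    m/z and RT ranges default to the acquisition windows of a 40-minute
    run scanning 70–1200 Th. Abundances are log-normal with the location
    chosen so that ``abundance_below_threshold_frac`` of the mass lies
    below ``abundance_threshold``, keeping the noise filter exercised.
    Jitter SDs default to 0.0008 Th / 0.1 min, small enough that over 99%
    of planted overlaps stay inside the ±0.003 Th / ±0.5 min tolerance.
    """

    seed: int = 0
    n_benchmark_ions: int = 1000
    n_digest_ions: int = 800
    n_blank_ions: int = 150
    mz_range: tuple = (70.0, 1200.0)
    rt_range: tuple = (0.0, 40.0)
    charge_values: tuple = (1, 2, 3)
    charge_probs: tuple = (0.3, 0.5, 0.2)
    abundance_threshold: float = 1e5
    abundance_below_threshold_frac: float = 0.25
    abundance_sigma: float = 1.0
    overlap_fraction: float = 0.5
    mz_jitter_sd: float = 0.0008
    rt_jitter_sd: float = 0.1
    blank_contamination_fraction: float = 0.05
    tolerances: MatchTolerances = field(default_factory=MatchTolerances)

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.in_tolerance_probability() < 0.99:
            raise ValueError(
                "jitter SDs too large: planted overlaps would leave the matching "
                f"tolerance with probability {1 - self.in_tolerance_probability():.3g} > 1%"
            )

    def in_tolerance_probability(self) -> float:
        """Probability a jittered copy stays inside the tolerance box."""
        tol = self.tolerances
        p_mz = (
            1.0 if self.mz_jitter_sd == 0
            else 2 * stats.norm.cdf(tol.mz_tol / self.mz_jitter_sd) - 1
        )
        p_rt = (
            1.0 if self.rt_jitter_sd == 0
            else 2 * stats.norm.cdf(tol.rt_tol / self.rt_jitter_sd) - 1
        )
        return p_mz * p_rt

    def abundance_log_mean(self) -> float:
        q = stats.norm.ppf(self.abundance_below_threshold_frac)
        return math.log(self.abundance_threshold) - self.abundance_sigma * q

    def separation(self) -> float:
        """Minimum same-charge distance between landmark ions (2× tolerance radius)."""
        tol = self.tolerances
        return 2.0 * eq1_distance(tol.mz_tol, tol.rt_tol, tol)


class _LandmarkRegistry:
    """Per-charge positions with a minimum weighted-distance separation rule."""

    def __init__(self, cfg: IonTableSimConfig):
        self.cfg = cfg
        self.sep = cfg.separation()
        self.weight = cfg.tolerances.weight
        self.points = {z: [] for z in cfg.charge_values}  # charge -> [(mz, rt)]

    def _clear(self, mz: float, rt: float, charge: int) -> bool:
        pts = self.points[charge]
        if not pts:
            return True
        arr = np.asarray(pts)
        d = np.hypot((arr[:, 0] - mz) * self.weight, arr[:, 1] - rt)
        return bool(d.min() > self.sep)

    def place(self, n: int, rng: np.random.Generator, register: bool = True):
        """Rejection-sample n separated positions; returns (mz, rt, charge) arrays."""
        cfg = self.cfg
        out_mz, out_rt, out_z = [], [], []
        attempts = 0
        max_attempts = 200 * max(n, 1)
        while len(out_mz) < n:
            if attempts > max_attempts:
                raise ValueError(
                    f"cannot place {n} ions at separation {self.sep:.3g} within the "
                    "configured m/z-RT window; requested density is too high"
                )
            attempts += 1
            mz = rng.uniform(*cfg.mz_range)
            rt = rng.uniform(*cfg.rt_range)
            z = int(rng.choice(cfg.charge_values, p=cfg.charge_probs))
            if self._clear(mz, rt, z):
                out_mz.append(mz)
                out_rt.append(rt)
                out_z.append(z)
                if register:
                    self.points[z].append((mz, rt))
        return np.array(out_mz), np.array(out_rt), np.array(out_z)

    def register_table(self, table: IonTable) -> None:
        for ion in table:
            self.points.setdefault(ion.charge, []).append((ion.mz, ion.rt))


def _abundances(cfg: IonTableSimConfig, n: int, rng: np.random.Generator, scale: float = 1.0):
    return scale * rng.lognormal(cfg.abundance_log_mean(), cfg.abundance_sigma, size=n)


def _abundances_above_threshold(cfg: IonTableSimConfig, n: int, rng: np.random.Generator):
    """Log-normal draws truncated above the noise threshold (inverse-CDF).

    Used for benchmark and blank tables: those serve as the matching
    reference and subtraction background, so their ion lists must be stable
    under the abundance filter for planted ground truth to be identifiable.
    """
    q = cfg.abundance_below_threshold_frac
    u = rng.uniform(q, 1.0, size=n)
    return np.exp(cfg.abundance_log_mean() + cfg.abundance_sigma * stats.norm.ppf(u))


def simulate_benchmark(
    cfg: IonTableSimConfig,
    source_id: str = "WPC",
    replicate_id: str = "pooled",
    registry: _LandmarkRegistry | None = None,
    seed: int | None = None,
) -> IonTable:
    """Generate the benchmark ion table with mutually separated ions."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    registry = registry if registry is not None else _LandmarkRegistry(cfg)
    mz, rt, z = registry.place(cfg.n_benchmark_ions, rng)
    abundance = _abundances_above_threshold(cfg, cfg.n_benchmark_ions, rng)
    ions = [
        PeptideIon(f"ref_{i:05d}", float(mz[i]), int(z[i]), float(rt[i]), float(abundance[i]))
        for i in range(cfg.n_benchmark_ions)
    ]
    return IonTable(source_id=source_id, replicate_id=replicate_id, ions=tuple(ions))


def simulate_blank(
    cfg: IonTableSimConfig,
    source_id: str = "Blank",
    replicate_id: str = "pooled",
    registry: _LandmarkRegistry | None = None,
    seed: int | None = None,
) -> IonTable:
    """Generate the enzyme-only blank table, separated from prior landmarks."""
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    registry = registry if registry is not None else _LandmarkRegistry(cfg)
    mz, rt, z = registry.place(cfg.n_blank_ions, rng)
    abundance = _abundances_above_threshold(cfg, cfg.n_blank_ions, rng)
    ions = [
        PeptideIon(f"blank_{i:05d}", float(mz[i]), int(z[i]), float(rt[i]), float(abundance[i]))
        for i in range(cfg.n_blank_ions)
    ]
    return IonTable(source_id=source_id, replicate_id=replicate_id, ions=tuple(ions))


@dataclass(frozen=True)
class DigestGroundTruth:
    """Planted composition of one simulated digest."""

    planted_pairs: tuple        # (digest ion_id, benchmark ion_id)
    blank_derived: tuple        # digest ion_ids copied (with jitter) from blank ions
    unique_ids: tuple           # digest ion_ids with no benchmark counterpart


def simulate_digest(
    benchmark: IonTable,
    cfg: IonTableSimConfig,
    blank: IonTable | None = None,
    source_id: str = "digest",
    replicate_id: str = "r1",
    registry: _LandmarkRegistry | None = None,
    seed: int | None = None,
    abundance_scale: float = 1.0,
) -> tuple[IonTable, DigestGroundTruth]:
    """Generate a digest sharing a planted fraction of the benchmark's ions.

    round(overlap_fraction × n_digest_ions) ions are jittered copies of
    distinct benchmark ions; the remainder are unique ions placed outside
    tolerance of every benchmark and blank ion. If a blank is supplied,
    round(blank_contamination_fraction × n_digest_ions) additional jittered
    blank copies are appended. Fresh abundances are drawn for every ion.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    n = cfg.n_digest_ions
    n_overlap = round(cfg.overlap_fraction * n)
    if n_overlap > len(benchmark):
        raise ValueError(
            f"overlap_fraction × n_digest_ions = {n_overlap} exceeds benchmark size {len(benchmark)}"
        )
    n_unique = n - n_overlap

    if registry is None:
        registry = _LandmarkRegistry(cfg)
        registry.register_table(benchmark)
        if blank is not None:
            registry.register_table(blank)

    ions: list[PeptideIon] = []
    prefix = f"{source_id}_{replicate_id}"

    chosen = rng.choice(len(benchmark), size=n_overlap, replace=False)
    planted_pairs = []
    for i, idx in enumerate(chosen):
        ref = benchmark.ions[int(idx)]
        ion_id = f"{prefix}_ov_{i:05d}"
        ions.append(PeptideIon(
            ion_id,
            ref.mz + rng.normal(0.0, cfg.mz_jitter_sd),
            ref.charge,
            max(0.0, ref.rt + rng.normal(0.0, cfg.rt_jitter_sd)),
            float(_abundances(cfg, 1, rng, abundance_scale)[0]),
        ))
        planted_pairs.append((ion_id, ref.ion_id))

    mz, rt, z = registry.place(n_unique, rng, register=False)
    unique_ids = []
    for i in range(n_unique):
        ion_id = f"{prefix}_un_{i:05d}"
        ions.append(PeptideIon(
            ion_id, float(mz[i]), int(z[i]), float(rt[i]),
            float(_abundances(cfg, 1, rng, abundance_scale)[0]),
        ))
        unique_ids.append(ion_id)

    blank_derived = []
    if blank is not None and len(blank) > 0:
        n_contam = round(cfg.blank_contamination_fraction * n)
        picks = rng.choice(len(blank), size=min(n_contam, len(blank)), replace=False)
        for i, idx in enumerate(picks):
            src = blank.ions[int(idx)]
            ion_id = f"{prefix}_bl_{i:05d}"
            ions.append(PeptideIon(
                ion_id,
                src.mz + rng.normal(0.0, cfg.mz_jitter_sd),
                src.charge,
                max(0.0, src.rt + rng.normal(0.0, cfg.rt_jitter_sd)),
                float(_abundances(cfg, 1, rng, abundance_scale)[0]),
            ))
            blank_derived.append(ion_id)

    order = rng.permutation(len(ions))
    table = IonTable(source_id=source_id, replicate_id=replicate_id,
                     ions=tuple(ions[int(j)] for j in order))
    truth = DigestGroundTruth(
        planted_pairs=tuple(planted_pairs),
        blank_derived=tuple(blank_derived),
        unique_ids=tuple(unique_ids),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Biological read-outs


@dataclass(frozen=True)
class BioSimConfig:
    """Planted-cluster generator for the seven-assay read-out table.

    Cluster mean vectors sit on scaled coordinate axes so that every pair of
    clusters is separated by ``cluster_sep`` effective source-level standard
    deviations, where the effective SD combines source scatter and replicate
    noise averaged over replicates. Requires n_clusters <= number of
    variables.
    """

    seed: int = 0
    source_ids: tuple = tuple(f"S{i + 1:02d}" for i in range(18))
    n_replicates: int = 3
    variables: tuple = BIO_VARIABLES
    n_clusters: int = 3
    cluster_sep: float = 4.0
    within_cluster_sd: float = 0.3
    replicate_sd: float = 1.0
    baseline: float = 100.0
    outlier_rate: float = 0.0
    outlier_sd_range: tuple = (6.0, 10.0)
    cluster_assignment: tuple | None = None  # cluster index per source, optional

    def __post_init__(self):
        if self.n_clusters > len(self.variables):
            raise ValueError("n_clusters must not exceed the number of variables")
        if self.cluster_assignment is not None:
            if len(self.cluster_assignment) != len(self.source_ids):
                raise ValueError("cluster_assignment must cover every source")

    def effective_sd(self) -> float:
        return math.sqrt(self.within_cluster_sd ** 2 + self.replicate_sd ** 2 / self.n_replicates)

    def assignment(self) -> tuple:
        if self.cluster_assignment is not None:
            return tuple(self.cluster_assignment)
        return tuple(i % self.n_clusters for i in range(len(self.source_ids)))


@dataclass(frozen=True)
class BioGroundTruth:
    assignment: dict            # source_id -> cluster index
    cluster_means: np.ndarray   # (n_clusters, d) true mean vectors
    outliers: tuple             # (source_id, replicate_id, variable) of injected outliers


def simulate_bio_readouts(cfg: BioSimConfig) -> tuple[BioReadoutTable, BioGroundTruth]:
    """Generate replicate read-outs with planted Gaussian cluster structure.

    Each source draws a true vector from its cluster (isotropic source
    scatter around the cluster mean); replicates add independent noise.
    Each (source, variable) group independently receives, with probability
    ``outlier_rate``, one corrupted replicate displaced by 6–10 replicate
    SDs — far beyond ordinary noise.
    """
    rng = np.random.default_rng(cfg.seed)
    d = len(cfg.variables)
    assignment = cfg.assignment()
    scale = cfg.cluster_sep * cfg.effective_sd() / math.sqrt(2.0)
    cluster_means = np.full((cfg.n_clusters, d), cfg.baseline)
    for c in range(cfg.n_clusters):
        cluster_means[c, c] += scale

    rows = []
    outliers = []
    for s_idx, src in enumerate(cfg.source_ids):
        cluster = assignment[s_idx]
        true_vec = cluster_means[cluster] + rng.normal(0.0, cfg.within_cluster_sd, size=d)
        values = true_vec[None, :] + rng.normal(
            0.0, cfg.replicate_sd, size=(cfg.n_replicates, d))
        # at most one corrupted replicate per (source, variable) group, so the
        # single-outlier screening contract has clean ground truth (two
        # injected outliers in one group would mask each other)
        for v_idx, var in enumerate(cfg.variables):
            if cfg.outlier_rate > 0 and rng.random() < cfg.outlier_rate:
                r = int(rng.integers(cfg.n_replicates))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                values[r, v_idx] += sign * rng.uniform(*cfg.outlier_sd_range) * cfg.replicate_sd
                outliers.append((src, f"r{r + 1}", var))
        for r in range(cfg.n_replicates):
            for v_idx, var in enumerate(cfg.variables):
                rows.append({
                    "source_id": src, "replicate_id": f"r{r + 1}",
                    "variable": var, "value": max(values[r, v_idx], 0.0),
                })
    table = BioReadoutTable(pd.DataFrame(rows))
    truth = BioGroundTruth(
        assignment={src: assignment[i] for i, src in enumerate(cfg.source_ids)},
        cluster_means=cluster_means,
        outliers=tuple(outliers),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Whole-study simulation


@dataclass(frozen=True)
class ProteomicGroup:
    """Digest-level generator parameters shared by a planted proteomic cluster.

    Each source in a group draws its own overlap fraction and abundance
    scale around the group values, so within-cluster spread is Gaussian at
    the source level rather than mere ion-sampling noise.
    """

    overlap_fraction: float
    abundance_scale: float = 1.0
    overlap_sd: float = 0.02
    log_scale_sd: float = 0.1


#: Three planted proteomic phenotypes: benchmark-like, dissimilar, intermediate.
DEFAULT_PROTEOMIC_GROUPS = (
    ProteomicGroup(overlap_fraction=0.85, abundance_scale=1.0),
    ProteomicGroup(overlap_fraction=0.12, abundance_scale=0.45),
    ProteomicGroup(overlap_fraction=0.55, abundance_scale=2.5),
)


@dataclass(frozen=True)
class StudySimConfig:
    seed: int = 0
    source_ids: tuple = tuple(f"S{i + 1:02d}" for i in range(18))
    n_replicates: int = 3
    ion: IonTableSimConfig = field(default_factory=lambda: IonTableSimConfig(
        n_benchmark_ions=600, n_digest_ions=400, n_blank_ions=120))
    proteomic_groups: tuple = DEFAULT_PROTEOMIC_GROUPS
    bio_n_clusters: int = 3
    bio_outlier_rate: float = 0.0


@dataclass(frozen=True)
class StudyData:
    benchmark: IonTable
    blank: IonTable
    digests: tuple              # IonTable per (source, replicate)
    bio: BioReadoutTable
    digest_truth: dict          # (source_id, replicate_id) -> DigestGroundTruth
    bio_truth: BioGroundTruth
    proteomic_groups: dict      # source_id -> group index


def simulate_study(cfg: StudySimConfig) -> StudyData:
    """Generate a complete synthetic study: ion tables plus read-out table.

    Sources are assigned round-robin to the proteomic groups; the blank is
    included as an extra row of the biological table (it is a sample there,
    while being the subtraction reference for the proteomic side).
    """
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(2 + len(cfg.source_ids) * cfg.n_replicates + 1)]
    registry = _LandmarkRegistry(cfg.ion)
    benchmark = simulate_benchmark(cfg.ion, registry=registry, seed=seeds[0])
    blank = simulate_blank(cfg.ion, registry=registry, seed=seeds[1])

    digests = []
    truth = {}
    groups = {}
    idx = 2
    source_rng = np.random.default_rng(ss.spawn(1)[0])
    for i, src in enumerate(cfg.source_ids):
        group_idx = i % len(cfg.proteomic_groups)
        group = cfg.proteomic_groups[group_idx]
        groups[src] = group_idx
        overlap = float(np.clip(
            source_rng.normal(group.overlap_fraction, group.overlap_sd), 0.01, 0.99))
        scale = group.abundance_scale * math.exp(source_rng.normal(0.0, group.log_scale_sd))
        ion_cfg = replace(cfg.ion, overlap_fraction=overlap)
        for r in range(cfg.n_replicates):
            rep = f"r{r + 1}"
            table, gt = simulate_digest(
                benchmark, ion_cfg, blank=blank, source_id=src, replicate_id=rep,
                registry=registry, seed=seeds[idx], abundance_scale=scale,
            )
            digests.append(table)
            truth[(src, rep)] = gt
            idx += 1

    bio_cfg = BioSimConfig(
        seed=seeds[idx],
        source_ids=tuple(cfg.source_ids) + ("Blank",),
        n_replicates=cfg.n_replicates,
        n_clusters=cfg.bio_n_clusters,
        outlier_rate=cfg.bio_outlier_rate,
    )
    bio, bio_truth = simulate_bio_readouts(bio_cfg)
    return StudyData(
        benchmark=benchmark, blank=blank, digests=tuple(digests), bio=bio,
        digest_truth=truth, bio_truth=bio_truth, proteomic_groups=groups,
    )
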