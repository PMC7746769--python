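"""Per-digest characteristics derived from benchmark matching.

Five summary characteristics describe each digest's peptide profile relative
to the benchmark protein:

  (a) abundance fractions of di/tripeptide vs oligopeptide ions,
  (b) total abundance of retained ions,
  (c) count of unique (non-benchmark-overlapping) ions,
  (d) overlapping-ion count as a percentage of retained ions, and
  (e) overlapping-ion abundance as a percentage of retained abundance.

Size classification uses the neutral (uncharged) peptide mass recovered from
m/z and charge; ions at or below a configurable cutoff (default 425 Da, the
upper range of common tripeptides) count as di/tripeptides. Absolute
fraction values depend on this cutoff; comparisons between digests under a
fixed cutoff do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .ion_io import IonTable, PeptideIon
from .peak_matching import MatchResult

logger = logging.getLogger(__name__)

#: Mass of a proton in Dalton, for charge-state correction.
PROTON_MASS = 1.007276


@dataclass(frozen=True)
class SizeClassRule:
    """Neutral-mass rule separating di/tripeptides from oligopeptides."""

    proton_mass: float = PROTON_MASS
    ditri_max_neutral_mass: float = 425.0

    def __post_init__(self):
        if self.ditri_max_neutral_mass <= 0:
            raise ValueError("ditri_max_neutral_mass must be > 0")


def neutral_mass(ion: PeptideIon, proton_mass: float = PROTON_MASS) -> float:
    """Neutral monoisotopic mass in Da: (m/z − proton mass) × charge."""
    return (ion.mz - proton_mass) * ion.charge


def classify_size(ion: PeptideIon, rule: SizeClassRule | None = None) -> str:
    """Classify an ion as ``"ditri"`` or ``"oligo"`` by neutral mass (inclusive cutoff)."""
    rule = rule or SizeClassRule()
    if neutral_mass(ion, rule.proton_mass) <= rule.ditri_max_neutral_mass:
        return "ditri"
    return "oligo"


@dataclass(frozen=True)
class DigestFeatures:
    """The per-digest characteristics feeding the proteomic clustering.

    ``frac_ditri`` and ``frac_oligo`` are abundance fractions summing to 1
    for non-empty digests; ``pct_overlap`` counts ions, while
    ``pct_abundance_overlap`` weights them by abundance.
    """

    frac_ditri: float
    frac_oligo: float
    total_abundance: float
    n_unique: int
    pct_overlap: float
    pct_abundance_overlap: float

    def to_dict(self) -> dict:
        return {
            "frac_ditri": self.frac_ditri,
            "frac_oligo": self.frac_oligo,
            "total_abundance": self.total_abundance,
            "n_unique": self.n_unique,
            "pct_overlap": self.pct_overlap,
            "pct_abundance_overlap": self.pct_abundance_overlap,
        }


#: Canonical order of the proteomic feature columns.
FEATURE_NAMES = (
    "frac_ditri",
    "frac_oligo",
    "total_abundance",
    "n_unique",
    "pct_overlap",
    "pct_abundance_overlap",
)


def compute_features(
    digest: IonTable, match: MatchResult, rule: SizeClassRule | None = None
) -> DigestFeatures:
    """Derive the five characteristics from a filtered digest and its match.

    ``digest`` must be the same (filtered, blank-corrected) table the match
    was computed from. An empty digest yields all-zero features with a
    logged warning, keeping the downstream feature matrix total.
    """
    rule = rule or SizeClassRule()
    if match.audit["n_query_in"] != len(digest):
        raise ValueError(
            "match was not produced from this digest: "
            f"{match.audit['n_query_in']} query ions vs {len(digest)} table ions"
        )
    n_retained = len(digest)
    if n_retained == 0:
        logger.warning(
            "digest %s/%s is empty after filtering; features set to 0",
            digest.source_id, digest.replicate_id,
        )
        return DigestFeatures(0.0, 0.0, 0.0, 0, 0.0, 0.0)

    matched_ids = match.matched_query_ids
    total_abundance = sum(ion.abundance for ion in digest)
    ditri_abundance = sum(
        ion.abundance for ion in digest if classify_size(ion, rule) == "ditri"
    )
    overlap_abundance = sum(ion.abundance for ion in digest if ion.ion_id in matched_ids)
    n_overlap = len(matched_ids)

    if total_abundance > 0:
        frac_ditri = ditri_abundance / total_abundance
        frac_oligo = 1.0 - frac_ditri
        pct_abundance_overlap = 100.0 * overlap_abundance / total_abundance
    else:
        logger.warning(
            "digest %s/%s has zero total abundance; fractions set to 0",
            digest.source_id, digest.replicate_id,
        )
        frac_ditri = frac_oligo = pct_abundance_overlap = 0.0

    return DigestFeatures(
        frac_ditri=frac_ditri,
        frac_oligo=frac_oligo,
        total_abundance=total_abundance,
        n_unique=n_retained - n_overlap,
        pct_overlap=100.0 * n_overlap / n_retained,
        pct_abundance_overlap=pct_abundance_overlap,
    )


def export_overlap_tables(
    match: MatchResult,
    digest: IonTable,
    benchmark: IonTable,
    rule: SizeClassRule | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the tile-plot and abundance-comparison tables for one digest.

    The tile table has one row per benchmark ion with its size class and an
    overlap indicator; the comparison table has one row per overlapping
    benchmark ion pairing the benchmark abundance with the summed abundance
    of the digest ions assigned to it.
    """
    rule = rule or SizeClassRule()
    per_ref = match.per_reference_abundance
    n_assigned: dict = {}
    for _, rid, _ in match.pairs:
        n_assigned[rid] = n_assigned.get(rid, 0) + 1

    tile = pd.DataFrame(
        {
            "ref_id": [i.ion_id for i in benchmark],
            "mz": [i.mz for i in benchmark],
            "rt_min": [i.rt for i in benchmark],
            "charge": [i.charge for i in benchmark],
            "size_class": [classify_size(i, rule) for i in benchmark],
            "overlapped": [i.ion_id in per_ref for i in benchmark],
            "n_query_matched": [n_assigned.get(i.ion_id, 0) for i in benchmark],
        }
    )
    overlapping = [i for i in benchmark if i.ion_id in per_ref]
    comparison = pd.DataFrame(
        {
            "ref_id": [i.ion_id for i in overlapping],
            "benchmark_abundance": [i.abundance for i in overlapping],
            "digest_abundance": [per_ref[i.ion_id] for i in overlapping],
        }
    )
    return tile, comparison
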