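"""Abundance filtering, blank subtraction, and benchmark matching of ion tables.

The matching rules mirror the study design they support: two ion peaks from
different LC-MS runs are considered the same peptide ion when their charge
states are equal and their m/z and retention-time differences fall within
±0.003 Th and ±0.5 min respectively (inclusive). When several reference
peaks satisfy the tolerance for one query peak, the nearest is chosen in a
two-dimensional (m/z, RT) space where both axes are weighted equally — the
m/z axis is scaled by rt_tol/mz_tol so that 0.003 Th is equivalent to
0.5 min — and distance is Euclidean:

    distance = sqrt((Δmz · rt_tol/mz_tol)² + Δrt²)      [rt-equivalent minutes]

Processing order follows the upstream accounting: low-abundance peaks
(raw abundance < 1e5) are dropped first, then peaks overlapping the blank
(enzyme-only) digest are excluded, then each digest is matched to the
benchmark protein's table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ion_io import IonTable, PeptideIon

#: Raw-abundance threshold below which ion peaks are excluded.
DEFAULT_ABUNDANCE_THRESHOLD = 1e5


@dataclass(frozen=True)
class MatchTolerances:
    """Matching tolerances: m/z in Thomson, RT in minutes.

    ``weight`` (rt-equivalent minutes per Thomson) is defined as
    rt_tol / mz_tol, weighting both criteria equally in the distance.
    """

    mz_tol: float = 0.003
    rt_tol: float = 0.5

    def __post_init__(self):
        if not (self.mz_tol > 0 and self.rt_tol > 0):
            raise ValueError("mz_tol and rt_tol must be > 0")

    @property
    def weight(self) -> float:
        return self.rt_tol / self.mz_tol


def eq1_distance(delta_mz: float, delta_rt: float, tol: MatchTolerances) -> float:
    """Weighted Pythagorean distance in rt-equivalent minutes.

    Symmetric in the sign of both arguments; at ``delta_mz == mz_tol`` and
    ``delta_rt == 0`` it equals ``rt_tol`` exactly.
    """
    return math.hypot(delta_mz * tol.weight, delta_rt)


def tolerance_match_predicate(q: PeptideIon, r: PeptideIon, tol: MatchTolerances) -> bool:
    """True iff equal charge, |Δmz| <= mz_tol and |Δrt| <= rt_tol (inclusive)."""
    return (
        q.charge == r.charge
        and abs(q.mz - r.mz) <= tol.mz_tol
        and abs(q.rt - r.rt) <= tol.rt_tol
    )


def filter_low_abundance(
    table: IonTable, threshold: float = DEFAULT_ABUNDANCE_THRESHOLD
) -> tuple[IonTable, int]:
    """Drop ions with raw abundance strictly below ``threshold``.

    Retains exactly the ions with ``abundance >= threshold``, in their
    original order; returns the filtered table and the excluded count.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = [ion for ion in table if ion.abundance >= threshold]
    return table.with_ions(kept), len(table) - len(kept)


@dataclass(frozen=True)
class MatchResult:
    """Directional assignment of query ions onto reference ions.

    ``pairs`` holds (query ion_id, reference ion_id, distance) with distance
    in rt-equivalent minutes; each query ion appears in at most one pair.
    ``per_reference_abundance`` sums the abundances of all query ions
    assigned to a reference ion (zero or more per reference).
    """

    pairs: tuple[tuple[object, object, float], ...]
    unmatched_query: tuple
    per_reference_abundance: dict
    audit: dict

    def __post_init__(self):
        a = self.audit
        if a["n_matched"] + a["n_unmatched"] != a["n_query_in"]:
            raise ValueError("match audit does not conserve ion counts")

    @property
    def matched_query_ids(self) -> set:
        return {q for q, _, _ in self.pairs}

    def pairs_frame(self, query: IonTable | None = None) -> pd.DataFrame:
        """Pairs as a DataFrame (query_id, ref_id, distance[, query_abundance])."""
        frame = pd.DataFrame(self.pairs, columns=["query_id", "ref_id", "distance"])
        if query is not None:
            abundance = {ion.ion_id: ion.abundance for ion in query}
            frame["query_abundance"] = [abundance[q] for q in frame["query_id"]]
        return frame

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "unmatched_query": list(self.unmatched_query),
            "per_reference_abundance": {str(k): v for k, v in self.per_reference_abundance.items()},
            "audit": dict(self.audit),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class FilterAudit:
    """Ion-count accounting for one digest through the filtering pipeline.

    The conservation identity ``n_observed = n_abundance_excluded +
    n_blank_excluded + n_retained`` is enforced at construction.
    """

    n_observed: int
    n_abundance_excluded: int
    n_blank_excluded: int
    n_retained: int

    def __post_init__(self):
        counts = (self.n_observed, self.n_abundance_excluded, self.n_blank_excluded, self.n_retained)
        if any(c < 0 for c in counts):
            raise ValueError(f"filter audit counts must be non-negative: {counts}")
        if self.n_observed != self.n_abundance_excluded + self.n_blank_excluded + self.n_retained:
            raise ValueError(
                "filter audit does not conserve ion counts: "
                f"{self.n_observed} != {self.n_abundance_excluded} + "
                f"{self.n_blank_excluded} + {self.n_retained}"
            )

    def to_dict(self) -> dict:
        return {
            "n_observed": self.n_observed,
            "n_abundance_excluded": self.n_abundance_excluded,
            "n_blank_excluded": self.n_blank_excluded,
            "n_retained": self.n_retained,
        }


class _SortedReference:
    """Reference table indexed for windowed candidate lookup by m/z."""

    def __init__(self, reference: IonTable):
        ions = list(reference)
        order = np.argsort([i.mz for i in ions], kind="stable")
        self.ions = [ions[j] for j in order]
        self.mz = np.array([i.mz for i in self.ions])
        self.rt = np.array([i.rt for i in self.ions])
        self.charge = np.array([i.charge for i in self.ions])

    def candidates(self, q: PeptideIon, tol: MatchTolerances):
        lo = np.searchsorted(self.mz, q.mz - tol.mz_tol, side="left")
        hi = np.searchsorted(self.mz, q.mz + tol.mz_tol, side="right")
        for j in range(lo, hi):
            r = self.ions[j]
            if tolerance_match_predicate(q, r, tol):
                yield r


def match_to_reference(
    query: IonTable, reference: IonTable, tol: MatchTolerances | None = None
) -> MatchResult:
    """Assign each query ion to its nearest in-tolerance reference ion.

    For every query ion the set of reference ions passing the tolerance
    predicate is formed; if non-empty, the pair with minimal weighted
    distance is recorded. Ties are broken by smaller |Δmz|, then smaller
    reference ion_id. Query ions are never split across references;
    reference ions may receive any number of query ions, whose abundances
    are summed in ``per_reference_abundance``.
    """
    tol = tol or MatchTolerances()
    ref = _SortedReference(reference)
    pairs = []
    unmatched = []
    per_ref: dict = {}
    for q in query:
        best = None
        for r in ref.candidates(q, tol):
            d = eq1_distance(q.mz - r.mz, q.rt - r.rt, tol)
            key = (d, abs(q.mz - r.mz), r.ion_id)
            if best is None or key < best[0]:
                best = (key, r)
        if best is None:
            unmatched.append(q.ion_id)
        else:
            key, r = best
            pairs.append((q.ion_id, r.ion_id, key[0]))
            per_ref[r.ion_id] = per_ref.get(r.ion_id, 0.0) + q.abundance
    audit = {
        "n_query_in": len(query),
        "n_matched": len(pairs),
        "n_unmatched": len(unmatched),
    }
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_query=tuple(unmatched),
        per_reference_abundance=per_ref,
        audit=audit,
    )


def subtract_blank(
    table: IonTable, blank: IonTable, tol: MatchTolerances | None = None
) -> tuple[IonTable, int]:
    """Remove every ion of ``table`` overlapping any blank ion within tolerance.

    Exclusion uses the bare tolerance predicate (no nearest-match ranking):
    the question is membership in the enzyme background, not assignment.
    Idempotent: a second subtraction with the same blank removes nothing.
    """
    tol = tol or MatchTolerances()
    ref = _SortedReference(blank)
    kept = [q for q in table if next(iter(ref.candidates(q, tol)), None) is None]
    return table.with_ions(kept), len(table) - len(kept)


@dataclass(frozen=True)
class DigestMatchRecord:
    """One digest replicate after filtering, with its benchmark match and audit."""

    table: IonTable
    match: MatchResult
    audit: FilterAudit


@dataclass(frozen=True)
class MatchingPipelineResult:
    benchmark: IonTable          # abundance-filtered (and optionally blank-corrected)
    blank: IonTable              # abundance-filtered
    records: dict = field(default_factory=dict)  # (source_id, replicate_id) -> DigestMatchRecord


def run_matching_pipeline(
    digests: list[IonTable],
    blank: IonTable,
    benchmark: IonTable,
    tol: MatchTolerances | None = None,
    threshold: float = DEFAULT_ABUNDANCE_THRESHOLD,
    blank_correct_benchmark: bool = True,
) -> MatchingPipelineResult:
    """Filter, blank-subtract, and benchmark-match a set of digest tables.

    Order of operations: the abundance filter is applied to every table
    (digests, blank, benchmark); the blank is subtracted from each digest
    (and, by default, from the benchmark itself); each corrected digest is
    then matched against the corrected benchmark. Per-digest
    :class:`FilterAudit` conservation holds by construction.
    """
    tol = tol or MatchTolerances()
    blank_f, _ = filter_low_abundance(blank, threshold)
    benchmark_f, _ = filter_low_abundance(benchmark, threshold)
    if blank_correct_benchmark:
        benchmark_f, _ = subtract_blank(benchmark_f, blank_f, tol)

    records = {}
    for digest in digests:
        n_observed = len(digest)
        filtered, n_abund = filter_low_abundance(digest, threshold)
        corrected, n_blank = subtract_blank(filtered, blank_f, tol)
        match = match_to_reference(corrected, benchmark_f, tol)
        audit = FilterAudit(
            n_observed=n_observed,
            n_abundance_excluded=n_abund,
            n_blank_excluded=n_blank,
            n_retained=len(corrected),
        )
        records[(digest.source_id, digest.replicate_id)] = DigestMatchRecord(
            table=corrected, match=match, audit=audit
        )
    return MatchingPipelineResult(benchmark=benchmark_f, blank=blank_f, records=records)
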