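"""Filtering, blank subtraction, and nearest-match behaviour against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digesta.ion_io import IonTable, PeptideIon
from digesta.peak_matching import (
    FilterAudit,
    MatchTolerances,
    eq1_distance,
    filter_low_abundance,
    match_to_reference,
    run_matching_pipeline,
    subtract_blank,
    tolerance_match_predicate,
)

from conftest import make_table, random_dense_table

TOL = MatchTolerances()


def brute_force_match(query, reference, tol):
    """Exhaustive O(n²) nearest-match oracle with the documented tie-breaks."""
    pairs, unmatched = [], []
    for q in query:
        candidates = [r for r in reference if tolerance_match_predicate(q, r, tol)]
        if not candidates:
            unmatched.append(q.ion_id)
            continue
        best = min(
            candidates,
            key=lambda r: (eq1_distance(q.mz - r.mz, q.rt - r.rt, tol),
                           abs(q.mz - r.mz), r.ion_id),
        )
        pairs.append((q.ion_id, best.ion_id,
                      eq1_distance(q.mz - best.mz, q.rt - best.rt, tol)))
    return pairs, unmatched


class TestEq1Distance:
    def test_tolerance_equivalence_point(self):
        # 0.003 Th is weighted to be worth exactly 0.5 min
        assert eq1_distance(0.003, 0.0, TOL) == 0.5

    def test_zero(self):
        assert eq1_distance(0.0, 0.0, TOL) == 0.0

    def test_corner(self):
        assert eq1_distance(0.003, 0.5, TOL) == pytest.approx(np.sqrt(0.5), rel=1e-12)

    @given(dmz=st.floats(-0.01, 0.01), drt=st.floats(-1.0, 1.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_sign_symmetry_and_axes(self, dmz, drt):
        assert eq1_distance(dmz, drt, TOL) == eq1_distance(-dmz, -drt, TOL)
        assert eq1_distance(dmz, 0.0, TOL) == pytest.approx(abs(dmz) * TOL.weight)
        assert eq1_distance(0.0, drt, TOL) == abs(drt)


class TestTolerancePredicate:
    def test_identical_ions(self):
        a = PeptideIon(0, 500.0, 2, 10.0, 1e6)
        assert tolerance_match_predicate(a, a, TOL)

    def test_inclusive_boundary(self):
        a = PeptideIon(0, 500.0, 2, 10.0, 1e6)
        b = PeptideIon(1, 500.003, 2, 10.0, 1e6)
        c = PeptideIon(2, 500.0, 2, 10.5, 1e6)
        assert tolerance_match_predicate(a, b, TOL)
        assert tolerance_match_predicate(a, c, TOL)

    def test_charge_must_match_exactly(self):
        a = PeptideIon(0, 500.0, 2, 10.0, 1e6)
        b = PeptideIon(1, 500.0, 3, 10.0, 1e6)
        assert not tolerance_match_predicate(a, b, TOL)


class TestAbundanceFilter:
    def test_strict_less_than_exclusion(self):
        table = make_table([(500, 1, 10, 5e4), (501, 1, 10, 1e5), (502, 1, 10, 2e5)])
        kept, excluded = filter_low_abundance(table, 1e5)
        assert [i.abundance for i in kept] == [1e5, 2e5]  # boundary retained
        assert excluded == 1

    def test_empty_table(self):
        kept, excluded = filter_low_abundance(IonTable("S", "r1", ()), 1e5)
        assert len(kept) == 0 and excluded == 0

    def test_zero_threshold_is_identity(self):
        table = make_table([(500, 1, 10, 0.0), (501, 1, 10, 1.0)])
        kept, excluded = filter_low_abundance(table, 0.0)
        assert kept.ions == table.ions and excluded == 0


class TestMatchToReference:
    def test_nearest_of_two_candidates(self):
        query = make_table([(500.000, 2, 10.0, 1e6)], source_id="Q")
        ref = make_table([(500.001, 2, 10.0, 1e6), (500.002, 2, 10.1, 1e6)], source_id="R")
        result = match_to_reference(query, ref, TOL)
        assert len(result.pairs) == 1
        qid, rid, dist = result.pairs[0]
        assert rid == 0
        assert dist == pytest.approx(0.001 * TOL.weight, rel=1e-9)

    def test_self_match_at_zero_distance(self, rng):
        table = random_dense_table(rng, 50)
        result = match_to_reference(table, table, TOL)
        assert len(result.pairs) == len(table)
        assert all(q == r and d == 0.0 for q, r, d in result.pairs)

    def test_equal_distance_tie_broken_by_dmz_then_id(self):
        # two references at identical weighted distance: one closer in m/z wins
        query = make_table([(500.000, 1, 10.0, 1e6)], source_id="Q")
        ref = make_table(
            [(500.0018, 1, 10.0, 1e6),          # pure-m/z offset: d = 0.3
             (500.0, 1, 10.3, 1e6)],            # pure-RT offset: d = 0.3
            source_id="R",
        )
        result = match_to_reference(query, ref, TOL)
        assert result.pairs[0][1] == 1  # |Δmz| = 0 beats |Δmz| = 0.0018

    def test_multiple_queries_summed_per_reference(self):
        query = make_table([(500.000, 1, 10.0, 100.0), (500.001, 1, 10.1, 50.0)], "Q")
        ref = make_table([(500.0005, 1, 10.0, 1e6)], "R")
        result = match_to_reference(query, ref, TOL)
        assert result.per_reference_abundance[0] == pytest.approx(150.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        query = random_dense_table(rng, 200, source_id="Q")
        ref = random_dense_table(rng, 200, source_id="R")
        result = match_to_reference(query, ref, TOL)
        pairs, unmatched = brute_force_match(query, ref, TOL)
        assert list(result.pairs) == pairs
        assert list(result.unmatched_query) == unmatched

    def test_audit_conserves_counts(self, rng):
        query = random_dense_table(rng, 120, source_id="Q")
        ref = random_dense_table(rng, 60, source_id="R")
        a = match_to_reference(query, ref, TOL).audit
        assert a["n_matched"] + a["n_unmatched"] == a["n_query_in"] == 120


class TestSubtractBlank:
    def test_table_equal_to_blank_empties(self, rng):
        table = random_dense_table(rng, 40)
        remainder, removed = subtract_blank(table, table, TOL)
        assert len(remainder) == 0 and removed == 40

    def test_disjoint_charges_identity(self):
        table = make_table([(500, 1, 10, 1e6), (501, 1, 11, 1e6)])
        blank = make_table([(500, 2, 10, 1e6), (501, 2, 11, 1e6)], source_id="Blank")
        remainder, removed = subtract_blank(table, blank, TOL)
        assert remainder.ions == table.ions and removed == 0

    def test_idempotent(self, rng):
        table = random_dense_table(rng, 150)
        blank = random_dense_table(rng, 60, source_id="Blank")
        once, n1 = subtract_blank(table, blank, TOL)
        twice, n2 = subtract_blank(once, blank, TOL)
        assert n2 == 0 and twice.ions == once.ions
        assert n1 > 0  # dense tables overlap; the first pass must remove something


class TestFilterAudit:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError, match="conserve"):
            FilterAudit(10, 5, 3, 5)

    def test_study_scale_accounting(self):
        # totals at the scale of a full 18-digest study remain consistent
        audit = FilterAudit(422697, 414436, 3542, 4719)
        assert audit.n_observed - audit.n_abundance_excluded - audit.n_blank_excluded \
            == audit.n_retained


class TestPipeline:
    def test_digest_equal_to_benchmark_fully_matches(self, rng):
        bench = random_dense_table(rng, 80, source_id="WPC")
        digest = IonTable("D", "r1", bench.ions)
        blank = IonTable("Blank", "r1", ())
        out = run_matching_pipeline([digest], blank, bench, TOL, threshold=0.0)
        record = out.records[("D", "r1")]
        assert record.match.audit["n_unmatched"] == 0
        assert record.audit.n_retained == 80

    def test_audit_conservation_on_random_runs(self, rng):
        for _ in range(5):
            digest = random_dense_table(rng, 200, source_id="D")
            blank = random_dense_table(rng, 40, source_id="Blank")
            bench = random_dense_table(rng, 100, source_id="WPC")
            out = run_matching_pipeline([digest], blank, bench, TOL, threshold=1.5e5)
            audit = out.records[("D", "r1")].audit
            assert audit.n_observed == 200  # constructor enforces the identity
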