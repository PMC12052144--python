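"""Dual-direction detection, cis/trans and chromosome tests, overlaps and
gene-set enrichment, each checked against an independent small-case oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isomas._stats import harmonic_mean_p, hypergeom_upper_tail
from isomas.downstream import (chromosome_preference_test, cis_enrichment_test,
                               detect_dual_direction,
                               hypergeometric_enrichment, overlap_coefficient,
                               target_overlap_between_cancers)
from isomas.io_formats import GeneAnnotation
from isomas.scan import GeneMutationStatus

from conftest import make_expression


class TestHarmonicMeanP:
    def test_two_value_arithmetic(self):
        assert harmonic_mean_p([0.01, 0.04]) == pytest.approx(2 / 125, abs=1e-15)

    def test_single_value_is_identity(self):
        assert harmonic_mean_p([0.37]) == pytest.approx(0.37)

    def test_constant_list_is_the_constant(self):
        assert harmonic_mean_p([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            harmonic_mean_p([])
        with pytest.raises(ValueError):
            harmonic_mean_p([0.2, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_bounded_by_min_and_max(self, ps):
        h = harmonic_mean_p(ps)
        assert min(ps) - 1e-12 <= h <= max(ps) + 1e-12


class TestDualDirection:
    def _cohort(self, up_shift, down_shift):
        # target gene TG with two isoforms; iSoMAs gene not expressed
        n = 40
        rng = np.random.default_rng(0)
        base = rng.normal(10, 0.5, (3, n)).clip(0)
        status = np.r_[np.ones(10, bool), np.zeros(30, bool)]
        base[0, status] += up_shift
        base[1, status] += down_shift
        expr = make_expression(base, ["TG.1", "TG.2", "OT.1"],
                               ["TG", "TG", "OT"],
                               [f"s{i}" for i in range(n)])
        return expr, GeneMutationStatus("MUT", status)

    def test_opposite_significant_isoforms_flag_dual(self):
        expr, status = self._cohort(+5.0, -5.0)
        recs, agg = detect_dual_direction(expr, status, ["TG.1", "TG.2"])
        rec = [r for r in recs if r.target_gene == "TG"][0]
        assert rec.is_dual
        assert agg["n_dual_genes"] == 1
        # HMP over exactly the two significant isoforms
        ps = [p for _, p, _ in rec.up_isoforms + rec.down_isoforms]
        assert rec.hmp == pytest.approx(harmonic_mean_p(ps))
        assert agg["neg_log10_mHMP"] == pytest.approx(-np.log10(rec.hmp))

    def test_same_direction_is_not_dual(self):
        expr, status = self._cohort(+5.0, +5.0)
        recs, agg = detect_dual_direction(expr, status, ["TG.1", "TG.2"])
        assert not any(r.is_dual for r in recs)

    def test_second_direction_below_threshold_is_not_dual(self):
        expr, status = self._cohort(+5.0, -0.05)  # tiny down-shift: p > 0.05
        recs, _ = detect_dual_direction(expr, status, ["TG.1", "TG.2"])
        rec = [r for r in recs if r.target_gene == "TG"][0]
        assert not rec.is_dual

    def test_single_isoform_gene_cannot_be_dual(self):
        expr, status = self._cohort(+5.0, -5.0)
        recs, _ = detect_dual_direction(expr, status, ["OT.1"])
        assert [r.is_dual for r in recs] == [False]


def _annotation(chroms, tsss, genes=None):
    n = len(chroms)
    tids = [f"t{i}" for i in range(n)]
    genes = genes or [f"g{i}" for i in range(n)]
    df = pd.DataFrame({"gene_id": genes, "chrom": [str(c) for c in chroms],
                       "strand": "+", "tss": tsss},
                      index=pd.Index(tids, name="transcript_id"))
    return GeneAnnotation(df), tids


class TestCisEnrichment:
    def test_all_targets_in_window_matches_enumeration(self):
        # N=10 universe, m=4 in cis window, q=3 targets all cis
        ann, tids = _annotation([1] * 10,
                                [100] * 4 + [5_000_000] * 6,
                                genes=["G"] + [f"g{i}" for i in range(1, 10)])
        res = cis_enrichment_test("G", tids[:3], ann, tids, window_bp=1000)
        assert res.k == 3 and res.m == 4 and res.q == 3 and res.N == 10
        # oracle: enumerate all C(10,3) draws
        hits = sum(1 for c in itertools.combinations(range(10), 3)
                   if sum(i < 4 for i in c) >= 3)
        assert res.p == pytest.approx(hits / 120)
        assert res.p == pytest.approx(4 / 120)

    def test_no_cis_targets_gives_p_near_one(self):
        ann, tids = _annotation([1] * 10, [100] * 4 + [5_000_000] * 6,
                                genes=["G"] + [f"g{i}" for i in range(1, 10)])
        res = cis_enrichment_test("G", tids[4:7], ann, tids, window_bp=1000)
        assert res.k == 0
        assert res.p == 1.0
        assert res.trans_consistent

    def test_unannotated_gene_returns_none(self):
        ann, tids = _annotation([1] * 4, [1, 2, 3, 4])
        assert cis_enrichment_test("missing", tids[:2], ann, tids) is None

    def test_tail_consistency_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            N = int(rng.integers(5, 30))
            m = int(rng.integers(1, N))
            q = int(rng.integers(1, N))
            k = int(rng.integers(0, min(m, q) + 1))
            upper = hypergeom_upper_tail(k, N, m, q)
            lower = stats.hypergeom.cdf(k, N, m, q)
            point = stats.hypergeom.pmf(k, N, m, q)
            assert upper + lower - point == pytest.approx(1.0, abs=1e-10)


class TestChromosomePreference:
    def test_identical_composition_gives_p_one(self):
        chroms = [1, 1, 2, 2, 3, 3]
        ann, tids = _annotation(chroms, [100] * 6)
        d, p, span = chromosome_preference_test(tids, ann, tids)
        assert d == 0.0 and p == 1.0 and span == 3

    def test_concentration_on_one_chromosome_is_detected(self):
        chroms = list(range(1, 23)) * 10  # uniform universe
        ann, tids = _annotation(chroms, [100] * len(chroms))
        targets = [t for t, c in zip(tids, chroms) if c == 1][:10] * 10
        d, p, span = chromosome_preference_test(set(targets), ann, tids)
        assert p < 0.05
        assert span == 1

    def test_single_target_does_not_crash(self):
        ann, tids = _annotation([1, 2, 3, 4], [100] * 4)
        d, p, span = chromosome_preference_test(tids[:1], ann, tids)
        assert 0 < p <= 1.0

    def test_permutation_mode_agrees_qualitatively_with_ks(self):
        chroms = list(range(1, 23)) * 10
        ann, tids = _annotation(chroms, [100] * len(chroms))
        targets = [t for t, c in zip(tids, chroms) if c == 1][:10] * 10
        _, p_perm, _ = chromosome_preference_test(
            set(targets), ann, tids, method="permutation",
            n_permutations=500, seed=1)
        assert p_perm < 0.05
        # a size-matched random subset shows no preference
        _, p_null, _ = chromosome_preference_test(
            tids[:100], ann, tids, method="permutation",
            n_permutations=500, seed=1)
        assert p_null > 0.05


class TestOverlaps:
    def test_subset_gives_one(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_disjoint_gives_zero(self):
        assert overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_partial_overlap_fraction(self):
        assert overlap_coefficient({"a", "b", "c"}, {"b", "c", "d", "e"}) \
            == pytest.approx(2 / 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 20), min_size=1, max_size=10),
           st.sets(st.integers(0, 20), min_size=1, max_size=10))
    def test_symmetry(self, a, b):
        assert overlap_coefficient(a, b) == overlap_coefficient(b, a)

    def test_target_overlap_three_step_mean(self):
        a = {"g1": [f"t{i}" for i in range(30)],
             "g2": [f"t{i}" for i in range(100, 160)]}
        b = {"g1": [f"t{i}" for i in range(10, 40)],
             "g2": [f"t{i}" for i in range(100, 160)],
             "g3": ["x"]}
        # g1 top-20 lists overlap on t10..t19 -> 10; g2 lists coincide -> 20
        got = target_overlap_between_cancers(a, b, top_k=20)
        assert got == pytest.approx((10 + 20) / 2)

    def test_identical_lists_give_top_k(self):
        a = {"g": [f"t{i}" for i in range(50)]}
        assert target_overlap_between_cancers(a, a, top_k=10) == 10

    def test_no_shared_genes_reports_missing(self):
        assert target_overlap_between_cancers({"g1": ["t"]}, {"g2": ["t"]}) is None


class TestEnrichment:
    def test_matches_brute_force_enumeration(self):
        background = [f"g{i}" for i in range(10)]
        gene_set = background[:4]
        query = ["g0", "g1", "g9"]  # k = 2
        res = hypergeometric_enrichment(query, gene_set, background)
        hits = sum(1 for c in itertools.combinations(range(10), 3)
                   if sum(i < 4 for i in c) >= 2)
        assert res.p == pytest.approx(hits / 120)
        assert res.p == pytest.approx(40 / 120)
        assert (res.N, res.m, res.q, res.k) == (10, 4, 3, 2)

    def test_k_zero_covers_whole_space(self):
        background = [f"g{i}" for i in range(10)]
        res = hypergeometric_enrichment(["g9"], background[:4], background)
        assert res.k == 0 and res.p == 1.0

    def test_empty_query_returns_one_by_convention(self):
        background = [f"g{i}" for i in range(10)]
        res = hypergeometric_enrichment(["zz"], background[:2], background)
        assert res.q == 0 and res.p == 1.0 and res.n_dropped == 1

    def test_gene_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["a"], ["zz"], ["a", "b"])

    def test_closed_form_matches_monte_carlo(self):
        rng = np.random.default_rng(41)
        N, m, q, k = 60, 12, 15, 5
        p = hypergeom_upper_tail(k, N, m, q)
        draws = rng.hypergeometric(m, N - m, q, size=100_000)
        freq = float(np.mean(draws >= k))
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(freq - p) <= 3 * se
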