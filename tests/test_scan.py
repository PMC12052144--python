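"""The association scan: qualifying genes, PC-score testing, two-layer
calling, target ranking and the direct per-isoform test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from isomas._stats import wilcoxon_rank_sum
from isomas.pca import PcaModel, reconstruct_scores
from isomas.scan import (GeneMutationStatus, call_isomas_genes,
                         differential_pc_score_test, direct_isoform_test,
                         qualifying_genes, rank_targets)

from conftest import make_expression, make_mutations


def exact_wilcoxon_two_sided(x, y):
    """Enumeration oracle: two-sided rank-sum p by exhausting all
    C(n1+n2, n1) assignments of the pooled values to the first group."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        stat = ranks[list(comb)].sum()
        total += 1
        if abs(stat - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


class TestQualifyingGenes:
    def _mut(self, gene_counts, n=100):
        rows = []
        for gene, (count, vt) in gene_counts.items():
            for i in range(count):
                rows.append((gene, vt, f"s{i}"))
        return make_mutations(rows), [f"s{i}" for i in range(n)]

    def test_threshold_is_inclusive(self):
        mut, samples = self._mut({"A": (2, "SNP")})
        assert qualifying_genes(mut, samples, 0.02) == ["A"]

    def test_below_threshold_excluded(self):
        mut, samples = self._mut({"A": (1, "SNP")})
        assert qualifying_genes(mut, samples, 0.02) == []

    def test_indel_only_gene_excluded(self):
        mut, samples = self._mut({"A": (10, "INS"), "B": (10, "DEL"),
                                  "C": (10, "SNP")})
        assert qualifying_genes(mut, samples, 0.02) == ["C"]


def _model_from_scores(S):
    S = np.asarray(S, float)
    n, K = S.shape
    return PcaModel(
        loadings=pd.DataFrame(np.eye(K)[:K], index=[f"f{i}" for i in range(K)],
                              columns=[f"PC_{k+1}" for k in range(K)]),
        scores=pd.DataFrame(S, index=[f"s{i}" for i in range(n)],
                            columns=[f"PC_{k+1}" for k in range(K)]),
        variance_fraction=np.ones(K) / K, K=K)


class TestDifferentialPcScoreTest:
    def test_complete_separation_3v3_matches_enumeration(self):
        scores = np.array([[10.0], [11.0], [12.0], [1.0], [2.0], [3.0]])
        status = GeneMutationStatus("g", [1, 1, 1, 0, 0, 0])
        p = differential_pc_score_test(_model_from_scores(scores), status)
        assert p[0] == pytest.approx(0.1, abs=1e-12)
        assert p[0] == pytest.approx(
            exact_wilcoxon_two_sided([10, 11, 12], [1, 2, 3]), abs=1e-12)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 5, 0), (4, 4, 1), (2, 8, 2)])
    def test_small_sample_p_equals_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, n1), rng.normal(0.8, 1, n2)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            exact_wilcoxon_two_sided(x, y), abs=1e-12)

    def test_identical_groups_give_p_one(self):
        scores = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        status = GeneMutationStatus("g", [1, 1, 1, 0, 0, 0])
        p = differential_pc_score_test(_model_from_scores(scores), status)
        assert p[0] > 0.99

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(3)
        wt = rng.normal(0, 1, 470)
        mut = wt[:30] + 1000.0
        scores = np.r_[mut, wt][:, None]
        status = GeneMutationStatus("g", np.r_[np.ones(30), np.zeros(470)])
        p = differential_pc_score_test(_model_from_scores(scores), status)
        assert p[0] < 1e-10

    def test_output_length_is_K_regardless_of_feature_count(self, planted_cohort):
        model = planted_cohort["model"]
        gene = planted_cohort["truth"].drivers[0]
        status = planted_cohort["result"].statuses[gene]
        assert differential_pc_score_test(model, status).shape == (model.K,)

    def test_scores_and_reconstructed_scores_give_identical_p(self, planted_cohort):
        model = planted_cohort["model"]
        scaled = planted_cohort["scaled"]
        gene = planted_cohort["truth"].drivers[0]
        status = planted_cohort["result"].statuses[gene]
        p_model = differential_pc_score_test(model, status)
        rebuilt = _model_from_scores(
            reconstruct_scores(scaled, model.loadings).to_numpy())
        p_oracle = differential_pc_score_test(rebuilt, status)
        np.testing.assert_array_equal(p_model, p_oracle)


class TestTwoLayerCalling:
    def test_raw_threshold_arithmetic_single_gene(self):
        table = call_isomas_genes({"g": np.r_[5e-4, np.ones(49)]}, K=50)
        row = table.loc["g"]
        assert row["P_min_bonf"] == pytest.approx(0.025)
        assert row["q"] == pytest.approx(0.025)
        assert bool(row["is_isomas"])
        assert row["selected_pc"] == 1

    def test_first_significant_pc_selected(self):
        p = np.ones(50)
        p[3] = 1e-9   # PC_4
        p[1] = 1e-6   # PC_2 (less significant but earlier)
        table = call_isomas_genes({"g": p}, K=50)
        assert table.loc["g", "selected_pc"] == 2

    def test_lowering_alpha_never_adds_genes(self):
        rng = np.random.default_rng(12)
        pvals = {f"g{i}": rng.uniform(1e-6, 1, 50) for i in range(40)}
        called_loose = set()
        for alpha in (0.05, 0.01, 0.001):
            table = call_isomas_genes(pvals, K=50, alpha_pc=alpha)
            called = set(table.index[table["is_isomas"]])
            if called_loose:
                assert called <= called_loose
            called_loose = called

    def test_layer2_bh_spans_all_tested_genes(self):
        # one borderline gene among many null genes: BH q reflects the family
        pvals = {"hit": np.r_[9e-4 / 50, np.ones(49)]}
        for i in range(99):
            pvals[f"null{i}"] = np.full(50, 0.5)
        table = call_isomas_genes(pvals, K=50)
        assert table.loc["hit", "q"] == pytest.approx(
            min(1.0, table.loc["hit", "P_min_bonf"] * 100))


class TestRankTargets:
    def _model(self, loadings_col):
        L = np.asarray(loadings_col, float)[:, None]
        return PcaModel(
            loadings=pd.DataFrame(L, index=[f"iso{i+1}" for i in range(len(L))],
                                  columns=["PC_1"]),
            scores=pd.DataFrame(np.zeros((2, 1)), index=["s1", "s2"],
                                columns=["PC_1"]),
            variance_fraction=np.ones(1), K=1)

    def test_absolute_value_ordering_keeps_sign(self):
        out = rank_targets(self._model([0.9, -0.95, 0.1]), 1, top_k=3)
        assert list(out["transcript_id"]) == ["iso2", "iso1", "iso3"]
        assert list(out["loading"]) == [-0.95, 0.9, 0.1]
        assert list(out["direction"]) == [-1, 1, 1]

    def test_truncation_to_top_k(self):
        out = rank_targets(self._model([0.9, -0.95, 0.1]), 1, top_k=2)
        assert len(out) == 2

    def test_all_zero_loadings_stable_order_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            out = rank_targets(self._model([0.0, 0.0, 0.0]), 1, top_k=3)
        assert list(out["transcript_id"]) == ["iso1", "iso2", "iso3"]

    def test_signed_top_bottom_mode(self):
        out = rank_targets(self._model([0.2, -0.95, 0.9, -0.1]), 1, top_k=4,
                           rank_mode="signed-top-bottom")
        assert list(out["transcript_id"]) == ["iso3", "iso1", "iso4", "iso2"]


class TestDirectIsoformTest:
    def _fixture(self):
        expr = make_expression([[4, 4, 4, 1, 1, 1],
                                [0, 0, 0, 0, 0, 0]],
                               ["t1", "t2"], ["G1", "G2"],
                               [f"s{i}" for i in range(6)])
        status = GeneMutationStatus("g", [1, 1, 1, 0, 0, 0])
        return expr, status

    def test_log2fc_uses_unit_pseudocount(self):
        expr, status = self._fixture()
        _, lfc = direct_isoform_test(expr, status, "t1")
        assert lfc == pytest.approx(np.log2(5 / 2), abs=1e-12)

    def test_all_zero_isoform_degenerates_gracefully(self):
        expr, status = self._fixture()
        p, lfc = direct_isoform_test(expr, status, "t2")
        assert p == 1.0
        assert lfc == 0.0

    def test_unknown_transcript_is_hard_error(self):
        expr, status = self._fixture()
        with pytest.raises(KeyError):
            direct_isoform_test(expr, status, "nope")


def test_label_permutation_null_calibration(null_cohort):
    """Permuting mutant labels on a null cohort keeps the Bonferroni-level
    family-wise rate near its nominal bound."""
    model = null_cohort["model"]
    S = model.scores.to_numpy()
    rng = np.random.default_rng(99)
    n = S.shape[0]
    n_mut = 20
    hits = 0
    n_perm = 1000
    from isomas._stats import wilcoxon_rank_sum_matrix
    for _ in range(n_perm):
        idx = np.zeros(n, dtype=bool)
        idx[rng.choice(n, n_mut, replace=False)] = True
        p = wilcoxon_rank_sum_matrix(S[idx], S[~idx])
        if min(1.0, model.K * p.min()) < 0.05:
            hits += 1
    assert hits / n_perm <= 0.10
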