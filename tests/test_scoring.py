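import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scxtalk as sx
from scxtalk.scoring import (
    partner_in_top,
    pooled_empirical_pvalues,
    top_gene_mask,
    top_set_size,
)
from scxtalk.synthetic import PlantedPair
from conftest import oracle_score, oracle_top_set, random_instance


def _matrix_from(X):
    N, C = X.shape
    return sx.ExpressionMatrix(
        np.array([f"g{i}" for i in range(N)], dtype=object),
        np.array([f"c{j}" for j in range(C)], dtype=object),
        X,
    )


class TestTopGeneSet:
    def test_top_20_percent_of_ten_genes(self):
        x = pd.Series(np.arange(10, 0, -1, dtype=float),
                      index=[f"g{i}" for i in range(10)])
        assert sx.top_gene_set(x, 0.2) == {"g0", "g1"}

    def test_t_one_is_whole_universe(self):
        x = pd.Series([3.0, 1.0, 2.0], index=["a", "b", "c"])
        assert sx.top_gene_set(x, 1.0) == {"a", "b", "c"}

    def test_boundary_tie_broken_by_gene_index(self):
        x = pd.Series([5.0, 2.0, 2.0, 1.0, 0.0], index=list("abcde"))
        # k=2; b and c tie at the boundary, the earlier gene wins
        assert sx.top_gene_set(x, 0.4) == {"a", "b"}

    def test_empty_top_set_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            top_set_size(4, 0.1)

    def test_fixed_size_across_heavily_tied_cells(self):
        rng = np.random.default_rng(0)
        X = rng.random((50, 10))
        X[rng.random((50, 10)) < 0.7] = 0.0
        mask = top_gene_mask(X, 0.2)
        np.testing.assert_array_equal(mask.sum(axis=0), np.full(10, 10))

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            X = rng.integers(0, 4, size=(17, 3)).astype(float)
            mask = top_gene_mask(X, 0.3)
            for c in range(3):
                assert set(np.flatnonzero(mask[:, c])) == oracle_top_set(X[:, c], 0.3)


class TestPartnerInTop:
    def test_complex_requires_every_subunit(self):
        top = {"ITGAX", "ITGB2", "THY1"}
        assert partner_in_top(["ITGAX", "ITGB2"], top) == 1
        assert partner_in_top(["ITGB1", "ITGA9"], {"ITGB1"}) == 0
        assert partner_in_top(["VCAN"], {"TLR2"}) == 0

    def test_empty_partner_rejected(self):
        with pytest.raises(ValueError):
            partner_in_top([], {"A"})


class TestScorePair:
    def test_direct_enumeration_example(self):
        # A: L top in both cells, R not; B: R top in 1 of 2 cells, L never
        # paracrine score = (1 + 0.5) / 2 = 0.75
        X = np.array(
            #  a1   a2   b1   b2
            [[9.0, 9.0, 1.0, 1.0],   # L
             [1.0, 1.0, 9.0, 2.0],   # R
             [5.0, 5.0, 5.0, 9.0],
             [4.0, 4.0, 4.0, 5.0],
             [3.0, 3.0, 3.0, 4.0],
             [2.0, 2.0, 2.0, 3.0],
             [1.5, 1.5, 1.5, 2.5],
             [0.5, 0.5, 0.5, 0.6],
             [0.4, 0.4, 0.3, 0.5],
             [0.1, 0.2, 0.2, 0.2]]
        )
        m = _matrix_from(X)
        pair = sx.InteractionPair(("g0",), ("g1",))
        res = sx.score_pair(pair, m, ["c0", "c1"], ["c2", "c3"], t=0.2)
        assert res["score_a"] == 1.0
        assert res["score_b"] == 0.5
        assert res["score"] == 0.75

    def test_both_top_everywhere_kills_paracrine(self):
        X = np.zeros((10, 4)) + 1.0
        X[0, :] = 9.0
        X[1, :] = 8.0
        m = _matrix_from(X)
        pair = sx.InteractionPair(("g0",), ("g1",))
        para = sx.score_pair(pair, m, ["c0", "c1"], ["c2", "c3"], t=0.2, mode="paracrine")
        auto = sx.score_pair(pair, m, ["c0", "c1"], ["c2", "c3"], t=0.2, mode="autocrine")
        assert para["score"] == 0.0
        assert auto["score"] == 1.0

    def test_absent_from_all_top_sets_scores_zero(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 4)) + 1
        X[0, :] = 0.0
        X[1, :] = 0.0
        m = _matrix_from(X)
        pair = sx.InteractionPair(("g0",), ("g1",))
        for mode in ("paracrine", "autocrine"):
            res = sx.score_pair(pair, m, ["c0", "c1"], ["c2", "c3"], t=0.2, mode=mode)
            assert res["score"] == 0.0

    def test_complex_missing_subunit_caps_score_at_half(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 4)) + 1
        X[0, :2] = 9.0   # subunit 1 of ligand complex, top in A
        X[1, :] = 0.0    # subunit 2 never expressed
        X[2, 2:] = 9.0   # receptor top in all B cells
        X[2, :2] = 0.0
        X[0, 2:] = 0.0
        m = _matrix_from(X)
        pair = sx.InteractionPair(("g0", "g1"), ("g2",))
        res = sx.score_pair(pair, m, ["c0", "c1"], ["c2", "c3"], t=0.2)
        assert res["score_a"] == 0.0
        assert res["score_b"] == 1.0
        assert res["score"] == 0.5


class TestScoreTableOracle:
    def test_vectorized_equals_double_loop(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            X, cols_a, cols_b, pa, pb = random_instance(rng)
            m = _matrix_from(X)
            genes = list(m.genes)
            pair = sx.InteractionPair(tuple(genes[i] for i in pa),
                                      tuple(genes[i] for i in pb))
            for mode in ("paracrine", "autocrine"):
                res = sx.score_pair(
                    pair, m, [f"c{j}" for j in cols_a], [f"c{j}" for j in cols_b],
                    t=0.2, mode=mode,
                )
                oa, ob = oracle_score(X, cols_a, cols_b, pa, pb, 0.2, mode)
                assert res["score_a"] == oa
                assert res["score_b"] == ob

    def test_paracrine_bounded_by_autocrine(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            X, cols_a, cols_b, pa, pb = random_instance(rng)
            m = _matrix_from(X)
            genes = list(m.genes)
            pair = sx.InteractionPair(tuple(genes[i] for i in pa),
                                      tuple(genes[i] for i in pb))
            args = (pair, m, [f"c{j}" for j in cols_a], [f"c{j}" for j in cols_b])
            para = sx.score_pair(*args, t=0.25, mode="paracrine")
            auto = sx.score_pair(*args, t=0.25, mode="autocrine")
            assert para["score_a"] <= auto["score_a"] + 1e-12
            assert para["score_b"] <= auto["score_b"] + 1e-12
            assert 0 <= para["score"] <= auto["score"] <= 1

    def test_cluster_and_pair_reversal_symmetry(self):
        rng = np.random.default_rng(17)
        for mode in ("paracrine", "autocrine"):
            X, cols_a, cols_b, pa, pb = random_instance(rng)
            m = _matrix_from(X)
            genes = list(m.genes)
            pair = sx.InteractionPair(tuple(genes[i] for i in pa),
                                      tuple(genes[i] for i in pb))
            rev = sx.InteractionPair(pair.partner_b, pair.partner_a)
            a = [f"c{j}" for j in cols_a]
            b = [f"c{j}" for j in cols_b]
            fwd = sx.score_pair(pair, m, a, b, t=0.3, mode=mode)
            bwd = sx.score_pair(rev, m, b, a, t=0.3, mode=mode)
            assert fwd["score"] == bwd["score"]
            assert fwd["score_a"] == bwd["score_b"]

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(31)
        X, cols_a, cols_b, pa, pb = random_instance(rng)
        m1 = _matrix_from(X)
        m2 = _matrix_from(np.log1p(4 * X))
        genes = list(m1.genes)
        pair = sx.InteractionPair(tuple(genes[i] for i in pa), tuple(genes[i] for i in pb))
        a = [f"c{j}" for j in cols_a]
        b = [f"c{j}" for j in cols_b]
        r1 = sx.score_pair(pair, m1, a, b, t=0.2)
        r2 = sx.score_pair(pair, m2, a, b, t=0.2)
        assert r1["score"] == r2["score"]

    def test_sorted_output_and_unscoreable_dropped(self, tiny_matrix):
        labels = pd.Series(["A", "A", "B", "B"], index=tiny_matrix.cells)
        ca = sx.ClusterAssignment(labels, "A", "B")
        table = sx.InteractionTable(
            [sx.InteractionPair(("g1",), ("g2",)),
             sx.InteractionPair(("g1",), ("MISSING",))]
        )
        res = sx.score_table(tiny_matrix, ca, table, t=0.4)
        assert list(res["pair_id"]) == ["g1_g2"]
        assert (res["score"].diff().dropna() <= 0).all()

    def test_no_scoreable_pairs_raises(self, tiny_matrix):
        labels = pd.Series(["A", "A", "B", "B"], index=tiny_matrix.cells)
        ca = sx.ClusterAssignment(labels, "A", "B")
        table = sx.InteractionTable([sx.InteractionPair(("X",), ("Y",))])
        with pytest.raises(ValueError, match="no scoreable pairs"), pytest.warns(UserWarning):
            sx.score_table(tiny_matrix, ca, table)


class TestBootstrap:
    def test_p_value_bounds_and_determinism(self, planted_dataset, bundled_table):
        matrix, assignment, _, _ = planted_dataset
        res1 = sx.bootstrap_pvalues(matrix, assignment, bundled_table,
                                    n_iter=150, seed=42)
        res2 = sx.bootstrap_pvalues(matrix, assignment, bundled_table,
                                    n_iter=150, seed=42)
        pd.testing.assert_frame_equal(res1, res2)
        assert (res1["p_value"] >= 1 / 151 - 1e-12).all()
        assert (res1["p_value"] <= 1.0 + 1e-12).all()

    def test_score_zero_has_p_one(self, default_cfg, bundled_table):
        # planting with fraction 0 forces both partners out of every top set
        pair = sx.InteractionPair(("APP",), ("FPR2",))
        cfg = dataclasses.replace(
            default_cfg,
            planted_pairs=(PlantedPair(pair, "tumor", "myeloid", 0.0, 0.0),),
        )
        matrix, assignment, _ = sx.generate_dataset(cfg)
        res = sx.bootstrap_pvalues(matrix, assignment, bundled_table,
                                   n_iter=120, seed=1)
        row = res.set_index("pair_id").loc[pair.pair_id]
        assert row["score"] == 0.0
        assert row["p_value"] == 1.0

    def test_pooled_formula_extremes(self):
        null = np.full((999, 3), 0.1)
        p = pooled_empirical_pvalues(np.array([0.5, 0.0]), null)
        assert p[0] == pytest.approx(1 / 1000)  # exceeds every null score
        assert p[1] == pytest.approx(1.0)       # every null >= 0

    def test_planted_pair_significant(self, planted_dataset, bundled_table):
        matrix, assignment, _, pair = planted_dataset
        res = sx.bootstrap_pvalues(matrix, assignment, bundled_table,
                                   n_iter=200, seed=8)
        row = res.set_index("pair_id").loc[pair.pair_id]
        assert row["p_value"] <= 0.05

    def test_low_n_iter_warns(self, tiny_matrix):
        labels = pd.Series(["A", "A", "B", "B"], index=tiny_matrix.cells)
        ca = sx.ClusterAssignment(labels, "A", "B")
        table = sx.InteractionTable([sx.InteractionPair(("g1",), ("g2",))])
        with pytest.warns(UserWarning, match="n_iter"):
            sx.bootstrap_pvalues(tiny_matrix, ca, table, t=0.4, n_iter=50, seed=0)


class TestFilterSignificant:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["pair_id", "score_a", "score_b", "score", "p_value"]
        )

    def test_filter_rules(self):
        df = self._frame(
            [
                ("keep", 0.9, 0.6, 0.75, 0.001),
                ("one_sided", 1.0, 0.0, 0.55, 0.001),
                ("weak_score", 0.5, 0.48, 0.49, 1e-6),
                ("not_significant", 0.9, 0.6, 0.75, 0.2),
                ("boundary_score", 0.5, 0.5, 0.50, 0.001),
            ]
        )
        kept = sx.filter_significant(df)
        assert list(kept["pair_id"]) == ["keep"]

    def test_requires_pvalues(self):
        df = pd.DataFrame({"pair_id": ["a"], "score": [0.9],
                           "score_a": [0.9], "score_b": [0.9]})
        with pytest.raises(ValueError, match="p-values"):
            sx.filter_significant(df)


class TestCrosstalkScorerEstimator:
    def test_fit_and_attributes(self, planted_dataset, bundled_table):
        matrix, _, truth, pair = planted_dataset
        X = matrix.to_frame()
        y = truth.cluster_of.reindex(X.index).to_numpy()
        scorer = sx.CrosstalkScorer(
            bundled_table, cluster_a="tumor", cluster_b="myeloid",
            n_iter=150, random_state=0,
        )
        scorer.fit(X, y)
        assert scorer.results_.iloc[0]["pair_id"] == pair.pair_id
        assert pair.pair_id in set(scorer.significant_["pair_id"])
        assert scorer.clusters_ == ("tumor", "myeloid")
        got = scorer.transform()
        assert got is scorer.results_

    def test_sklearn_param_interface(self, bundled_table):
        scorer = sx.CrosstalkScorer(bundled_table)
        params = scorer.get_params()
        assert params["mode"] == "paracrine"
        scorer.set_params(mode="autocrine", n_iter=0)
        assert scorer.mode == "autocrine"

    def test_two_label_inference_and_errors(self, bundled_table, planted_dataset):
        matrix, _, truth, _ = planted_dataset
        X = matrix.to_frame()
        y = truth.cluster_of.reindex(X.index).to_numpy()
        with pytest.raises(ValueError, match="exactly two"):
            sx.CrosstalkScorer(bundled_table, n_iter=0).fit(X, y)  # 3 clusters
        with pytest.raises(ValueError, match="interaction table"):
            sx.CrosstalkScorer(None).fit(X, y)
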