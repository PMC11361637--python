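"""Tests for tree-ensemble importance and edge filtering."""

import numpy as np
import pandas as pd
import pytest

from mgregen import grn
from mgregen import preprocess as pp


def expr_from(values, gene_ids):
    values = np.asarray(values, dtype=float)
    return pp.ExpressionMatrix(values, gene_ids,
                               [f"c{j}" for j in range(values.shape[1])])


def fast_params(**kw):
    base = dict(n_trees=50, seed=0)
    base.update(kw)
    return grn.GRNParams(**base)


class TestInferImportance:
    @pytest.mark.parametrize("seed", range(10))
    def test_copied_tf_dominates_target(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        tfs = rng.normal(size=(6, n))
        target = tfs[0].copy()
        expr = expr_from(np.vstack([tfs, target]),
                         [f"tf{i}" for i in range(6)] + ["target"])
        imp = grn.infer_importance(expr, [f"tf{i}" for i in range(6)],
                                   fast_params(seed=seed))
        col = imp.values["target"]
        assert col.idxmax() == "tf0"

    def test_noise_target_has_no_dominant_tf(self):
        shares = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 200
            tfs = rng.normal(size=(6, n))
            target = rng.normal(size=n)
            expr = expr_from(np.vstack([tfs, target]),
                             [f"tf{i}" for i in range(6)] + ["noise"])
            imp = grn.infer_importance(expr, [f"tf{i}" for i in range(6)],
                                       fast_params(seed=seed))
            shares.append(imp.values["noise"].max())
        assert np.mean(shares) < 3.0 / 6.0

    def test_importances_sum_to_one_per_target(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(8, 60))
        expr = expr_from(v, [f"g{i}" for i in range(8)])
        imp = grn.infer_importance(expr, ["g0", "g1", "g2"], fast_params())
        sums = imp.values.sum(axis=0, skipna=True)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_self_pairs_excluded(self):
        rng = np.random.default_rng(2)
        expr = expr_from(rng.normal(size=(4, 50)), list("abcd"))
        imp = grn.infer_importance(expr, ["a", "b"], fast_params())
        assert np.isnan(imp.values.loc["a", "a"])
        assert np.isnan(imp.values.loc["b", "b"])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(6, 80))
        expr = expr_from(v, [f"g{i}" for i in range(6)])
        a = grn.infer_importance(expr, ["g0", "g1"], fast_params(seed=7))
        b = grn.infer_importance(expr, ["g0", "g1"], fast_params(seed=7))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_errors(self):
        rng = np.random.default_rng(0)
        expr = expr_from(rng.normal(size=(3, 30)), list("abc"))
        with pytest.raises(ValueError):
            grn.infer_importance(expr, [], fast_params())
        with pytest.raises(KeyError, match="zz"):
            grn.infer_importance(expr, ["a", "zz"], fast_params())
        tiny = expr_from(rng.normal(size=(3, 10)), list("abc"))
        with pytest.raises(ValueError, match="20 cells"):
            grn.infer_importance(tiny, ["a"], fast_params())


def importance_from_scores(scores):
    """One TF, many targets, prescribed scores."""
    df = pd.DataFrame([scores], index=["tf0"],
                      columns=[f"g{i}" for i in range(len(scores))])
    return grn.ImportanceMatrix(df)


class TestQuantileFilter:
    def test_100_distinct_scores_keep_exactly_5(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(0.001, 1.0, 100))
        kept = grn.filter_importance_quantile(importance_from_scores(scores),
                                              0.95)
        assert len(kept) == 5
        assert set(kept["importance"]) == set(np.sort(scores)[-5:])

    def test_all_equal_scores_all_retained(self):
        kept = grn.filter_importance_quantile(
            importance_from_scores(np.full(40, 0.25)), 0.95)
        assert len(kept) == 40

    def test_output_size_non_increasing_in_q(self):
        rng = np.random.default_rng(1)
        imp = importance_from_scores(rng.uniform(size=57))
        sizes = [len(grn.filter_importance_quantile(imp, q))
                 for q in np.linspace(0.05, 0.99, 20)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestEdgeSign:
    def edges(self):
        return pd.DataFrame({"tf": ["tf0"] * 3,
                             "target": ["pos", "neg", "weak"],
                             "importance": [0.5, 0.4, 0.3]})

    def build_expr(self, r_pos=0.05, r_neg=-0.05, r_weak=0.01, n=2000):
        # construct targets with prescribed sample correlation to the TF
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        out = [x]
        for r in (r_pos, r_neg, r_weak):
            e = rng.normal(size=n)
            e = e - e.mean()
            # orthogonalize e against x, then mix to hit r exactly
            e = e - (e @ x) / (x @ x) * x
            e = e / e.std()
            out.append(r * x + np.sqrt(1 - r**2) * e)
        return expr_from(np.vstack(out), ["tf0", "pos", "neg", "weak"])

    def test_threshold_rule(self):
        signed = grn.annotate_edge_sign(self.edges(), self.build_expr(), 0.03)
        by_target = signed.set_index("target")["sign"]
        assert by_target["pos"] == "positive"
        assert by_target["neg"] == "negative"
        assert "weak" not in by_target.index
        assert signed.attrs["n_discarded"] == 1

    def test_boundary_exactly_at_threshold_discarded(self):
        # integer construction with Pearson r = 3/sqrt(4*2500) = 0.03 exactly
        x = np.array([1.0, -1, 1, -1, 0, 0, 0, 0])
        y = np.array([2.0, 0, 1, 0, -43, 21, 13, 6])
        expr = expr_from(np.vstack([x, y, -y]), ["tf0", "plus", "minus"])
        edges = pd.DataFrame({"tf": ["tf0", "tf0"],
                              "target": ["plus", "minus"],
                              "importance": [0.5, 0.5]})
        signed = grn.annotate_edge_sign(edges, expr, 0.03)
        assert len(signed) == 0
        barely = grn.annotate_edge_sign(edges, expr, 0.0299)
        assert set(zip(barely["target"], barely["sign"])) == {
            ("plus", "positive"), ("minus", "negative")}

    def test_zero_variance_gene_discarded(self):
        rng = np.random.default_rng(0)
        v = np.vstack([rng.normal(size=50), np.full(50, 1.0)])
        expr = expr_from(v, ["tf0", "flat"])
        edges = pd.DataFrame({"tf": ["tf0"], "target": ["flat"],
                              "importance": [0.9]})
        signed = grn.annotate_edge_sign(edges, expr, 0.03)
        assert len(signed) == 0
        assert signed.attrs["n_undefined_cor"] == 1


class TestTFExpressedFilter:
    def make_counts(self, tf_counts):
        v = np.vstack([tf_counts, np.ones_like(tf_counts)])
        return pp.CountMatrix(np.asarray(v, dtype=int), ["tf0", "g0"],
                              [f"c{j}" for j in range(len(tf_counts))])

    def edges(self):
        return pd.DataFrame({"tf": ["tf0"], "target": ["g0"],
                             "importance": [0.9], "cor": [0.5],
                             "sign": ["positive"]})

    def test_silent_tf_removed(self):
        counts = self.make_counts([0] * 20)
        labels = np.array(["progenitor"] * 20)
        out = grn.filter_tf_expressed(self.edges(), counts, labels)
        assert len(out) == 0

    def test_ten_percent_detection_retained_at_default_threshold(self):
        counts = self.make_counts([1, 1] + [0] * 18)
        labels = np.array(["progenitor"] * 20)
        out = grn.filter_tf_expressed(self.edges(), counts, labels)
        assert len(out) == 1

    def test_missing_cluster_errors(self):
        counts = self.make_counts([1] * 5)
        with pytest.raises(ValueError):
            grn.filter_tf_expressed(self.edges(), counts,
                                    np.array(["MG"] * 5))


class TestSignedEdgeInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_sign_consistent_with_correlation(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n = 12, 120
        v = rng.normal(size=(n_genes, n))
        genes = [f"g{i}" for i in range(n_genes)]
        expr = expr_from(v, genes)
        tfs = genes[:4]
        edges = pd.DataFrame(
            [(tf, tg, rng.uniform()) for tf in tfs for tg in genes[4:]],
            columns=["tf", "target", "importance"],
        )
        thr = rng.uniform(0.01, 0.2)
        signed = grn.annotate_edge_sign(edges, expr, thr)
        pos = signed[signed["sign"] == "positive"]
        neg = signed[signed["sign"] == "negative"]
        assert (pos["cor"] > thr).all()
        assert (neg["cor"] < -thr).all()
        assert (signed["cor"].abs() > thr).all()
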