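"""Tests for QC, normalization, HVG selection and marker statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgregen import preprocess as pp


def toy_counts(values, prefix=("g", "c")):
    values = np.asarray(values)
    genes = [f"{prefix[0]}{i}" for i in range(values.shape[0])]
    cells = [f"{prefix[1]}{j}" for j in range(values.shape[1])]
    return pp.CountMatrix(values, genes, cells)


class TestQCFilter:
    def test_low_complexity_cell_removed(self):
        # cell 0: 150 detected genes; cell 1: 250 detected genes, both deep
        v = np.zeros((300, 2), dtype=int)
        v[:150, 0] = 10
        v[:250, 1] = 10
        out = pp.qc_filter(toy_counts(v), pp.QCParams(min_cells_per_gene=0))
        assert out.cell_ids == ["c1"]

    def test_empty_matrix_passes_through(self):
        out = pp.qc_filter(toy_counts(np.zeros((0, 0), dtype=int)))
        assert out.n_genes == 0 and out.n_cells == 0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(4)
        v = rng.poisson(2.0, size=(20, 15))
        params = pp.QCParams(min_genes_per_cell=8, min_umis_per_cell=20,
                             min_cells_per_gene=3)
        out = pp.qc_filter(toy_counts(v), params)
        # independent exhaustive recount
        keep_cells = [
            j for j in range(15)
            if sum(v[i, j] > 0 for i in range(20)) >= 8
            and sum(v[:, j]) >= 20
        ]
        keep_genes = [
            i for i in range(20)
            if sum(v[i, j] > 0 for j in keep_cells) >= 3
        ]
        assert out.cell_ids == [f"c{j}" for j in keep_cells]
        assert out.gene_ids == [f"g{i}" for i in keep_genes]
        np.testing.assert_array_equal(out.values,
                                      v[np.ix_(keep_genes, keep_cells)])

    def test_all_cells_removed_gives_warned_empty_result(self):
        v = np.ones((5, 3), dtype=int)
        with pytest.warns(UserWarning):
            out = pp.qc_filter(toy_counts(v),
                               pp.QCParams(min_umis_per_cell=100))
        assert out.n_cells == 0
        assert out.warnings_

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.poisson(1.5, size=(15, 12))
        params = pp.QCParams(min_genes_per_cell=4, min_umis_per_cell=8,
                             min_cells_per_gene=2)
        once = pp.qc_filter(toy_counts(v), params)
        if once.n_cells == 0:
            return
        twice = pp.qc_filter(once, params)
        assert once.gene_ids == twice.gene_ids
        assert once.cell_ids == twice.cell_ids
        np.testing.assert_array_equal(once.values, twice.values)


class TestNormalizeLog:
    def test_hand_arithmetic(self):
        cm = toy_counts([[1], [1], [2]])
        out = pp.normalize_log(cm, scale=4)
        np.testing.assert_allclose(out.values[:, 0],
                                   [np.log1p(1), np.log1p(1), np.log1p(2)])

    def test_all_zero_gene_stays_zero(self):
        cm = toy_counts([[0, 0], [3, 5]])
        out = pp.normalize_log(cm)
        assert (out.values[0] == 0).all()

    def test_depth_invariance_within_cell(self):
        cm1 = toy_counts([[1], [2], [3]])
        cm2 = toy_counts([[2], [4], [6]])
        np.testing.assert_allclose(pp.normalize_log(cm1).values,
                                   pp.normalize_log(cm2).values)

    def test_zero_total_cell_error_names_cell(self):
        cm = toy_counts([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="c1"):
            pp.normalize_log(cm)


class TestSelectHVG:
    def test_tiny_ranking_matches_variance_sort(self):
        rng = np.random.default_rng(0)
        scales = [0.1, 2.0, 0.5, 3.0, 1.0]
        v = np.stack([rng.normal(0, s, size=50) for s in scales])
        norm = pp.ExpressionMatrix(v, [f"g{i}" for i in range(5)],
                                   [f"c{j}" for j in range(50)])
        ranked = pp.select_hvg(norm, 5)
        expected = [f"g{i}" for i in np.argsort(-v.var(axis=1), kind="stable")]
        assert ranked == expected

    def test_constant_gene_never_outranks_variable_gene(self):
        rng = np.random.default_rng(1)
        v = np.vstack([np.full(40, 3.0), rng.normal(3.0, 1.0, size=(9, 40))])
        norm = pp.ExpressionMatrix(v, [f"g{i}" for i in range(10)],
                                   [f"c{j}" for j in range(40)])
        assert pp.select_hvg(norm, 9)[-1] != "g0"
        assert pp.select_hvg(norm, 10)[-1] == "g0"

    def test_requesting_too_many_genes_errors(self):
        norm = pp.ExpressionMatrix(np.zeros((3, 4)), list("abc"), list("wxyz"))
        with pytest.raises(ValueError):
            pp.select_hvg(norm, 4)


def _exact_rank_sum_p(x, y):
    """Enumerate all C(n+m, n) group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2
    stats_ = [
        abs(sum(ranks[list(idx)]) - mean)
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    return float(np.mean([s >= abs(obs - mean) - 1e-12 for s in stats_]))


class TestRankSumMarkers:
    def make_norm(self, a, b):
        v = np.hstack([a, b])
        genes = [f"g{i}" for i in range(v.shape[0])]
        cells = [f"c{j}" for j in range(v.shape[1])]
        labels = ["A"] * a.shape[1] + ["B"] * b.shape[1]
        return pp.ExpressionMatrix(v, genes, cells), np.array(labels)

    def test_identical_groups_yield_no_tested_genes(self):
        block = np.tile(np.linspace(0.5, 2.0, 6), (4, 1))
        norm, labels = self.make_norm(block, block)
        out = pp.rank_sum_markers(norm, labels, pp.DEGParams.condition_degs())
        assert len(out) == 0

    def test_separated_4v4_matches_exact_enumeration(self):
        a = np.array([[1.0, 1.1, 1.2, 1.3]])
        b = np.array([[2.0, 2.1, 2.2, 2.3]])
        norm, labels = self.make_norm(a, b)
        out = pp.rank_sum_markers(
            norm, labels, pp.DEGParams(logfc_threshold=0.0, min_pct=0.0,
                                       adjust="none"),
            groups=["A"], reference="B",
        )
        expected = _exact_rank_sum_p(a[0], b[0])
        assert expected == pytest.approx(2 / 70)
        assert out["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_null_calibration(self):
        # two-group null: fraction of raw p < 0.05 stays at the nominal level
        rng = np.random.default_rng(12)
        v = rng.normal(size=(5000, 200))
        norm = pp.ExpressionMatrix(v, [f"g{i}" for i in range(5000)],
                                   [f"c{j}" for j in range(200)])
        labels = np.array(["A"] * 100 + ["B"] * 100)
        out = pp.rank_sum_markers(
            norm, labels,
            pp.DEGParams(logfc_threshold=0.0, min_pct=0.0, adjust="none"),
            groups=["A"], reference="B",
        )
        frac = (out["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_direction_recovery_on_planted_effects(self):
        rng = np.random.default_rng(21)
        n_genes, n = 200, 60
        base = rng.normal(1.0, 0.2, size=(n_genes, 2 * n)).clip(min=0.01)
        direction = rng.choice([-1.0, 1.0], size=n_genes)
        planted = np.expm1(base.copy())
        planted[:, n:] *= np.where(direction > 0, 2.0, 0.5)[:, None]
        v = np.log1p(planted)
        norm = pp.ExpressionMatrix(v, [f"g{i}" for i in range(n_genes)],
                                   [f"c{j}" for j in range(2 * n)])
        labels = np.array(["ref"] * n + ["alt"] * n)
        out = pp.rank_sum_markers(
            norm, labels, pp.DEGParams.condition_degs(),
            groups=["alt"], reference="ref",
        )
        merged = out.set_index("gene")["log2fc"]
        idx = [int(g[1:]) for g in merged.index]
        agree = np.mean(np.sign(merged.to_numpy()) == direction[idx])
        assert agree >= 0.95

    def test_bh_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(50, 40))
        v[:10, 20:] += 2.0
        norm = pp.ExpressionMatrix(v, [f"g{i}" for i in range(50)],
                                   [f"c{j}" for j in range(40)])
        labels = np.array(["A"] * 20 + ["B"] * 20)
        out = pp.rank_sum_markers(
            norm, labels,
            pp.DEGParams(logfc_threshold=0.0, min_pct=0.0, adjust="BH"),
            groups=["B"], reference="A",
        )
        srt = out.sort_values("p")
        assert (srt["p_adj"].to_numpy() <= 1.0).all()
        assert (np.diff(srt["p_adj"].to_numpy()) >= -1e-12).all()
        assert (srt["p_adj"].to_numpy() >= srt["p"].to_numpy() - 1e-12).all()

    def test_tiny_group_rejected(self):
        norm = pp.ExpressionMatrix(np.ones((3, 3)), list("abc"),
                                   ["c0", "c1", "c2"])
        with pytest.raises(ValueError):
            pp.rank_sum_markers(norm, np.array(["A", "A", "B"]),
                                pp.DEGParams())
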