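"""Network construction primitives: correlation, adjacency, TOM, clustering,
eigengenes, module merging and membership."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from rfinet.coexpression import (
    GREY,
    CoexpressionNetwork,
    NetworkParams,
    adjacency,
    average_linkage_dendrogram,
    correlation_matrix,
    cut_tree_to_modules,
    merge_close_modules,
    module_eigengenes,
    module_membership,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)


def _expr(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def _two_block_expr(rng, n_per_block=20, n_samples=12, noise=0.1):
    z1, z2 = rng.normal(size=n_samples), rng.normal(size=n_samples)
    rows = [z1 + noise * rng.normal(size=n_samples) for _ in range(n_per_block)]
    rows += [z2 + noise * rng.normal(size=n_samples) for _ in range(n_per_block)]
    return _expr(rows)


class TestCorrelationMatrix:
    def test_duplicated_feature_r_one(self, rng):
        x = rng.normal(size=10)
        r = correlation_matrix(_expr([x, x]))
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_feature_r_minus_one(self, rng):
        x = rng.normal(size=10)
        r = correlation_matrix(_expr([x, -x]))
        assert r.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        m = _expr(rng.normal(size=(8, 15)))
        r = correlation_matrix(m).to_numpy()
        arr = m.to_numpy()
        for i in range(8):
            for j in range(8):
                xi = arr[i] - arr[i].mean()
                xj = arr[j] - arr[j].mean()
                expected = (xi @ xj) / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_matrix(_expr(rng.normal(size=(4, 2))))


class TestAdjacency:
    def test_extreme_correlations_unsigned(self):
        r = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert np.allclose(adjacency(r, 6), 1.0)

    def test_zero_correlation(self):
        r = np.eye(3)
        a = adjacency(r, 6)
        assert np.allclose(a[~np.eye(3, dtype=bool)], 0.0)

    def test_elementwise_oracle(self, rng):
        r = np.clip(rng.uniform(-1, 1, size=(6, 6)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        a_u = adjacency(r, 5, signed=False)
        a_s = adjacency(r, 5, signed=True)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                assert a_u[i, j] == pytest.approx(abs(r[i, j]) ** 5)
                assert a_s[i, j] == pytest.approx(((1 + r[i, j]) / 2) ** 5)


class TestTOM:
    def test_two_node_collapses_to_adjacency(self):
        a = np.array([[1.0, 0.37], [0.37, 1.0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.37)

    def test_complete_graph_is_all_ones(self):
        a = np.ones((5, 5))
        assert np.allclose(tom_similarity(a), 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        k = a.sum(axis=1) - 1.0
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(
                    a[i, u] * a[u, j] for u in range(6) if u not in (i, j)
                )
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_values_in_unit_interval(self, rng):
        a = rng.uniform(0, 1, size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError):
            tom_similarity(a)


class TestUPGMA:
    def test_hand_computed_four_points(self):
        # distances: d(0,1)=1, d(2,3)=2, cross pairs 8,9,10,9.
        # UPGMA: merge (0,1)@1, then (2,3)@2, then clusters@(8+9+10+9)/4=9
        d = np.array(
            [
                [0.0, 1.0, 8.0, 9.0],
                [1.0, 0.0, 10.0, 9.0],
                [8.0, 10.0, 0.0, 2.0],
                [9.0, 9.0, 2.0, 0.0],
            ]
        )
        Z = average_linkage_dendrogram(d)
        assert Z[0][:3].tolist() == [0.0, 1.0, 1.0]
        assert Z[1][:3].tolist() == [2.0, 3.0, 2.0]
        assert Z[2][2] == pytest.approx(9.0)

    def test_heights_nondecreasing(self, rng):
        x = rng.normal(size=(12, 5))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        Z = average_linkage_dendrogram(d)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_singleton_input(self):
        assert average_linkage_dendrogram(np.zeros((1, 1))).shape == (0, 4)

    def test_two_blocks_merge_last(self, rng):
        expr = _two_block_expr(rng)
        tom = tom_similarity(adjacency(correlation_matrix(expr).to_numpy(), 6))
        Z = average_linkage_dendrogram(1 - tom)
        # the final merge joins the two blocks, far above within-block heights
        assert Z[-1, 2] > np.median(Z[:-1, 2]) * 1.5


class TestCutTree:
    def test_two_planted_blocks_fully_assigned(self, rng):
        expr = _two_block_expr(rng)
        tom = tom_similarity(adjacency(correlation_matrix(expr).to_numpy(), 6))
        Z = average_linkage_dendrogram(1 - tom)
        labels = cut_tree_to_modules(Z, expr.index, 5, cut_height_quantile=0.98)
        assert (labels != GREY).all()
        assert labels.nunique() == 2
        # block membership respected
        first = labels.iloc[:20]
        second = labels.iloc[20:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_all_grey_when_below_min_size(self, rng):
        expr = _expr(rng.normal(size=(4, 10)))
        tom = tom_similarity(adjacency(correlation_matrix(expr).to_numpy(), 6))
        Z = average_linkage_dendrogram(1 - tom)
        with pytest.warns(UserWarning):
            labels = cut_tree_to_modules(Z, expr.index, 30, 0.5)
        assert (labels == GREY).all()

    def test_color_names_by_size(self, rng):
        expr = _two_block_expr(rng, n_per_block=10)
        extra = _two_block_expr(rng, n_per_block=15)  # bigger blocks
        both = pd.concat(
            [expr.iloc[:10], extra.iloc[:15].set_index(pd.Index([f"g{i}" for i in range(15)]))]
        )
        tom = tom_similarity(adjacency(correlation_matrix(both).to_numpy(), 6))
        Z = average_linkage_dendrogram(1 - tom)
        labels = cut_tree_to_modules(Z, both.index, 5, 0.98)
        sizes = labels[labels != GREY].value_counts()
        if len(sizes) >= 2:
            assert sizes.index[0] == "turquoise"
            assert sizes.index[1] == "blue"


class TestEigengenes:
    def test_identical_profiles_var_explained_one(self, rng):
        x = rng.normal(size=12)
        expr = _expr([x, x, x])
        labels = pd.Series(["blue"] * 3, index=expr.index)
        eig = module_eigengenes(expr, labels)
        assert eig.var_explained["blue"] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        me = eig.profiles.loc["blue"].to_numpy()
        assert np.allclose(np.abs(np.corrcoef(me, z)[0, 1]), 1.0)

    def test_unit_norm(self, rng):
        expr = _expr(rng.normal(size=(10, 8)))
        labels = pd.Series(["blue"] * 10, index=expr.index)
        eig = module_eigengenes(expr, labels)
        assert np.linalg.norm(eig.profiles.loc["blue"]) == pytest.approx(1.0)

    def test_orientation_sign_convention(self, rng):
        expr = _two_block_expr(rng, n_per_block=10)
        labels = pd.Series(["blue"] * 20, index=expr.index)
        labels.iloc[10:] = "brown"
        eig = module_eigengenes(expr, labels)
        negated = module_eigengenes(-expr, labels)
        mm = module_membership(expr, eig)
        # mean member correlation is nonnegative for each module
        for mod in eig.modules():
            members = labels[labels == mod].index
            assert mm.loc[members, mod].mean() >= 0
        mm_neg = module_membership(-expr, negated)
        for mod in negated.modules():
            members = labels[labels == mod].index
            assert mm_neg.loc[members, mod].mean() >= 0

    def test_matches_power_iteration_oracle(self, rng):
        expr = _expr(rng.normal(size=(9, 11)))
        labels = pd.Series(["blue"] * 9, index=expr.index)
        eig = module_eigengenes(expr, labels)
        z = expr.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        # power iteration on z^T z for the first right singular vector
        v = rng.normal(size=11)
        for _ in range(2000):
            v = z.T @ (z @ v)
            v /= np.linalg.norm(v)
        me = eig.profiles.loc["blue"].to_numpy()
        assert np.allclose(np.abs(me @ v), 1.0, atol=1e-8)

    def test_constant_member_excluded_with_warning(self, rng):
        rows = rng.normal(size=(3, 10))
        rows[1] = 4.2
        expr = _expr(rows)
        labels = pd.Series(["blue"] * 3, index=expr.index)
        with pytest.warns(UserWarning, match="constant"):
            eig = module_eigengenes(expr, labels)
        assert "blue" in eig.modules()


class TestMergeModules:
    def test_duplicated_module_merged(self, rng):
        z = rng.normal(size=10)
        rows = [z + 0.05 * rng.normal(size=10) for _ in range(12)]
        expr = _expr(rows)
        labels = pd.Series(["blue"] * 6 + ["brown"] * 6, index=expr.index)
        merged, eig = merge_close_modules(expr, labels)
        assert merged.nunique() == 1
        assert len(eig.modules()) == 1

    def test_orthogonal_modules_untouched(self, rng):
        expr = _two_block_expr(rng, n_per_block=8)
        labels = pd.Series(["blue"] * 8 + ["brown"] * 8, index=expr.index)
        merged, _ = merge_close_modules(expr, labels)
        assert merged.nunique() == 2

    def test_chain_of_close_modules_collapses(self, rng):
        z = rng.normal(size=20)
        rows = []
        for shift in (0.0, 0.3, 0.6):  # three mutually correlated signals
            for _ in range(6):
                rows.append(z + shift * rng.normal(size=20) * 0.5 + 0.05 * rng.normal(size=20))
        expr = _expr(rows)
        labels = pd.Series(
            ["blue"] * 6 + ["brown"] * 6 + ["yellow"] * 6, index=expr.index
        )
        merged, _ = merge_close_modules(expr, labels, merge_height=0.25)
        assert merged.nunique() == 1


class TestModuleMembership:
    def test_perfect_member_mm_one(self, rng):
        x = rng.normal(size=10)
        expr = _expr([x, x, 2 * x + 1])
        labels = pd.Series(["blue"] * 3, index=expr.index)
        eig = module_eigengenes(expr, labels)
        mm = module_membership(expr, eig)
        assert mm.loc["f2", "blue"] == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self, rng):
        expr = _expr(rng.normal(size=(20, 9)))
        labels = pd.Series(["blue"] * 10 + ["brown"] * 10, index=expr.index)
        eig = module_eigengenes(expr, labels)
        mm = module_membership(expr, eig)
        assert (mm.to_numpy() >= -1 - 1e-12).all()
        assert (mm.to_numpy() <= 1 + 1e-12).all()

    def test_matches_pearson_oracle(self, rng):
        expr = _expr(rng.normal(size=(6, 12)))
        labels = pd.Series(["blue"] * 6, index=expr.index)
        eig = module_eigengenes(expr, labels)
        mm = module_membership(expr, eig)
        me = eig.profiles.loc["blue"].to_numpy()
        for f in expr.index:
            expected = np.corrcoef(expr.loc[f], me)[0, 1]
            assert mm.loc[f, "blue"] == pytest.approx(expected, abs=1e-12)


class TestSoftThreshold:
    def test_smallest_power_reaching_target(self, rng):
        # strong modular structure reaches the scale-free target quickly;
        # the chosen beta must be the first candidate whose fit passes
        expr = _two_block_expr(rng, n_per_block=30, noise=0.3)
        beta, table = pick_soft_threshold(expr, (1, 2, 3, 4, 5, 6, 7, 8), 0.8)
        passing = table[table["fit"] >= 0.8]
        if len(passing):
            assert beta == passing["power"].iloc[0]
        else:
            assert beta == table.loc[table["fit"].idxmax(), "power"]

    def test_no_power_reaches_target_warns_argmax(self, rng):
        expr = _expr(rng.normal(size=(30, 10)))
        with pytest.warns(UserWarning, match="argmax"):
            beta, table = pick_soft_threshold(expr, (1, 2), target_r2=0.999)
        assert beta == table.loc[table["fit"].idxmax(), "power"]

    def test_regression_against_lstsq_oracle(self, rng):
        k = np.abs(rng.normal(size=200)) + 0.1
        fit, slope = scale_free_fit(k, n_bins=10)
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            mask = idx == b
            if mask.any():
                xs.append(np.log10(k[mask].mean()))
                ys.append(np.log10(mask.mean()))
        A = np.column_stack([xs, np.ones(len(xs))])
        coef, res_, *_ = np.linalg.lstsq(A, ys, rcond=None)
        pred = A @ coef
        ss_res = ((np.array(ys) - pred) ** 2).sum()
        ss_tot = ((np.array(ys) - np.mean(ys)) ** 2).sum()
        assert slope == pytest.approx(coef[0], abs=1e-10)
        assert fit == pytest.approx(-np.sign(coef[0]) * (1 - ss_res / ss_tot), abs=1e-10)

    def test_unsorted_candidates_rejected(self, rng):
        expr = _expr(rng.normal(size=(10, 8)))
        with pytest.raises(ValueError):
            pick_soft_threshold(expr, (6, 2))


class TestNetworkModel:
    def test_determinism(self, rng):
        expr = _two_block_expr(rng, n_per_block=15)
        params = NetworkParams(min_module_size=5)
        r1 = CoexpressionNetwork(expr, params).fit()
        r2 = CoexpressionNetwork(expr, params).fit()
        pd.testing.assert_series_equal(r1.assignment, r2.assignment)
        pd.testing.assert_frame_equal(r1.eigengenes.profiles, r2.eigengenes.profiles)

    def test_two_block_structure_recovered(self, rng):
        expr = _two_block_expr(rng, n_per_block=20, n_samples=15)
        res = CoexpressionNetwork(expr, NetworkParams(min_module_size=5)).fit()
        assert len(res.modules) == 2
        lab = res.assignment
        assert lab.iloc[:20].nunique() == 1
        assert lab.iloc[20:].nunique() == 1

    def test_few_samples_warns(self, rng):
        expr = _expr(rng.normal(size=(10, 5)))
        with pytest.warns(UserWarning, match="noisy"):
            CoexpressionNetwork(expr)

    def test_summary_mentions_modules(self, rng):
        expr = _two_block_expr(rng, n_per_block=15)
        res = CoexpressionNetwork(expr, NetworkParams(min_module_size=5)).fit()
        assert "modules" in res.summary()
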