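"""Network construction, TOM, module detection, eigengenes, trait stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from coexnet import (
    adjacency,
    cluster_and_cut,
    gene_trait_statistics,
    merge_close_modules,
    module_eigengene,
    module_trait_association,
    scale_free_fit,
    select_variable_genes,
    topological_overlap,
)
from coexnet.network import SmallModuleWarning, _tom_linkage


def _expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(len(values))],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


class TestSelectVariableGenes:
    def test_identity_subset(self, rng):
        expr = _expr(rng.normal(size=(20, 10)))
        assert set(select_variable_genes(expr, k=20)) == set(expr.index)

    def test_constant_gene_never_beats_variable_gene(self, rng):
        expr = _expr(np.vstack([np.full(10, 3.0), rng.normal(size=(5, 10))]))
        assert "g0" not in select_variable_genes(expr, k=5)

    def test_agrees_with_bruteforce_sort(self, rng):
        expr = _expr(rng.normal(size=(50, 12)) * rng.uniform(0.1, 3, size=(50, 1)))
        got = list(select_variable_genes(expr, k=17))
        var = expr.var(axis=1, ddof=1)
        expected = sorted(expr.index, key=lambda g: (-var[g], g))[:17]
        assert got == expected

    def test_invalid_k(self, rng):
        expr = _expr(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            select_variable_genes(expr, k=0)
        with pytest.raises(ValueError):
            select_variable_genes(expr, k=6)


class TestAdjacency:
    def test_perfect_and_anti_correlation_saturate(self):
        s = np.arange(6.0)
        expr = _expr([s, 2 * s + 1, -s])
        a = adjacency(expr, beta=14)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(1.0)  # unsigned network

    def test_direct_power_at_cor_08(self, rng):
        # y = 0.8*x + 0.6*z with z unit-variance and exactly orthogonal to x
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std()
        z = rng.normal(size=50)
        z = z - z.mean() - x * (z @ x) / (x @ x)
        z = z / z.std()
        y = 0.8 * x + 0.6 * z
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.8, abs=1e-12)
        a = adjacency(_expr([x, y]), beta=14)
        assert a[0, 1] == pytest.approx(0.8**14, rel=1e-9)
        assert a[0, 1] == pytest.approx(0.04398, abs=5e-5)

    def test_constant_row_named_in_error(self):
        expr = _expr([[1.0, 1, 1, 1], [0, 1, 2, 3]])
        with pytest.raises(ValueError, match="g0"):
            adjacency(expr)

    def test_raising_beta_weakly_decreases_offdiagonal(self, rng):
        expr = _expr(rng.normal(size=(12, 9)))
        a6 = adjacency(expr, beta=6)
        a14 = adjacency(expr, beta=14)
        off = ~np.eye(12, dtype=bool)
        assert (a14[off] <= a6[off] + 1e-15).all()


def _tom_bruteforce(a):
    n = len(a)
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return tom


class TestTopologicalOverlap:
    def test_clique_saturates(self):
        a = np.ones((3, 3))
        assert topological_overlap(a) == pytest.approx(np.ones((3, 3)))

    def test_empty_network(self):
        a = np.eye(4)
        tom = topological_overlap(a)
        off = ~np.eye(4, dtype=bool)
        assert (tom[off] == 0).all()
        assert (np.diag(tom) == 1).all()

    @given(
        hnp.arrays(
            np.float64,
            st.integers(min_value=2, max_value=8).map(lambda n: (n, n)),
            elements=st.floats(min_value=0.0, max_value=1.0),
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_triple_loop(self, raw):
        a = (raw + raw.T) / 2.0
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom, _tom_bruteforce(a), atol=1e-12)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= -1e-12 and tom.max() <= 1 + 1e-12

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


class TestScaleFreeFit:
    def test_constructed_power_law_fits_well(self, rng):
        """A network whose degree sequence follows p(k) ~ k^-1.5."""
        k = np.round(10 * (1 - rng.uniform(size=4000)) ** (-1 / 0.9)).astype(int)
        k = k[k < 2000]
        # regress directly through the internal fit on the k vector
        from coexnet.network import _fit_power_law

        out = _fit_power_law(k.astype(float), n_bins=10)
        assert out["r_squared"] >= 0.95
        assert out["slope"] < 0
        assert out["sft_index"] == pytest.approx(out["r_squared"])

    def test_equicorrelated_data_is_not_scale_free(self, rng):
        shared = rng.normal(size=20)
        expr = _expr([shared + rng.normal(scale=0.2, size=20) for _ in range(60)])
        out = scale_free_fit(expr, beta_grid=[1.0])
        assert out.loc[0, "r_squared"] < 0.5

    def test_output_length_matches_grid(self, rng):
        expr = _expr(rng.normal(size=(30, 10)))
        grid = [1, 2, 6, 14]
        out = scale_free_fit(expr, beta_grid=grid)
        assert list(out["beta"]) == grid

    def test_negative_beta_rejected(self, rng):
        with pytest.raises(ValueError):
            scale_free_fit(_expr(rng.normal(size=(5, 5))), beta_grid=[-1])


class TestClusterAndCut:
    def test_two_noise_free_blocks_recovered(self):
        d = np.ones((100, 100))
        d[:50, :50] = 0.05
        d[50:, 50:] = 0.05
        np.fill_diagonal(d, 0.0)
        genes = pd.Index([f"g{i:03d}" for i in range(100)])
        ms = cluster_and_cut(d, genes, min_module_size=30, cut_height_frac=0.5)
        labels = ms.labels
        assert set(labels.unique()) == {"M1", "M2"}
        assert labels.iloc[:50].nunique() == 1
        assert labels.iloc[50:].nunique() == 1

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        d = rng.uniform(0.2, 1.0, size=(20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        genes = pd.Index([f"g{i}" for i in range(20)])
        with pytest.warns(SmallModuleWarning):
            ms = cluster_and_cut(d, genes, min_module_size=30)
        assert (ms.labels == "unassigned").all()

    def test_modules_named_by_size_rank(self):
        d = np.ones((90, 90))
        d[:50, :50] = 0.05
        d[50:85, 50:85] = 0.05
        np.fill_diagonal(d, 0)
        genes = pd.Index([f"g{i:02d}" for i in range(90)])
        ms = cluster_and_cut(d, genes, min_module_size=30, cut_height_frac=0.5)
        assert (ms.labels.iloc[:50] == "M1").all()
        assert (ms.labels.iloc[50:85] == "M2").all()
        assert (ms.labels.iloc[85:] == "unassigned").all()


class TestModuleEigengene:
    def test_identical_genes_share_the_standardized_profile(self, rng):
        profile = rng.normal(size=10)
        expr = _expr(np.tile(profile, (5, 1)))
        labels = pd.Series("M1", index=expr.index)
        eig, var = module_eigengene(expr, labels)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.loc["M1"].to_numpy(), z, atol=1e-10)
        assert var["M1"] == pytest.approx(1.0)

    def test_two_gene_module_matches_closed_form(self, rng):
        expr = _expr(rng.normal(size=(2, 8)))
        labels = pd.Series("M1", index=expr.index)
        eig, var = module_eigengene(expr, labels)
        x = (expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True)) / expr.to_numpy().std(
            1, ddof=1, keepdims=True
        )
        r = np.corrcoef(x[0], x[1])[0, 1]
        # 2x2 standardized covariance has eigenvalues 1 +- |r|
        assert var["M1"] == pytest.approx((1 + abs(r)) / 2, abs=1e-10)
        e = (x[0] + np.sign(r) * x[1])  # leading eigvec direction (1, sign(r))
        e = e / e.std(ddof=1)
        got = eig.loc["M1"].to_numpy()
        assert abs(np.corrcoef(got, e)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_follows_module_mean(self, rng):
        expr = _expr(rng.normal(size=(6, 12)) + rng.normal(size=12) * 2)
        labels = pd.Series("M1", index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        xs = (expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True)) / expr.to_numpy().std(1, ddof=1, keepdims=True)
        assert np.corrcoef(eig.loc["M1"], xs.mean(0))[0, 1] >= 0
        flipped = module_eigengene(-expr, labels)[0]
        assert np.corrcoef(flipped.loc["M1"], (-xs).mean(0))[0, 1] >= 0

    def test_single_gene_module(self, rng):
        expr = _expr(rng.normal(size=(1, 6)))
        labels = pd.Series("M1", index=expr.index)
        eig, var = module_eigengene(expr, labels)
        assert var["M1"] == pytest.approx(1.0)


class TestMergeCloseModules:
    def test_split_module_is_reunited(self, rng):
        shared = rng.normal(size=16)
        expr = _expr([shared + rng.normal(scale=0.05, size=16) for _ in range(40)])
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=expr.index)
        ms = merge_close_modules(expr, labels, threshold=0.8)
        assert len(ms.eigengenes) == 1
        assert (ms.labels == "M1").all()

    def test_boundary_correlation_is_strict(self, rng):
        # Two modules built on factors correlated at ~0.79 stay separate.
        f1 = rng.normal(size=400)
        f2 = 0.79 * (f1 - f1.mean()) / f1.std() + np.sqrt(1 - 0.79**2) * rng.normal(size=400)
        expr = _expr(
            [f1 + rng.normal(scale=1e-3, size=400) for _ in range(5)]
            + [f2 + rng.normal(scale=1e-3, size=400) for _ in range(5)]
        )
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=expr.index)
        r = np.corrcoef(f1, f2)[0, 1]
        ms = merge_close_modules(expr, labels, threshold=max(0.8, r + 1e-3))
        assert len(ms.eigengenes) == 2

    def test_convergence_no_retained_pair_above_threshold(self, rng):
        expr = _expr(rng.normal(size=(60, 14)))
        labels = pd.Series(
            [f"A{i}" for i in range(6) for _ in range(10)], index=expr.index
        )
        ms = merge_close_modules(expr, labels, threshold=0.5)
        eig = ms.eigengenes.to_numpy()
        for i in range(len(eig)):
            for j in range(i + 1, len(eig)):
                assert np.corrcoef(eig[i], eig[j])[0, 1] <= 0.5 + 1e-12


class TestTraitStatistics:
    def test_trait_equal_to_eigengene(self, rng):
        eig = pd.DataFrame(
            {"M1": rng.normal(size=10)}, index=[f"s{i}" for i in range(10)]
        ).T
        trait = pd.Series(eig.loc["M1"], index=eig.columns)
        out = module_trait_association(eig, trait)
        assert out.loc["M1", "r_trait"] == pytest.approx(1.0)
        assert out.loc["M1", "p_trait"] == 0.0

    def test_constant_trait_rejected(self, rng):
        eig = pd.DataFrame({"M1": rng.normal(size=8)}, index=[f"s{i}" for i in range(8)]).T
        with pytest.raises(ValueError, match="constant"):
            module_trait_association(eig, pd.Series(1.0, index=eig.columns))

    def test_gene_identical_to_eigengene_has_unit_membership(self, rng):
        profile = rng.normal(size=12)
        expr = _expr(np.tile(profile, (4, 1)))
        labels = pd.Series("M1", index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        trait = pd.Series(rng.integers(0, 2, 12), index=expr.columns).astype(float)
        assoc = gene_trait_statistics(expr, labels, eig, trait)
        np.testing.assert_allclose(
            assoc.gene_table["module_membership"].to_numpy(), 1.0, atol=1e-10
        )

    def test_tiny_module_flagged(self, rng):
        expr = _expr(rng.normal(size=(2, 10)))
        labels = pd.Series("M1", index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        trait = pd.Series(rng.normal(size=10), index=expr.columns)
        with pytest.warns(SmallModuleWarning):
            assoc = gene_trait_statistics(expr, labels, eig, trait)
        assert np.isnan(assoc.module_table.loc["M1", "r_gsmm"])


def test_linkage_heights_are_monotone(rng):
    d = rng.uniform(0.1, 1.0, size=(30, 30))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    z = _tom_linkage(d)
    assert (np.diff(z[:, 2]) >= -1e-12).all()
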