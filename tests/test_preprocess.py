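import numpy as np
import pandas as pd
import pytest

from velodirect import CountDataset, compute_moments, filter_genes, hvg_count_rule, normalize, select_hvgs
from velodirect.errors import ConfigError, EmptyResultError, ProvenanceError
from velodirect.preprocess import dispersion_ranking


def make_ds(spliced, unspliced=None, clusters=None):
    spliced = np.asarray(spliced, dtype=float)
    if unspliced is None:
        unspliced = spliced * 0.2
    n, g = spliced.shape
    cm = pd.DataFrame({"cluster": clusters if clusters is not None else ["c0"] * n},
                      index=[f"cell{i}" for i in range(n)])
    gm = pd.DataFrame(index=[f"g{j}" for j in range(g)])
    return CountDataset(spliced=spliced, unspliced=np.asarray(unspliced, float),
                        cell_meta=cm, gene_meta=gm)


class TestFilterGenes:
    def test_threshold_zero_is_identity(self):
        ds = make_ds(np.arange(12).reshape(3, 4))
        out = filter_genes(ds, 0)
        assert out.n_genes == 4

    def test_gene_needs_both_layers(self):
        # spliced total 5 but unspliced total 0 -> removed at threshold 1
        s = np.array([[5.0, 5.0], [0.0, 5.0]])
        u = np.array([[0.0, 2.0], [0.0, 2.0]])
        out = filter_genes(make_ds(s, u), 1)
        assert list(out.gene_ids) == ["g1"]

    def test_three_gene_enumeration(self):
        # totals (10,10), (10,0), (0,10): only the first survives threshold 1
        s = np.array([[10.0, 10.0, 0.0]])
        u = np.array([[10.0, 0.0, 10.0]])
        out = filter_genes(make_ds(s, u), 1)
        assert list(out.gene_ids) == ["g0"]

    def test_all_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_genes(make_ds(np.ones((2, 2))), 1000)


class TestHvgCountRule:
    @pytest.mark.parametrize("n_cells,expected", [
        (2930, 2000), (3696, 2500), (7202, 3000),   # the three tabulated dataset sizes
        (1, 2000), (2999, 2000), (3000, 2500), (6000, 2500), (6001, 3000),
    ])
    def test_tiers(self, n_cells, expected):
        assert hvg_count_rule(n_cells) == expected

    def test_invalid(self):
        with pytest.raises(ConfigError):
            hvg_count_rule(0)


class TestNormalize:
    def test_equal_totals_unchanged(self):
        s = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        out = normalize(make_ds(s, s.copy()))
        np.testing.assert_allclose(out.spliced, s)
        np.testing.assert_allclose(out.log_spliced, np.log1p(s))

    def test_double_total_cell_halved(self):
        s = np.array([[2.0, 2.0], [2.0, 2.0], [4.0, 4.0]])
        out = normalize(make_ds(s, s.copy()))
        # median total 4 -> third cell scaled by 1/2
        np.testing.assert_allclose(out.spliced[2], [2.0, 2.0])
        np.testing.assert_allclose(out.spliced[0], [2.0, 2.0])

    def test_each_layer_uses_own_totals(self):
        s = np.array([[4.0], [4.0], [8.0]])
        u = np.array([[1.0], [1.0], [1.0]])
        out = normalize(make_ds(s, u))
        np.testing.assert_allclose(out.unspliced, u)  # unspliced already even

    def test_zero_total_cell_warns_sf1(self):
        s = np.array([[0.0, 0.0], [2.0, 2.0], [2.0, 2.0]])
        with pytest.warns(UserWarning, match="zero total"):
            out = normalize(make_ds(s, np.ones_like(s)))
        np.testing.assert_allclose(out.spliced[0], [0.0, 0.0])

    def test_double_normalize_rejected(self):
        out = normalize(make_ds(np.ones((3, 2))))
        with pytest.raises(ProvenanceError):
            normalize(out)


class TestSelectHvgs:
    def _normed(self, spliced):
        return normalize(make_ds(spliced))

    def test_keep_all_when_n_top_large(self):
        ds = self._normed(np.random.default_rng(0).poisson(5, (20, 6)).astype(float))
        out = select_hvgs(ds, 100)
        assert out.n_genes == 6

    def test_high_variance_gene_ranked_first(self):
        # equal per-cell totals (normalization is identity) and exactly equal
        # gene means; g1 has 10x the sd of g0 and must rank first
        n = 48
        a = 0.5 * (-1.0) ** np.arange(n)
        b = 5.0 * (-1.0) ** (np.arange(n) // 2)
        ds = self._normed(np.column_stack([10 + a, 10 + b, 10 - a, 10 - b]))
        assert dispersion_ranking(ds)[0] == 1

    def test_deterministic_repeat(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(8, (40, 15)).astype(float)
        ds = self._normed(x)
        a = select_hvgs(ds, 5)
        b = select_hvgs(ds, 5)
        assert list(a.gene_ids) == list(b.gene_ids)

    def test_monotone_nesting(self):
        rng = np.random.default_rng(3)
        ds = self._normed(rng.poisson(6, (60, 30)).astype(float))
        small = set(select_hvgs(ds, 5).gene_ids)
        big = set(select_hvgs(ds, 12).gene_ids)
        assert small <= big

    def test_agrees_with_scanpy_seurat_flavor(self, sim_ds):
        """Cross-check the dispersion ranking against scanpy's seurat flavor."""
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        ds = normalize(filter_genes(sim_ds.to_count_dataset(), 1))
        n_top = 30
        ours = set(select_hvgs(ds, n_top).gene_ids)

        ad = anndata.AnnData(X=ds.log_spliced.copy())
        ad.var_names = ds.gene_ids
        sc.pp.highly_variable_genes(ad, n_top_genes=n_top, flavor="seurat")
        theirs = set(ad.var_names[ad.var["highly_variable"]])
        overlap = len(ours & theirs) / n_top
        assert overlap >= 0.7


class TestMoments:
    def _normed_ds(self, n=20, g=5, seed=0):
        rng = np.random.default_rng(seed)
        return normalize(make_ds(rng.poisson(10, (n, g)).astype(float) + 1))

    def test_k1_is_identity(self):
        ds = self._normed_ds()
        mom = compute_moments(ds, n_pcs=3, k_neighbors=1)
        np.testing.assert_allclose(mom.Mu, ds.unspliced)
        np.testing.assert_allclose(mom.Ms, ds.spliced)

    def test_constant_gene_moments(self):
        # constant gene in a normalized layer: moments stay constant and the
        # second moment is the square of the first
        s = np.column_stack([np.full(10, 7.0), np.arange(10) + 1.0])
        base = make_ds(s, s.copy())
        ds = CountDataset(spliced=s, unspliced=s.copy(), cell_meta=base.cell_meta,
                          gene_meta=base.gene_meta, normalized=True,
                          log_spliced=np.log1p(s))
        mom = compute_moments(ds, n_pcs=2, k_neighbors=4)
        np.testing.assert_allclose(mom.Ms[:, 0], 7.0)
        np.testing.assert_allclose(mom.Ms2[:, 0], 49.0)

    def test_hand_built_neighbor_means(self):
        # 4 cells in 1-D expression space: neighbors are unambiguous
        s = np.array([[0.0, 10.0], [1.0, 10.0], [10.0, 10.0], [11.0, 10.0]])
        ds = make_ds(s, s * 0.5)
        ds = CountDataset(spliced=s, unspliced=s * 0.5, cell_meta=ds.cell_meta,
                          gene_meta=ds.gene_meta, normalized=True, log_spliced=np.log1p(s))
        mom = compute_moments(ds, n_pcs=2, k_neighbors=2)
        # cells 0,1 mutual; cells 2,3 mutual
        np.testing.assert_allclose(mom.Ms[0, 0], 0.5)
        np.testing.assert_allclose(mom.Ms[2, 0], 10.5)

    def test_moments_are_convex_combinations(self):
        ds = self._normed_ds(n=40, g=8, seed=4)
        mom = compute_moments(ds, n_pcs=5, k_neighbors=7)
        assert np.all(mom.Mu >= ds.unspliced.min(axis=0) - 1e-12)
        assert np.all(mom.Mu <= ds.unspliced.max(axis=0) + 1e-12)

    def test_self_in_neighbor_list(self):
        ds = self._normed_ds(n=15, g=4, seed=5)
        mom = compute_moments(ds, n_pcs=3, k_neighbors=5)
        rows = np.arange(15)
        assert (mom.knn_indices == rows[:, None]).any(axis=1).all()

    def test_bad_k_rejected(self):
        ds = self._normed_ds()
        with pytest.raises(ConfigError):
            compute_moments(ds, k_neighbors=0)
        with pytest.raises(ProvenanceError):
            compute_moments(make_ds(np.ones((5, 3))), k_neighbors=2)
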