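import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from pdecm import singlecell as scm
from tests.conftest import CELL_TYPES


def _toy_adata(rng, n_per_type=50, types=("Fibroblast", "Macrophage")):
    """Two-type matrix with one gene exclusive to each type plus noise genes."""
    n = n_per_type * len(types)
    labels = np.repeat(types, n_per_type)
    # depth-balanced: both types carry the same expected total count, so the
    # per-cell normalization leaves the null genes identically distributed
    genes = ["FIB_ONLY", "MAC_ONLY", "BOTH_HI_MAC", "BOTH_HI_FIB"] + [
        f"N{i}" for i in range(20)
    ]
    counts = rng.poisson(1.0, size=(n, len(genes))).astype(float)
    counts[:, 0] = np.where(labels == "Fibroblast", rng.poisson(20, n), 0)
    counts[:, 1] = np.where(labels == "Macrophage", rng.poisson(20, n), 0)
    counts[:, 2] = np.where(labels == "Macrophage", rng.poisson(30, n), rng.poisson(10, n))
    counts[:, 3] = np.where(labels == "Fibroblast", rng.poisson(30, n), rng.poisson(10, n))
    adata = ad.AnnData(
        X=counts.copy(),
        obs=pd.DataFrame({"cell_type": labels}, index=[f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=genes),
    )
    adata.layers["counts"] = counts
    depth = counts.sum(axis=1, keepdims=True)
    adata.X = np.log1p(counts / depth * 1e4)
    return adata


class TestFindMarkers:
    def test_exclusive_gene_is_specific(self):
        adata = _toy_adata(np.random.default_rng(0), n_per_type=100)
        markers = scm.find_markers(adata)
        row = markers[(markers["gene"] == "FIB_ONLY") & (markers["cell_type"] == "Fibroblast")]
        assert bool(row["specific"].iloc[0])
        assert row["p_adj"].iloc[0] < 1e-10

    def test_p_matches_ranksum_oracle(self):
        adata = _toy_adata(np.random.default_rng(1))
        markers = scm.find_markers(adata)
        x = np.asarray(adata.X)
        fib = (adata.obs["cell_type"] == "Fibroblast").to_numpy()
        j = adata.var_names.get_loc("FIB_ONLY")
        _, p = mannwhitneyu(x[fib, j], x[~fib, j], alternative="two-sided")
        row = markers[(markers["gene"] == "FIB_ONLY") & (markers["cell_type"] == "Fibroblast")]
        assert row["p"].iloc[0] == pytest.approx(p, rel=1e-9)

    def test_null_gene_not_specific(self):
        adata = _toy_adata(np.random.default_rng(2), n_per_type=80)
        markers = scm.find_markers(adata)
        nulls = markers[markers["gene"].str.startswith("N")]
        # identically distributed genes: BH at 0.01 keeps false positives rare
        assert nulls["specific"].mean() <= 0.01 + 1e-9

    def test_all_zero_gene_untested(self):
        adata = _toy_adata(np.random.default_rng(3))
        adata.X[:, 5] = 0.0
        adata.layers["counts"][:, 5] = 0.0
        markers = scm.find_markers(adata)
        rows = markers[markers["gene"] == adata.var_names[5]]
        assert rows["p"].isna().all() and not rows["specific"].any()

    def test_small_type_skipped(self):
        adata = _toy_adata(np.random.default_rng(4), n_per_type=2)
        with pytest.raises(ValueError):
            scm.find_markers(adata[: 2].copy())  # single type left
        markers = scm.find_markers(adata, min_cells=3)
        assert markers.empty or markers["cell_type"].nunique() == 0


class TestAssignOrigin:
    def test_exclusive_gene_assigned(self):
        adata = _toy_adata(np.random.default_rng(5))
        markers = scm.find_markers(adata)
        origins = scm.assign_origin(["FIB_ONLY"], adata, markers)
        assert origins["FIB_ONLY"] == "Fibroblast"

    def test_two_type_specific_goes_to_higher_average(self):
        adata = _toy_adata(np.random.default_rng(6), n_per_type=100)
        markers = scm.find_markers(adata)
        origins = scm.assign_origin(["BOTH_HI_MAC"], adata, markers)
        assert origins["BOTH_HI_MAC"] == "Macrophage"

    def test_uniform_and_absent_unassigned(self):
        adata = _toy_adata(np.random.default_rng(7))
        markers = scm.find_markers(adata)
        origins = scm.assign_origin(["N0", "MISSING"], adata, markers)
        assert origins["N0"] is None and origins["MISSING"] is None

    def test_cell_order_invariance(self):
        adata = _toy_adata(np.random.default_rng(8))
        markers = scm.find_markers(adata)
        shuffled = adata[np.random.default_rng(9).permutation(adata.n_obs)].copy()
        markers2 = scm.find_markers(shuffled)
        genes = ["FIB_ONLY", "MAC_ONLY", "BOTH_HI_MAC"]
        assert scm.assign_origin(genes, adata, markers) == scm.assign_origin(
            genes, shuffled, markers2
        )


class TestOriginFractions:
    def test_all_and_partial(self):
        origins = {f"g{i}": "Fibroblast" for i in range(7)}
        origins.update({f"g{i}": None for i in range(7, 10)})
        fr = scm.origin_fractions(sorted(origins), origins)
        assert fr["Fibroblast"] == pytest.approx(0.7)
        assert fr["unassigned"] == pytest.approx(0.3)
        assert fr.sum() == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            scm.origin_fractions([], {})

    def test_planted_fibroblast_purity(self, sc_data, planted_truth):
        markers = scm.find_markers(sc_data)
        genes = sorted(planted_truth.pem_true)
        origins = scm.assign_origin(genes, sc_data, markers)
        fr = scm.origin_fractions(genes, origins)
        assert fr.get("Fibroblast", 0.0) >= 1.0 - 1e-9  # planted purity is 1


class TestSubcluster:
    def _separated(self, rng, n=120, n_genes=30):
        genes = [f"MAT{i}" for i in range(n_genes)]
        counts = rng.poisson(2.0, size=(n, n_genes)).astype(float)
        counts[n // 2 :, : n_genes // 2] += rng.poisson(25.0, size=(n // 2, n_genes // 2))
        adata = ad.AnnData(
            X=np.log1p(counts),
            obs=pd.DataFrame(
                {"cell_type": ["Fibroblast"] * n}, index=[f"c{i}" for i in range(n)]
            ),
            var=pd.DataFrame(index=genes),
        )
        return adata

    def test_two_planted_populations_recovered(self):
        adata = self._separated(np.random.default_rng(10))
        labels = scm.fibroblast_subcluster(adata, list(adata.var_names), seed=0)
        truth = [0] * 60 + [1] * 60
        assert labels.nunique() == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_resolution_zero_limit_single_cluster(self):
        # homogeneous population (connected neighbor graph): the zero-resolution
        # limit merges everything into one community
        rng = np.random.default_rng(11)
        genes = [f"MAT{i}" for i in range(30)]
        adata = ad.AnnData(
            X=np.log1p(rng.poisson(2.0, size=(100, 30)).astype(float)),
            obs=pd.DataFrame(
                {"cell_type": ["Fibroblast"] * 100}, index=[f"c{i}" for i in range(100)]
            ),
            var=pd.DataFrame(index=genes),
        )
        labels = scm.fibroblast_subcluster(
            adata, list(adata.var_names), resolution=1e-4, seed=0
        )
        assert labels.nunique() == 1

    def test_seed_determinism(self):
        adata = self._separated(np.random.default_rng(12))
        l1 = scm.fibroblast_subcluster(adata, list(adata.var_names), seed=7)
        l2 = scm.fibroblast_subcluster(adata, list(adata.var_names), seed=7)
        assert (l1 == l2).all()

    def test_too_few_features_errors(self):
        adata = self._separated(np.random.default_rng(13))
        with pytest.raises(ValueError, match="feature genes"):
            scm.fibroblast_subcluster(adata, ["MAT0"], seed=0)


class TestScScore:
    def test_planted_subpopulation_scores_higher(self, sc_data, planted_truth):
        fib = sc_data[sc_data.obs["cell_type"] == "Fibroblast"].copy()
        scores = scm.sc_score(fib, planted_truth.pem_true)
        sub = scores[fib.obs["pccnos_like"].to_numpy()]
        rest = scores[~fib.obs["pccnos_like"].to_numpy()]
        assert sub.mean() > rest.mean()


class TestCorrelateWithScore:
    def test_hand_examples_and_exclusions(self):
        counts = np.array(
            [[1.0, 3.0, 5.0], [3.0, 2.0, 1.0], [2.0, 2.0, 2.0], [0.0, 1.0, 2.0]]
        ).T  # 3 cells x 4 genes
        adata = ad.AnnData(
            X=counts.copy(),
            obs=pd.DataFrame(index=["c1", "c2", "c3"]),
            var=pd.DataFrame(index=["up", "down", "flat", "up2"]),
        )
        adata.layers["counts"] = counts
        scores = pd.Series([2.0, 4.0, 6.0], index=["c1", "c2", "c3"])
        out = scm.correlate_with_score(adata, scores, top_k=1)
        assert out["r"].is_monotonic_decreasing
        assert out["top"].sum() == 1

    def test_gene_equal_to_score_r1(self):
        rng = np.random.default_rng(14)
        n = 20
        counts = rng.poisson(5.0, size=(n, 10)).astype(float)
        counts[:, 0] = np.arange(1, n + 1)  # strictly increasing
        adata = ad.AnnData(
            X=counts.copy(),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
            var=pd.DataFrame(index=[f"g{i}" for i in range(10)]),
        )
        adata.layers["counts"] = counts
        depth = counts.sum(axis=1)
        tpm0 = counts[:, 0] / depth * 1e6
        scores = pd.Series(tpm0, index=adata.obs_names)  # equals gene 0 in TPM space
        out = scm.correlate_with_score(adata, scores)
        assert out.loc["g0", "r"] == pytest.approx(1.0)

    def test_frac_positive(self):
        counts = np.array([[0.0, 2.0], [3.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        adata = ad.AnnData(
            X=counts.copy(),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(4)]),
            var=pd.DataFrame(index=["a", "b"]),
        )
        adata.layers["counts"] = counts
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=adata.obs_names)
        out = scm.correlate_with_score(adata, scores)
        assert out.loc["a", "frac_positive"] == pytest.approx(0.5)
        assert out.loc["b", "frac_positive"] == pytest.approx(0.75)
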