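import warnings
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy import stats

import monomac as mm


class TestWardLinkage:
    def test_two_cells_single_merge(self):
        X = np.array([[0.0, 3.0]])  # one gene, two cells
        Z = mm.ward_cluster(X)
        assert Z.shape == (1, 4)
        assert np.isclose(Z[0, 2], 3.0)

    def test_three_collinear_points_merge_closest_first(self):
        # exhaustive check: of the three possible first merges, (0,1) is
        # cheapest for points 0, 1, 10
        X = np.array([[0.0, 1.0, 10.0]])
        Z = mm.ward_cluster(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_duplicate_points_merge_at_zero_height(self):
        X = np.array([[1.0, 1.0, 5.0]])
        Z = mm.ward_cluster(X)
        assert Z[0, 2] == 0.0

    def test_non_finite_values_rejected(self):
        X = np.array([[0.0, np.nan]])
        with pytest.raises(ValueError, match="finite"):
            mm.ward_cluster(X)


class TestDynamicCut:
    def test_two_separated_blobs_give_two_clusters(self, rng):
        X = np.hstack(
            [rng.standard_normal((5, 60)), rng.standard_normal((5, 60)) + 20]
        )
        res = mm.dynamic_cut(mm.ward_cluster(X), X, min_cluster_size=10)
        assert res.n_clusters == 2
        assert len(np.unique(res.labels[:60])) == 1
        assert len(np.unique(res.labels[60:])) == 1

    def test_single_blob_is_one_cluster(self, rng):
        X = rng.standard_normal((5, 120))
        res = mm.dynamic_cut(mm.ward_cluster(X), X, min_cluster_size=10)
        assert res.n_clusters == 1

    def test_min_cluster_size_larger_than_n_rejected(self, rng):
        X = rng.standard_normal((3, 10))
        with pytest.raises(ValueError, match="min_cluster_size"):
            mm.dynamic_cut(mm.ward_cluster(X), X, min_cluster_size=11)

    def test_labels_contiguous_and_complete(self, default_run):
        res = default_run["clusters"]
        assert sorted(np.unique(res.labels)) == list(range(1, res.n_clusters + 1))
        assert len(res.labels) == default_run["counts"].n_cells

    def test_recovers_planted_populations(self, default_run):
        from sklearn.metrics import adjusted_rand_score

        res = default_run["clusters"]
        truth = default_run["truth"]["truth_label"]
        assert abs(res.n_clusters - 5) <= 1
        assert adjusted_rand_score(truth, res.labels) >= 0.8

    def test_permutation_equivariance(self, rng):
        X = np.hstack(
            [rng.standard_normal((4, 40)), rng.standard_normal((4, 40)) + 15]
        )
        res = mm.dynamic_cut(mm.ward_cluster(X), X, min_cluster_size=5)
        perm = rng.permutation(X.shape[1])
        Xp = X[:, perm]
        res_p = mm.dynamic_cut(mm.ward_cluster(Xp), Xp, min_cluster_size=5)
        # cluster ids may differ, but the partition must be identical
        a = pd.Series(res.labels[perm])
        b = pd.Series(res_p.labels)
        assert a.groupby(b).nunique().max() == 1
        assert b.groupby(a).nunique().max() == 1


class TestMarkers:
    def test_exclusive_gene_ranks_first_everywhere(self, rng):
        labels = np.repeat([1, 2, 3], 30)
        X = rng.standard_normal((20, 90)) * 0.1
        X[7, labels == 1] += 5.0  # expressed only in cluster 1
        mt = mm.find_markers(X, labels, [f"g{i}" for i in range(20)])
        assert mt.top_sets[1][0] == "g7"
        for other in (2, 3):
            tab = mt.pairwise[(1, other)]
            assert tab.sort_values(["p", "gene"]).iloc[0]["gene"] == "g7"

    def test_null_pvalues_uniform_under_permutation(self, rng):
        labels = rng.permutation(np.repeat([1, 2], 100))
        X = rng.standard_normal((300, 200))
        mt = mm.find_markers(X, labels, [f"g{i}" for i in range(300)])
        pvals = mt.pairwise[(1, 2)]["p"]
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_planted_monocyte_markers_recovered(self, default_run):
        truth = default_run["truth"]["truth_label"].to_numpy()
        labels = default_run["clusters"].labels
        gene_table = default_run["gene_table"]
        sym = gene_table.set_index("gene_id")["symbol"]
        # focal cluster = the one dominated by Ly6C-high monocytes
        cross = pd.crosstab(labels, truth)
        mono_cluster = cross["mono_ly6c_hi"].idxmax()
        mt = mm.find_markers(
            default_run["logcounts"], labels, default_run["counts"].gene_ids
        )
        top_syms = set(sym.loc[mt.top_sets[mono_cluster]])
        assert top_syms & {"Ccr2", "Ly6c2", "Cd14"}

    def test_singleton_cluster_skipped_with_warning(self, rng):
        labels = np.array([1] * 30 + [2])
        X = rng.standard_normal((10, 31))
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            mt = mm.find_markers(X, labels, [f"g{i}" for i in range(10)])
        assert any("skipped" in str(x.message) for x in w)
        assert (1, 2) not in mt.pairwise


class TestPseudobulkByCluster:
    def test_sums_control_cells(self):
        import scipy.sparse as sp

        cm = mm.CountMatrix(
            sp.csr_matrix(np.array([[1, 3], [2, 4]])), ["g1", "g2"], ["c1", "c2"]
        )
        ct = mm.make_cell_table(["c1", "c2"], "s1", "control")
        prof = mm.pseudobulk_by_cluster(cm, np.array([1, 1]), ct)
        assert prof[1].tolist() == [4, 6]

    def test_non_control_cells_ignored_and_totals_conserved(self, default_run):
        counts = default_run["counts"]
        ct = default_run["cell_table"]
        labels = default_run["clusters"].labels
        prof = mm.pseudobulk_by_cluster(counts, labels, ct)
        is_ctrl = (ct["condition"] == "control").to_numpy()
        assert prof.to_numpy().sum() == counts.values[:, is_ctrl].sum()
        assert prof.shape[1] <= default_run["clusters"].n_clusters

    def test_cluster_without_control_cells_omitted(self):
        import scipy.sparse as sp

        cm = mm.CountMatrix(
            sp.csr_matrix(np.array([[1, 3]])), ["g1"], ["c1", "c2"]
        )
        ct = mm.make_cell_table(["c1", "c2"], "s1", ["control", "cKO"])
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            prof = mm.pseudobulk_by_cluster(cm, np.array([1, 2]), ct)
        assert list(prof.columns) == [1]
        assert any("omitted" in str(x.message) for x in w)


class TestBinarize:
    def _bimodal_profiles(self, rng, n_genes=2000, low=0.5, high=6.0):
        is_high = rng.random(n_genes) < 0.4
        log_vals = np.where(
            is_high, rng.normal(high, 0.4, n_genes), rng.normal(low, 0.3, n_genes)
        )
        cpm_target = np.maximum(2 ** log_vals - 1, 0)
        counts = cpm_target / cpm_target.sum() * 5e6
        return pd.DataFrame({"s1": counts}), is_high

    def test_threshold_between_modes_and_low_error(self, rng):
        profiles, is_high = self._bimodal_profiles(rng)
        expressed, thr = mm.binarize_expression(profiles)
        calls = expressed["s1"].to_numpy()
        # recompute the pooled log2 CPM exactly as the binarizer sees it:
        # the threshold must fall strictly between the two planted modes
        vals = profiles["s1"].to_numpy()
        logx = np.log2(vals / vals.sum() * 1e6 + 1)
        assert logx[~is_high].mean() < thr < logx[is_high].mean()
        assert (calls != is_high).mean() < 0.02

    def test_all_zero_gene_not_expressed(self, rng):
        profiles, _ = self._bimodal_profiles(rng)
        profiles.iloc[0, 0] = 0.0
        expressed, _ = mm.binarize_expression(profiles)
        assert not expressed.iloc[0, 0]

    def test_unimodal_input_falls_back_to_median(self, rng):
        vals = rng.integers(900, 1100, 500).astype(float)
        profiles = pd.DataFrame({"s1": vals})
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            _, thr = mm.binarize_expression(profiles)
        assert any("bimodal" in str(x.message) for x in w)


class TestFisherAnnotation:
    @staticmethod
    def _enumerated_tail(a, b, c, d):
        """Exact one-sided (enrichment) Fisher p by hypergeometric enumeration
        with rational arithmetic."""
        n_total = a + b + c + d
        row1, col1 = a + b, a + c
        denom = comb(n_total, col1)
        p = Fraction(0)
        for k in range(a, min(row1, col1) + 1):
            p += Fraction(comb(row1, k) * comb(n_total - row1, col1 - k), denom)
        return float(p)

    def test_worked_table_matches_enumeration(self):
        q = pd.DataFrame({"c1": [True] * 25 + [True] * 5 + [False] * 15 + [False] * 55})
        r = pd.DataFrame({"ref": [True] * 25 + [False] * 5 + [True] * 15 + [False] * 55})
        q.index = r.index = [f"g{i}" for i in range(100)]
        out = mm.fisher_annotation(q, r, fdr=1.1)
        expected = self._enumerated_tail(25, 5, 15, 55)
        assert np.isclose(out["c1"]["p"].iloc[0], expected, atol=1e-12, rtol=0)

    def test_identical_query_and_reference_rank_first(self, rng):
        genes = [f"g{i}" for i in range(500)]
        truth = rng.random(500) < 0.4
        q = pd.DataFrame({"c1": truth}, index=genes)
        r = pd.DataFrame(
            {"self": truth, "other": rng.random(500) < 0.4}, index=genes
        )
        out = mm.fisher_annotation(q, r)
        assert out["c1"]["reference"].iloc[0] == "self"

    def test_independent_binaries_rarely_significant(self, rng):
        n_sig = 0
        n_seeds = 60
        for seed in range(n_seeds):
            r2 = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(1000)]
            q = pd.DataFrame({"c1": r2.random(1000) < 0.3}, index=genes)
            r = pd.DataFrame({"ref": r2.random(1000) < 0.3}, index=genes)
            out = mm.fisher_annotation(q, r, fdr=0.05)
            n_sig += len(out["c1"]) > 0
        assert n_sig / n_seeds <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_empty_universe_rejected(self):
        q = pd.DataFrame({"c1": [True]}, index=["gA"])
        r = pd.DataFrame({"ref": [True]}, index=["gB"])
        with pytest.raises(ValueError, match="universe"):
            mm.fisher_annotation(q, r)

    def test_infinite_odds_ratio_sorts_first(self):
        genes = [f"g{i}" for i in range(60)]
        # query == reference on a clean split: zero off-diagonals -> infinite OR
        flags = np.array([True] * 20 + [False] * 40)
        q = pd.DataFrame({"c1": flags}, index=genes)
        noisy = flags.copy()
        noisy[0] = False
        noisy[30] = True
        r = pd.DataFrame({"exact": flags, "noisy": noisy}, index=genes)
        out = mm.fisher_annotation(q, r)
        assert out["c1"]["reference"].iloc[0] == "exact"
        assert np.isinf(out["c1"]["odds_ratio"].iloc[0])

    def test_end_to_end_cluster_annotation(self, default_run):
        """Monocyte clusters must annotate to the monocyte reference and
        macrophage clusters to the macrophage reference (top-1)."""
        counts = default_run["counts"]
        labels = default_run["clusters"].labels
        truth = default_run["truth"]["truth_label"].to_numpy()
        profiles = mm.pseudobulk_by_cluster(
            counts, labels, default_run["cell_table"]
        )
        sym = default_run["gene_table"].set_index("gene_id")["symbol"]
        profiles.index = sym.loc[profiles.index].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expressed, _ = mm.binarize_expression(profiles)
            _, ref_expressed, _ = mm.simulate_reference(default_run["design"])
        ann = mm.fisher_annotation(expressed, ref_expressed)
        cross = pd.crosstab(labels, truth)
        for cl in cross.index:
            dominant = cross.loc[cl].idxmax()
            want = "monocyte" if dominant.startswith("mono") else "macrophage"
            assert ann[cl]["reference"].iloc[0] == want
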