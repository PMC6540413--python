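"""Wilcoxon, moderated t, BH FDR, DEG filter, category clustering."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster.hierarchy import fcluster

import rccimmune as ri
from rccimmune.association import (
    AssociationError,
    fit_variance_prior,
    split_groups,
)
from rccimmune.signatures import GeneSignature, SignatureRegistry


def labels_for(n_rec: int, n_non: int) -> pd.Series:
    ids = [f"r{i}" for i in range(n_rec)] + [f"n{i}" for i in range(n_non)]
    return pd.Series(["recurrent"] * n_rec + ["non_recurrent"] * n_non, index=ids)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_minimal_exact_example(self):
        w, p = ri.wilcoxon_rank_sum([1, 2], [3, 4], "less")
        assert w == 3.0
        assert p == pytest.approx(1 / 6)

    def test_identical_samples_two_sided_p_one(self):
        _, p = ri.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], "two_sided")
        assert p == pytest.approx(1.0)

    def test_swap_mirrors_w_and_preserves_two_sided_p(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=14)
        wx, px = ri.wilcoxon_rank_sum(x, y, "two_sided")
        wy, py = ri.wilcoxon_rank_sum(y, x, "two_sided")
        n, m = len(x), len(y)
        null_mean_x = n * (n + m + 1) / 2
        null_mean_y = m * (n + m + 1) / 2
        assert wx - null_mean_x == pytest.approx(-(wy - null_mean_y))
        assert px == pytest.approx(py)

    @pytest.mark.parametrize("alternative", ["two_sided", "less", "greater"])
    def test_exact_matches_scipy_enumeration_all_small_shapes(self, alternative):
        """Independent oracle: scipy's exact Mann-Whitney null, every shape
        with n+m <= 8, tie-free data."""
        rng = np.random.default_rng(2024)
        scipy_alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
        for n, m in itertools.product(range(1, 8), repeat=2):
            if n + m > 8:
                continue
            for _ in range(3):
                x = rng.normal(size=n)
                y = rng.normal(size=m)
                w, p = ri.wilcoxon_rank_sum(x, y, alternative)
                ref = stats.mannwhitneyu(x, y, alternative=scipy_alt[alternative],
                                         method="exact")
                assert w == pytest.approx(ref.statistic + n * (n + 1) / 2)
                assert p == pytest.approx(ref.pvalue), (n, m, alternative)

    def test_normal_approximation_close_to_scipy_with_ties(self, rng):
        x = rng.integers(0, 6, size=20).astype(float)
        y = rng.integers(1, 7, size=25).astype(float)
        _, p = ri.wilcoxon_rank_sum(x, y, "two_sided")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(AssociationError):
            ri.wilcoxon_rank_sum([], [1.0], "less")


# ---------------------------------------------------------------------------
# mean-Z differences
# ---------------------------------------------------------------------------


class TestMeanZDifference:
    def test_equal_groups_zero_delta(self):
        z = pd.DataFrame({"sig": [1.0, -1.0, 1.0, -1.0]},
                         index=["r0", "r1", "n0", "n1"])
        delta = ri.mean_z_difference(z, labels_for(2, 2))
        assert delta["sig"] == pytest.approx(0.0)

    def test_relabeling_swap_negates_delta(self, rng):
        z = pd.DataFrame({"sig": rng.normal(size=8)},
                         index=[f"r{i}" for i in range(3)] + [f"n{i}" for i in range(5)])
        lab = labels_for(3, 5)
        swapped = lab.map({"recurrent": "non_recurrent", "non_recurrent": "recurrent"})
        assert ri.mean_z_difference(z, lab)["sig"] == pytest.approx(
            -ri.mean_z_difference(z, swapped)["sig"]
        )

    def test_planted_negative_effect_gives_negative_delta(self):
        report = ri.pipeline.run_signature_association(
            ri.SimulationConfig(n_samples=125, recurrence_fraction=0.2,
                                effect_map={"T-cell": -1.0}, seed=101)
        )
        assert report.loc["T-cell", "delta_z"] < 0

    def test_empty_group_rejected(self):
        z = pd.DataFrame({"sig": [1.0, 2.0]}, index=["r0", "r1"])
        with pytest.raises(AssociationError):
            ri.mean_z_difference(z, pd.Series(["recurrent", "recurrent"],
                                              index=["r0", "r1"]))


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def deg_fixture():
    rng = np.random.default_rng(77)
    G, n1, n2 = 80, 5, 7
    data = rng.normal(7.0, 1.0, size=(G, n1 + n2))
    data[:6, :n1] += 2.0  # six true positives
    mat = pd.DataFrame(data, index=[f"g{i:03d}" for i in range(G)],
                       columns=[f"r{i}" for i in range(n1)] + [f"n{i}" for i in range(n2)])
    return mat, labels_for(n1, n2)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self, deg_fixture):
        mat, labels = deg_fixture
        mine = ri.moderated_t(mat, labels, d0=0.0)
        rec, non = split_groups(mat.T, labels)
        ref = stats.ttest_ind(rec.T, non.T, axis=1, equal_var=True)
        assert np.allclose(mine["t"], ref.statistic, rtol=1e-12)
        assert np.allclose(mine["p"], ref.pvalue, rtol=1e-12)

    def test_d0_infinite_shares_common_variance(self, deg_fixture):
        mat, labels = deg_fixture
        out = ri.moderated_t(mat, labels, d0=np.inf, s0_2=0.9)
        assert np.allclose(out["s2_post"], 0.9)

    def test_log2fc_is_difference_of_group_means(self, deg_fixture):
        mat, labels = deg_fixture
        out = ri.moderated_t(mat, labels)
        rec, non = split_groups(mat.T, labels)
        expected = rec.mean(axis=0) - non.mean(axis=0)
        assert np.allclose(out["log2fc"], expected.loc[out.index])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(123)
        mat = pd.DataFrame(rng.normal(size=(1000, 20)),
                           columns=labels_for(10, 10).index)
        out = ri.moderated_t(mat, labels_for(10, 10))
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_matches_limma_ebayes(self, deg_fixture, tmp_path):
        """Independent oracle: R/limma lmFit + eBayes on the same matrix."""
        mat, labels = deg_fixture
        n1 = int((labels == "recurrent").sum())
        n2 = len(labels) - n1
        mat_path = tmp_path / "m.tsv"
        out_path = tmp_path / "out.csv"
        mat.to_csv(mat_path, sep="\t")
        script = f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{mat_path}", row.names=1))
design <- cbind(Intercept=1, rec=c(rep(1,{n1}), rep(0,{n2})))
fit <- eBayes(lmFit(m, design))
out <- data.frame(t=fit$t[,"rec"], p=fit$p.value[,"rec"], d0=fit$df.prior)
write.csv(out, "{out_path}")
"""
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out_path, index_col=0)
        mine = ri.moderated_t(mat, labels)
        assert mine.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert np.allclose(mine["t"], ref["t"], rtol=1e-8)
        assert np.allclose(mine["p"], ref["p"], rtol=1e-8)

    def test_zero_variance_gene_excluded(self, deg_fixture):
        mat, labels = deg_fixture
        mat = mat.copy()
        mat.loc["flat"] = 5.0
        out = ri.moderated_t(mat, labels)
        assert "flat" not in out.index

    def test_variance_prior_requires_genes(self):
        with pytest.raises(AssociationError):
            fit_variance_prior(np.array([1.0]), np.array([4.0]))


# ---------------------------------------------------------------------------
# BH FDR and DEG filter
# ---------------------------------------------------------------------------


class TestBH:
    def test_step_up_worked_example(self):
        q = ri.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_and_degenerate(self):
        assert ri.bh_fdr([0.2]).tolist() == [0.2]
        assert np.allclose(ri.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_equivariance(self, pvals, rnd):
        order = list(range(len(pvals)))
        rnd.shuffle(order)
        q = ri.bh_fdr(pvals)
        q_perm = ri.bh_fdr([pvals[i] for i in order])
        assert np.allclose([q[i] for i in order], q_perm)

    def test_out_of_range_rejected(self):
        with pytest.raises(AssociationError):
            ri.bh_fdr([0.5, 1.5])


class TestDEGFilter:
    @pytest.mark.parametrize(
        "fc,q,expected",
        [(1.5, 0.1, False),   # boundary FC is strict
         (2.0, 0.29, True),
         (2.0, 0.3, False),   # boundary q is strict
         (0.5, 0.2, True),    # 2-fold under-expression, symmetric
         (1.4, 0.01, False)],
    )
    def test_strict_symmetric_thresholds(self, fc, q, expected):
        out = ri.deg_filter(pd.Series([fc]), pd.Series([q]))
        assert bool(out.iloc[0]) is expected

    def test_deg_table_reports_planted_genes(self, deg_fixture):
        mat, labels = deg_fixture
        table = ri.deg_table(mat, labels)
        planted = {f"g{i:03d}" for i in range(6)}
        reported = set(table.index[table["reported"]])
        assert len(planted & reported) >= 5     # recovers the planted genes
        assert len(reported - planted) <= 2     # few false positives
        assert {"fold_change", "q", "log2fc", "reported"} <= set(table.columns)


# ---------------------------------------------------------------------------
# clustering of category genes
# ---------------------------------------------------------------------------


class TestGeneZscore:
    def test_row_example_and_idempotence(self):
        mat = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["g"])
        z = ri.gene_zscore(mat)
        assert z.loc["g"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        pd.testing.assert_frame_equal(ri.gene_zscore(z), z)

    def test_constant_row_rejected(self):
        mat = pd.DataFrame({"a": [1.0, 5.0], "b": [1.0, 6.0]}, index=["flat", "ok"])
        with pytest.raises(AssociationError, match="flat"):
            ri.gene_zscore(mat)


class TestCategoryGeneSet:
    def test_shared_genes_excluded(self):
        reg = SignatureRegistry([
            GeneSignature("A", frozenset({"g1", "g2"}), "response_category"),
            GeneSignature("B", frozenset({"g2", "g3"}), "response_category"),
        ])
        assert ri.category_gene_set(reg) == ["g1", "g3"]

    def test_disjoint_is_plain_union(self):
        reg = SignatureRegistry([
            GeneSignature("A", frozenset({"g1"}), "response_category"),
            GeneSignature("B", frozenset({"g2"}), "response_category"),
        ])
        assert ri.category_gene_set(reg) == ["g1", "g2"]

    def test_everything_shared_is_error(self):
        reg = SignatureRegistry([
            GeneSignature("A", frozenset({"g1"}), "response_category"),
            GeneSignature("B", frozenset({"g1"}), "response_category"),
        ])
        with pytest.raises(AssociationError):
            ri.category_gene_set(reg)

    def test_panel_overlap_exclusion_leaves_work(self, default_panel):
        genes = ri.category_gene_set(default_panel.signatures)
        union = set().union(
            *(s.genes for s in default_panel.signatures.of_kind("response_category"))
        )
        assert 0 < len(genes) < len(union)


def brute_force_complete_linkage(points: np.ndarray):
    """O(n^3) agglomeration oracle, lowest-index pair on ties."""
    clusters = [[i] for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a] for j in clusters[b]
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((d, sorted(clusters[a] + clusters[b])))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [
            sorted(clusters[a] + clusters[b])
        ]
    return merges


class TestHierarchicalCluster:
    def test_first_merge_joins_closest_pair(self):
        mat = pd.DataFrame({"s1": [0.0], "s2": [1.0], "s3": [10.0]}, index=["g"])
        mat = pd.concat([mat, mat * 0.5])  # need >=2 rows
        mat.index = ["g1", "g2"]
        result = ri.hierarchical_cluster(mat)
        # columns s1 and s2 (distance ~1.1) merge before s3 joins
        assert result.col_heights[0] < result.col_heights[1]
        first_two = set(result.col_order[:2]) | set(result.col_order[-2:])
        assert {0, 1} <= first_two

    def test_duplicated_sample_merges_at_height_zero(self, rng):
        arr = rng.normal(size=(5, 3))
        mat = pd.DataFrame(np.hstack([arr, arr[:, [0]]]),
                           columns=["a", "b", "c", "a_dup"])
        result = ri.hierarchical_cluster(mat)
        assert result.col_heights[0] == pytest.approx(0.0)

    def test_matches_bruteforce_and_permutation_invariant(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(6, 4))
            mat = pd.DataFrame(pts.T)  # 6 columns to cluster
            result = ri.hierarchical_cluster(mat)
            oracle = brute_force_complete_linkage(pts)
            assert np.allclose(result.col_heights, [m[0] for m in oracle])
            # permuting input columns: same merge heights
            perm = rng.permutation(6)
            permuted = ri.hierarchical_cluster(mat.iloc[:, perm])
            assert np.allclose(result.col_heights, permuted.col_heights)

    def test_deterministic_and_heights_monotone(self, rng):
        mat = pd.DataFrame(rng.normal(size=(20, 12)))
        a = ri.hierarchical_cluster(mat, n_flat_clusters=3)
        b = ri.hierarchical_cluster(mat, n_flat_clusters=3)
        assert a.row_order == b.row_order and a.col_labels == b.col_labels
        assert np.all(np.diff(a.row_heights) >= -1e-12)
        assert sorted(set(a.col_labels)) == [1, 2, 3]

    def test_non_finite_rejected(self):
        mat = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(AssociationError):
            ri.hierarchical_cluster(mat)
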