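"""Bi-standardization, per-protein regression, p-value adjustment, PCA,
two-stage clustering and enrichment statistics."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from albh3 import ProteomicsSimConfig
from albh3.proteomics import (
    GeneSetCollection,
    ProteomicsError,
    ProteomicsMatrix,
    adjust_pvalues,
    bistandardize,
    cluster_two_stage,
    fit_protein_regressions,
    gsea_permutation,
    ora_enrichment,
    pca,
    read_gmt,
)
from albh3.simulate import simulate_proteomics


def make_matrix(values: np.ndarray, times=None) -> ProteomicsMatrix:
    n_prot, n_samp = values.shape
    half = n_samp // 2
    times = list(times) if times is not None else list(range(n_samp))
    cell_lines = ["ALMC1"] * half + ["ALMC2"] * (n_samp - half)
    meta = pd.DataFrame(
        {"cell_line": cell_lines, "time_h": [float(t) for t in times[:n_samp]]},
        index=pd.Index([f"s{i}" for i in range(n_samp)], name="sample_id"),
    )
    vals = pd.DataFrame(
        values, index=pd.Index([f"p{i}" for i in range(n_prot)], name="protein_id"),
        columns=meta.index,
    )
    return ProteomicsMatrix(values=vals, samples=meta)


class TestBistandardize:
    def test_two_by_two_fixed_point(self):
        m = make_matrix(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        out, info = bistandardize(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[1, -1], [-1, 1]])
        assert info["converged"] and info["n_iter"] == 1

    def test_moments_after_convergence(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(30, 10)))
        out, info = bistandardize(m, tol=1e-8)
        x = out.values.to_numpy()
        assert info["converged"]
        assert np.abs(x.mean(axis=0)).max() < 1e-8
        assert np.abs(x.mean(axis=1)).max() < 1e-8
        assert np.abs(x.var(axis=0) - 1).max() < 1e-8
        assert np.abs(x.var(axis=1) - 1).max() < 1e-8

    def test_idempotent_at_fixed_point(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(12, 8)))
        once, _ = bistandardize(m, tol=1e-10)
        twice, info = bistandardize(once, tol=1e-10)
        assert info["n_iter"] == 1
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-8
        )

    def test_constant_row_named(self):
        vals = np.random.default_rng(2).normal(size=(4, 6))
        vals[2] = 5.0
        with pytest.raises(ProteomicsError, match="p2"):
            bistandardize(make_matrix(vals))


class TestRegression:
    def test_noiseless_coefficients_recovered_exactly(self):
        cfg = ProteomicsSimConfig(n_proteins=20, noise_sd=0.0, fraction_nonnull=0.5)
        matrix, truth = simulate_proteomics(cfg, seed=3)
        res = fit_protein_regressions(matrix)
        for coef in ("b0", "b1", "b2", "b3"):
            np.testing.assert_allclose(res[coef], truth[coef], atol=1e-8)

    def test_hand_built_interpolation(self):
        meta_times = (0.0, 2.0, 4.0, 6.0, 12.0)
        cl = np.array([1.0] * 5 + [0.0] * 5)
        t = np.array(meta_times * 2)
        y = 1.0 + 2.0 * cl + 0.5 * t
        res = fit_protein_regressions(make_matrix(y[None, :], times=meta_times * 2))
        assert res["b0"].iloc[0] == pytest.approx(1.0)
        assert res["b1"].iloc[0] == pytest.approx(2.0)
        assert res["b2"].iloc[0] == pytest.approx(0.5)
        assert res["b3"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_type_i_error_calibrated_under_null(self):
        cfg = ProteomicsSimConfig(n_proteins=2000, noise_sd=1.0, fraction_nonnull=0.0)
        matrix, _ = simulate_proteomics(cfg, seed=4)
        res = fit_protein_regressions(matrix)
        se3 = 3 * math.sqrt(0.05 * 0.95 / 2000)
        for coef in ("b1", "b2", "b3"):
            rate = (res[f"p_{coef}"] < 0.05).mean()
            assert abs(rate - 0.05) < se3, coef

    def test_estimator_unbiased_at_moderate_noise(self):
        # mean estimated cell-line effect across replicates close to truth
        rng = np.random.default_rng(5)
        times = (0.0, 2.0, 4.0, 6.0, 12.0)
        cl = np.array([1.0] * 5 + [0.0] * 5)
        t = np.array(times * 2)
        n_rep = 200
        y = 2.0 * cl + rng.normal(0, 0.5, size=(n_rep, 10))
        res = fit_protein_regressions(make_matrix(y, times=times * 2))
        est = res["b1"].to_numpy()
        se = est.std(ddof=1) / math.sqrt(n_rep)
        assert abs(est.mean() - 2.0) < 2 * se + 1e-12

    def test_rank_deficient_design_rejected(self):
        vals = np.random.default_rng(6).normal(size=(3, 10))
        m = make_matrix(vals, times=[0.0] * 10)  # no time variation
        with pytest.raises(ProteomicsError, match="rank"):
            fit_protein_regressions(m)

    def test_ranks_are_permutation_and_bonferroni_dominates(self):
        cfg = ProteomicsSimConfig(n_proteins=100, fraction_nonnull=0.3)
        matrix, _ = simulate_proteomics(cfg, seed=7)
        res = fit_protein_regressions(matrix)
        assert sorted(res["rank"]) == list(range(1, 101))
        assert (res["bonferroni_b1"] >= res["p_b1"] - 1e-12).all()
        # BH q is monotone nondecreasing when rows are ordered by raw p
        ordered = res.sort_values("p_b1")["q_b1"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH by direct definition."""
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running_min = min(running_min, p[order[i]] * m / rank)
        adj[order[i]] = running_min
    return np.minimum(adj, 1.0)


def brute_force_holm_sidak(p: np.ndarray) -> np.ndarray:
    """Step-down Holm-Sidak by direct definition."""
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_max = 0.0
    for i in range(m):
        val = 1.0 - (1.0 - p[order[i]]) ** (m - i)
        running_max = max(running_max, val)
        adj[order[i]] = min(1.0, running_max)
    return adj


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh", "holm_sidak"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bonferroni_definition(self):
        out = adjust_pvalues([0.01] + [0.5] * 9, "bonferroni")
        assert out[0] == pytest.approx(0.1)

    def test_bh_step_up_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03]
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_matches_brute_force_definitions(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(adjust_pvalues(p, "bh"), brute_force_bh(p), atol=1e-12)
        np.testing.assert_allclose(
            adjust_pvalues(p, "holm_sidak"), brute_force_holm_sidak(p), atol=1e-9
        )
        np.testing.assert_allclose(
            adjust_pvalues(p, "bonferroni"), np.minimum(1.0, p * p.size), atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ProteomicsError):
            adjust_pvalues([0.5, 1.5], "bh")


class TestPCA:
    def test_rank_one_data(self):
        base = np.array([[0.0, 1.0, 2.0]])
        vals = np.vstack([base, 2 * base])  # 2 proteins, 3 samples, colinear
        out = pca(make_matrix(vals, times=(0, 2, 4)), 2)
        assert out["variance_explained"][0] == pytest.approx(1.0)

    def test_hand_eigendecomposition(self):
        # samples at (0,0), (1,1), (2,2) in 2-protein space -> PC1 = (1,1)/sqrt(2)
        vals = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]])
        out = pca(make_matrix(vals, times=(0, 2, 4)), 1)
        np.testing.assert_allclose(
            out["loadings"].to_numpy()[0], [1 / math.sqrt(2)] * 2, atol=1e-12
        )

    def test_full_reconstruction(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(6, 5))
        m = make_matrix(vals)
        out = pca(m, 5)
        recon = out["scores"].to_numpy() @ out["loadings"].to_numpy()
        centered = vals.T - vals.T.mean(axis=0)
        np.testing.assert_allclose(recon, centered, atol=1e-8)
        assert out["variance_explained"].sum() == pytest.approx(1.0)

    def test_invalid_component_count(self):
        m = make_matrix(np.random.default_rng(9).normal(size=(4, 6)))
        with pytest.raises(ProteomicsError):
            pca(m, 7)


class TestClustering:
    def _blobs(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 0.2, size=(15, 10))
        b = rng.normal(8.0, 0.2, size=(15, 10))
        labels = np.array([0] * 15 + [1] * 15)
        return make_matrix(np.vstack([a, b])), labels

    def test_separated_blobs_recovered_exactly(self):
        m, labels = self._blobs()
        out = cluster_two_stage(m, n_clusters=2, k=1, seed=0)
        assert adjusted_rand_score(labels, out["cluster"]) == 1.0

    def test_k_equals_n_singletons(self):
        m = make_matrix(np.random.default_rng(11).normal(size=(6, 5)))
        out = cluster_two_stage(m, n_clusters=1, k=6, seed=0)
        assert out["subcluster"].nunique() == 6

    def test_deterministic_under_seed(self):
        m, _ = self._blobs()
        a = cluster_two_stage(m, n_clusters=3, k=2, seed=4)
        b = cluster_two_stage(m, n_clusters=3, k=2, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_clusters_rejected(self):
        m = make_matrix(np.random.default_rng(12).normal(size=(4, 5)))
        with pytest.raises(ProteomicsError):
            cluster_two_stage(m, n_clusters=9, k=2)


class TestORA:
    def test_null_overlap_p_is_one(self):
        coll = GeneSetCollection(
            sets={"s": frozenset({"g1", "g2", "g3"})},
            universe=frozenset(f"g{i}" for i in range(1, 21)),
        )
        out = ora_enrichment(["g10", "g11", "g12"], coll)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_undersized_set_excluded(self):
        coll = GeneSetCollection(
            sets={"tiny": frozenset({"g1", "g2"})},
            universe=frozenset(f"g{i}" for i in range(1, 21)),
            min_size=3,
        )
        out = ora_enrichment(["g1", "g2"], coll)
        assert len(out) == 0

    def test_exhaustive_hypergeometric_enumeration(self):
        # universe 20, set 5, query 5, overlap 4
        universe = frozenset(f"g{i}" for i in range(1, 21))
        members = frozenset({"g1", "g2", "g3", "g4", "g5"})
        query = ["g1", "g2", "g3", "g4", "g10"]
        coll = GeneSetCollection(sets={"s": members}, universe=universe)
        out = ora_enrichment(query, coll)
        expected = sum(
            math.comb(5, k) * math.comb(15, 5 - k) for k in (4, 5)
        ) / math.comb(20, 5)
        assert out["overlap"].iloc[0] == 4
        assert out["p"].iloc[0] == pytest.approx(expected)

    def test_empty_universe_rejected(self):
        coll = GeneSetCollection(sets={}, universe=frozenset())
        with pytest.raises(ProteomicsError):
            ora_enrichment([], coll)


def brute_force_es(ranked_in_set: list[bool], scores: list[float]) -> float:
    """Weighted KS running sum by direct loop (exponent 1)."""
    nr = sum(abs(s) for s, h in zip(scores, ranked_in_set) if h)
    n_miss = sum(1 for h in ranked_in_set if not h)
    running, best = 0.0, 0.0
    for s, h in zip(scores, ranked_in_set):
        running += abs(s) / nr if h else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def _collection(self, sets, ids):
        return GeneSetCollection(
            sets={k: frozenset(v) for k, v in sets.items()},
            universe=frozenset(ids), min_size=1, max_size=5000,
        )

    def test_toy_running_sum_matches_hand_computation(self):
        ids = [f"g{i}" for i in range(6)]
        scores = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0, -3.0], index=ids)
        coll = self._collection({"s": ["g1", "g3"]}, ids)
        out = gsea_permutation(scores, coll, n_perm=100, seed=0)
        in_set = [g in {"g1", "g3"} for g in ids]
        expected = brute_force_es(in_set, list(scores))
        assert out["es"].iloc[0] == pytest.approx(expected)

    def test_top_concentrated_set_is_extreme(self):
        rng = np.random.default_rng(13)
        ids = [f"g{i}" for i in range(100)]
        scores = pd.Series(np.sort(rng.uniform(0.5, 3.0, 100))[::-1], index=ids)
        coll = self._collection({"top": ids[:5]}, ids)
        out = gsea_permutation(scores, coll, n_perm=1000, seed=1)
        assert out["es"].iloc[0] > 0
        assert out["p"].iloc[0] <= 1 / (1000 + 1) + 1e-12

    def test_bottom_set_has_negative_es(self):
        ids = [f"g{i}" for i in range(50)]
        scores = pd.Series(np.linspace(2, -2, 50), index=ids)
        coll = self._collection({"bottom": ids[-5:]}, ids)
        out = gsea_permutation(scores, coll, n_perm=200, seed=2)
        assert out["es"].iloc[0] < 0

    def test_disjoint_set_skipped(self):
        ids = [f"g{i}" for i in range(10)]
        scores = pd.Series(np.arange(10.0), index=ids)
        coll = self._collection({"other": ["x1", "x2"]}, ids + ["x1", "x2"])
        out = gsea_permutation(scores, coll, n_perm=100, seed=3)
        assert len(out) == 0

    def test_permutation_p_deterministic_under_seed(self):
        ids = [f"g{i}" for i in range(30)]
        scores = pd.Series(np.linspace(1, -1, 30), index=ids)
        coll = self._collection({"s": ids[:4]}, ids)
        a = gsea_permutation(scores, coll, n_perm=200, seed=5)
        b = gsea_permutation(scores, coll, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestGMT:
    def test_parse_and_filter(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "setA\tdesc\tg1\tg2\tg3\n"
            "setB\tdesc\tg1\tg9999\n"
            "short_line\n"
        )
        coll = read_gmt(str(path), universe=[f"g{i}" for i in range(1, 11)])
        filtered = coll.filtered()
        assert set(filtered) == {"setA"}  # setB shrinks below min_size
        assert filtered["setA"] == frozenset({"g1", "g2", "g3"})
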