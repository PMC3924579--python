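"""PCA embedding and group-distance statistics of synchrony vectors."""
import numpy as np
import pytest
from scipy import stats

from lfpsync.errors import ConfigError, DataError
from lfpsync.patterns import PatternDataset, fit_pca, group_distances, project
from lfpsync.synth import gen_sync_vectors


def _dataset(n=64, seed=0, scale=0.1):
    rng = np.random.default_rng(seed)
    X = 0.5 + scale * rng.standard_normal((n, 32))
    labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    return PatternDataset(X=np.clip(X, 0, 1), labels=labels)


class TestFitPca:
    def test_line_data_single_component(self):
        t = np.linspace(0, 1, 20)
        direction = np.ones(32) / np.sqrt(32)
        X = 0.2 + np.outer(t, direction) * 0.5
        emb = fit_pca(PatternDataset(X=X, labels=np.array(["g"] * 20)))
        assert emb.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_variance_fractions(self):
        # oracle: Marchenko-Pastur edges (1 +/- sqrt(p/n))^2 bound the sample
        # eigenvalues of an isotropic Gaussian cloud
        rng = np.random.default_rng(1)
        n, p = 256, 32
        X = np.clip(0.5 + 0.05 * rng.standard_normal((n, p)), 0, 1)
        emb = fit_pca(PatternDataset(X=X, labels=np.array(["g"] * n)))
        lo, hi = (1 - np.sqrt(p / n)) ** 2, (1 + np.sqrt(p / n)) ** 2
        assert np.all(emb.variance_fractions < 1.05 * hi / p)
        assert np.all(emb.variance_fractions > 0.95 * lo / p)
        assert np.mean(emb.variance_fractions) == pytest.approx(1 / p, rel=1e-9)

    def test_matches_independent_eigendecomposition(self):
        # oracle: eigenvalues of the sample covariance via numpy.linalg.eigh
        ds = _dataset()
        emb = fit_pca(ds)
        cov = np.cov(ds.X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(emb.variance_fractions, eig / eig.sum(), atol=1e-9)

    def test_reconstruction_exact(self):
        ds = _dataset(n=48, seed=2)
        emb = fit_pca(ds)
        recon = emb.scores @ emb.loadings + emb.mean
        assert np.allclose(recon, ds.X, atol=1e-9)

    def test_variance_fractions_properties(self):
        emb = fit_pca(_dataset())
        assert np.all(np.diff(emb.variance_fractions) <= 1e-12)
        assert emb.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_sign_convention(self):
        ds = _dataset(seed=3)
        a = fit_pca(ds)
        b = fit_pca(ds)
        assert np.array_equal(a.loadings, b.loadings)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_columns_handled(self):
        X = np.full((10, 32), 0.5)
        X[:, 0] = np.linspace(0.2, 0.8, 10)
        emb = fit_pca(PatternDataset(X=X, labels=np.array(["g"] * 10)))
        assert emb.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(emb.variance_fractions[1:] < 1e-9)


class TestProject:
    def test_full_projection_preserves_distances(self):
        ds = _dataset(n=64)
        emb = fit_pca(ds)
        pts = project(emb, 32)
        d_orig = np.linalg.norm(ds.X[0] - ds.X[1])
        assert np.linalg.norm(pts[0] - pts[1]) == pytest.approx(d_orig, abs=1e-9)

    def test_projection_contracts(self):
        ds = _dataset(n=64, seed=4)
        emb = fit_pca(ds)
        d6 = np.linalg.norm(project(emb, 6)[0] - project(emb, 6)[1])
        d32 = np.linalg.norm(project(emb, 32)[0] - project(emb, 32)[1])
        assert d6 <= d32 + 1e-12

    def test_identical_rows_identical_points(self):
        X = np.vstack([np.full(32, 0.4)] * 2 + [np.full(32, 0.6)] * 2)
        emb = fit_pca(PatternDataset(X=X, labels=np.array(["g"] * 4)))
        pts = project(emb, min(6, emb.n_components))
        assert np.allclose(pts[0], pts[1], atol=1e-12)

    def test_k_out_of_range(self):
        emb = fit_pca(_dataset(n=16))
        with pytest.raises(ConfigError):
            project(emb, 33)


class TestGroupDistances:
    def test_identical_points_zero_distances(self):
        pts = np.zeros((8, 6))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        rep = group_distances(pts, labels, "a")
        assert rep.within == {"a": 0.0, "b": 0.0}
        assert rep.cross["b"] == 0.0

    def test_noise_free_clusters(self):
        pts = np.vstack([np.zeros((4, 6)), np.full((4, 6), 0.3)])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        rep = group_distances(pts, labels, "a")
        assert rep.within["a"] == 0.0
        assert rep.cross["b"] == pytest.approx(0.3 * np.sqrt(6))

    def test_cross_of_reference_equals_within(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((12, 6))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        rep = group_distances(pts, labels, "a")
        assert rep.cross["a"] == pytest.approx(rep.within["a"], abs=1e-12)

    def test_cross_mean_matches_brute_force(self):
        # oracle: exhaustive double loop over the two clouds
        vecs = gen_sync_vectors(
            {"a": np.full(32, 0.4), "b": np.full(32, 0.7)}, noise_sd=0.02,
            n_per_group=8, seed=6,
        )
        ds = PatternDataset.from_sync_vectors(vecs)
        emb = fit_pca(ds)
        pts = project(emb, 6)
        rep = group_distances(pts, ds.labels, "a", seed=0)
        a_pts = pts[ds.labels == "a"]
        b_pts = pts[ds.labels == "b"]
        brute = np.mean(
            [np.linalg.norm(x - y) for x in b_pts for y in a_pts]
        )
        assert rep.cross["b"] == pytest.approx(brute, abs=1e-12)
        assert bool(rep.table["significant"].iloc[0])

    def test_naive_ttest_reported(self):
        vecs = gen_sync_vectors(
            {"a": np.full(32, 0.4), "b": np.full(32, 0.7)}, noise_sd=0.02,
            n_per_group=8, seed=6,
        )
        ds = PatternDataset.from_sync_vectors(vecs)
        pts = project(fit_pca(ds), 6)
        rep = group_distances(pts, ds.labels, "a", seed=0)
        assert {"p_ttest", "t_vs_own_within", "p_vs_own_within"} <= set(rep.table.columns)
        assert rep.table["p_ttest"].iloc[0] < 0.05

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((16, 6))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        rep1 = group_distances(pts, labels, "a", seed=1)
        perm = rng.permutation(16)
        rep2 = group_distances(pts[perm], labels[perm], "a", seed=1)
        assert rep1.within["a"] == pytest.approx(rep2.within["a"], abs=1e-12)
        assert rep1.cross["b"] == pytest.approx(rep2.cross["b"], abs=1e-12)

    def test_rotation_invariance_before_pca(self):
        rng = np.random.default_rng(8)
        ds = _dataset(n=32, seed=9)
        q, _ = np.linalg.qr(rng.standard_normal((32, 32)))
        rotated = PatternDataset(X=np.clip(ds.X @ q, -10, 10), labels=ds.labels)
        k = 6
        rep_a = group_distances(project(fit_pca(ds), k), ds.labels, "a", seed=2)
        rep_b = group_distances(project(fit_pca(rotated), k), ds.labels, "a", seed=2)
        assert rep_a.cross["b"] == pytest.approx(rep_b.cross["b"], rel=1e-6)

    def test_separability_monotone_in_effect_size(self):
        flags = []
        for d in (0.0, 0.15, 0.4):
            vecs = gen_sync_vectors(
                {"a": np.full(32, 0.3), "b": np.clip(np.full(32, 0.3 + d), 0, 1)},
                noise_sd=0.02, n_per_group=8, seed=10,
            )
            ds = PatternDataset.from_sync_vectors(vecs)
            pts = project(fit_pca(ds), 6)
            rep = group_distances(pts, ds.labels, "a", seed=3)
            flags.append(bool(rep.table["significant"].iloc[0]))
        assert flags == sorted(flags)  # once separable, stays separable
        assert not flags[0] and flags[-1]

    def test_singleton_group_rejected(self):
        pts = np.zeros((3, 6))
        labels = np.array(["a", "a", "b"])
        with pytest.raises(DataError):
            group_distances(pts, labels, "a")

    def test_unknown_reference_rejected(self):
        pts = np.zeros((4, 6))
        labels = np.array(["a", "a", "b", "b"])
        with pytest.raises(ConfigError):
            group_distances(pts, labels, "c")
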