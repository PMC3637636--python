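"""Tests for projection-pursuit robust PCA and the outlier diagnostics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import robustps as rps
from robustps.robust_pca import RobustPCAResult


def principal_angle(u, v):
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    return np.arccos(min(1.0, abs(float(u @ v))))


def subspace_angles(A, B):
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s, -1, 1))


class TestMad:
    def test_constant_sample_is_zero(self):
        assert rps.mad([3.0, 3.0, 3.0]) == 0.0

    def test_hand_example(self):
        # median 3, absolute deviations (2,1,0,1,2), median deviation 1
        assert rps.mad([1, 2, 3, 4, 5]) == pytest.approx(1.4826)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rps.mad([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        z=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
        a=st.floats(-100, 100),
        b=st.floats(-1e3, 1e3),
    )
    def test_affine_equivariance(self, z, a, b):
        z = np.asarray(z)
        assert rps.mad(a * z + b) == pytest.approx(abs(a) * rps.mad(z), rel=1e-9, abs=1e-9)


class TestDirectionSearches:
    def test_cr_matches_exhaustive_candidate_search(self):
        # a handful of generic points: the CR maximiser must equal brute
        # force over the centred, normalised candidate directions
        gen = np.random.default_rng(123)
        X = gen.normal(size=(5, 3))
        res = rps.pp_pca_cr(X, 1, pp_index="mad")
        mu = np.median(X, axis=0)
        Xc = X - mu
        cands = [r / np.linalg.norm(r) for r in Xc if np.linalg.norm(r) > 0]
        vals = [rps.mad(Xc @ c) for c in cands]
        best = cands[int(np.argmax(vals))]
        assert principal_angle(res.eigenvectors[:, 0], best) < 1e-8
        assert res.eigenvalues[0] == pytest.approx(max(vals) ** 2)

    def test_grid_sd_matches_classical_pca(self):
        gen = np.random.default_rng(5)
        X = gen.normal(size=(200, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2])
        res = rps.pp_pca_grid(X, 1, pp_index="sd")
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc)
        assert principal_angle(res.eigenvectors[:, 0], Vt[0]) < 0.15

    def test_grid_rank_one_line(self):
        t = np.linspace(-2, 2, 25)
        X = np.column_stack([t, t])
        res = rps.pp_pca_grid(X, 2, pp_index="mad")
        assert res.truncated  # no scale remains after the first component
        assert principal_angle(res.eigenvectors[:, 0], np.array([1.0, 1.0])) < 1e-6

    def test_grid_angle_accuracy_against_closed_form(self):
        gen = np.random.default_rng(8)
        theta = 0.35
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        X = gen.normal(size=(400, 2)) @ np.diag([4.0, 0.5]) @ R.T
        res = rps.pp_pca_grid(X, 1, pp_index="sd", n_refinements=10)
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc)
        assert principal_angle(res.eigenvectors[:, 0], Vt[0]) < 1e-3

    def test_grid_resists_contamination_where_classical_breaks(self):
        gen = np.random.default_rng(21)
        n, p = 500, 10
        X = gen.normal(size=(n, p))
        X[:, 0] *= 3.0  # true leading axis is e_1
        clean_dir = np.zeros(p)
        clean_dir[0] = 1.0
        m = n // 20
        X[:m] = gen.normal(size=(m, p)) * 0.5 + 25.0 * np.array([0.0] * 5 + [1.0] + [0.0] * 4)
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc)
        classical_shift = principal_angle(Vt[0], clean_dir)
        robust = rps.pp_pca_grid(X, 1, pp_index="mad")
        robust_shift = principal_angle(robust.eigenvectors[:, 0], clean_dir)
        assert classical_shift > 0.3
        assert robust_shift < classical_shift / 3.0
        # the search should do at least as well as the obvious directions
        mu = np.median(X, axis=0)
        found_val = rps.mad((X - mu) @ robust.eigenvectors[:, 0])
        assert found_val >= rps.mad((X - mu) @ clean_dir) - 1e-9
        assert found_val >= rps.mad((X - mu) @ Vt[0]) - 1e-9

    def test_row_permutation_invariance_and_sorted_eigenvalues(self):
        gen = np.random.default_rng(3)
        X = gen.normal(size=(60, 4))
        res = rps.pp_pca_grid(X, 3)
        perm = gen.permutation(60)
        res_p = rps.pp_pca_grid(X[perm], 3)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.allclose(np.abs(res.eigenvectors.T @ res_p.eigenvectors).diagonal(), 1.0, atol=1e-6)

    def test_cr_and_grid_agree_on_clean_gaussian(self):
        gen = np.random.default_rng(17)
        X = gen.normal(size=(300, 6)) @ np.diag([3.0, 2.0, 1.5, 1.0, 0.7, 0.5])
        a = rps.pp_pca_cr(X, 3)
        b = rps.pp_pca_grid(X, 3)
        assert np.allclose(a.eigenvalues, b.eigenvalues, rtol=0.10)

    def test_k_too_large_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            rps.pp_pca_grid(X, 10)

    def test_scores_reproducible_from_inputs(self, rng):
        X = rng.normal(size=(80, 6))
        res = rps.pp_pca_grid(X, 4)
        recomputed = (X - res.location) @ res.eigenvectors
        assert np.allclose(recomputed, res.scores, atol=1e-10)
        assert np.allclose(np.linalg.norm(res.eigenvectors, axis=0), 1.0, atol=1e-10)


class TestEquivariance:
    def test_orthogonal_rotation_of_variables(self, rng):
        # the coordinatewise median is not rotation-equivariant, so the
        # invariant is stated conditional on the centre: with the centre
        # rotated alongside the data, eigenvalues and distances are
        # preserved and eigenvectors rotate correspondingly
        X = rng.normal(size=(120, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        mu = np.median(X, axis=0)
        res = rps.pp_pca_grid(X, 3, location=mu)
        res_q = rps.pp_pca_grid(X @ Q, 3, location=mu @ Q)
        assert np.allclose(res.eigenvalues, res_q.eigenvalues, atol=1e-8)
        assert np.allclose(res.eigenvectors.T @ Q, res_q.eigenvectors.T, atol=1e-6)
        d1 = rps.outlier_diagnostics(X, res)
        d2 = rps.outlier_diagnostics(X @ Q, res_q)
        assert np.allclose(d1.score_distance, d2.score_distance, atol=1e-8)
        assert np.allclose(d1.orth_distance, d2.orth_distance, atol=1e-8)


class TestScoreDistances:
    def test_hand_example(self):
        res = RobustPCAResult(
            eigenvectors=np.eye(2),
            eigenvalues=np.array([9.0, 16.0]),
            scores=np.array([[3.0, 4.0]]),
            location=np.zeros(2),
            pp_index="mad",
            algorithm="grid",
        )
        sd, cutoff = rps.score_distances(res)
        assert sd[0] == pytest.approx(np.sqrt(2.0))
        assert cutoff == pytest.approx(np.sqrt(stats.chi2.ppf(0.975, 2)))
        assert cutoff == pytest.approx(2.7162, abs=1e-3)

    def test_sign_flip_invariance(self):
        res = RobustPCAResult(
            eigenvectors=np.eye(2),
            eigenvalues=np.array([4.0, 1.0]),
            scores=np.array([[1.0, -2.0], [0.5, 0.25]]),
            location=np.zeros(2),
            pp_index="mad",
            algorithm="grid",
        )
        flipped = RobustPCAResult(
            eigenvectors=-res.eigenvectors,
            eigenvalues=res.eigenvalues,
            scores=-res.scores,
            location=res.location,
            pp_index="mad",
            algorithm="grid",
        )
        assert np.allclose(rps.score_distances(res)[0], rps.score_distances(flipped)[0])

    def test_zero_eigenvalue_rejected(self):
        res = RobustPCAResult(
            eigenvectors=np.eye(2),
            eigenvalues=np.array([1.0, 0.0]),
            scores=np.zeros((3, 2)),
            location=np.zeros(2),
            pp_index="mad",
            algorithm="grid",
        )
        with pytest.raises(ValueError):
            rps.score_distances(res)


class TestOrthDistances:
    def test_full_rank_zero_od(self, rng):
        X = rng.normal(size=(30, 3))
        res = rps.pp_pca_grid(X, 3)
        with pytest.warns(RuntimeWarning):
            od, cutoff, _, _ = rps.orth_distances(X, res)
        assert od.max() < 1e-8

    def test_data_in_affine_subspace(self, rng):
        # symmetric scores put the coordinatewise median inside the plane
        basis = np.linalg.qr(rng.normal(size=(5, 2)))[0]
        scores = rng.normal(size=(25, 2))
        scores = np.concatenate([scores, -scores])
        X = scores @ basis.T
        res = rps.pp_pca_grid(X, 2)
        with pytest.warns(RuntimeWarning):
            od, _, _, _ = rps.orth_distances(X, res)
        assert od.max() < 1e-8

    def test_cutoff_calibration_on_scaled_chisquare(self):
        # OD^2 ~ g2 * chi2_{g1}: the Wilson-Hilferty cutoff should be
        # exceeded by about 2.5% of draws
        gen = np.random.default_rng(42)
        g1, g2 = 5.0, 2.0
        od = np.sqrt(g2 * gen.chisquare(g1, size=10_000))
        z = np.cbrt(od**2)
        cutoff = (z.mean() + z.std(ddof=1) * stats.norm.ppf(0.975)) ** 1.5
        rate = (od > cutoff).mean()
        se = np.sqrt(0.025 * 0.975 / od.size)
        assert abs(rate - 0.025) < 3 * se


class TestClassification:
    def test_type_definitions(self):
        sd = np.array([0.0, 5.0, 1.0, 5.0])
        od = np.array([0.0, 1.0, 5.0, 5.0])
        labels = rps.classify_outliers(sd, od, sd_cutoff=2.0, od_cutoff=2.0)
        assert list(labels) == ["regular", "A", "B", "C"]

    def test_partition_property(self, rng):
        sd = rng.exponential(size=200)
        od = rng.exponential(size=200)
        labels = rps.classify_outliers(sd, od, 1.0, 1.0)
        counts = {k: (labels == k).sum() for k in ("regular", "A", "B", "C")}
        assert sum(counts.values()) == 200
        removal = labels != "regular"
        assert removal.sum() == counts["A"] + counts["B"] + counts["C"]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rps.classify_outliers([1.0], [1.0, 2.0], 1.0, 1.0)


class TestOperatingCharacteristics:
    def test_injected_subjects_flagged_with_few_false_flags(self, s4_contaminated, s4_grid_fit):
        diag = s4_grid_fit.outlier_diagnostics()
        inj = s4_contaminated.outlier_flags
        mask = diag.outlier_mask
        assert (mask & inj).sum() >= 0.9 * inj.sum()
        assert (mask & ~inj).sum() <= 0.02 * (~inj).sum()

    def test_estimator_interface(self, rng):
        X = rng.normal(size=(50, 8))
        est = rps.PPRobustPCA(n_components=2).fit(X)
        assert est.components_.shape == (8, 2)
        assert est.transform(X).shape == (50, 2)
        params = est.get_params()
        assert params["algorithm"] == "grid"
        clone_params = rps.PPRobustPCA(**params).get_params()
        assert clone_params == params

    def test_missing_values_imputed(self, rng):
        X = rng.normal(size=(40, 6))
        X[3, 2] = np.nan
        est = rps.PPRobustPCA(n_components=2).fit(X)
        assert np.isfinite(est.scores_).all()
        with pytest.raises(ValueError):
            rps.PPRobustPCA(n_components=2, impute_missing=False).fit(X)
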