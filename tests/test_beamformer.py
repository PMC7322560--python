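import numpy as np
import pytest

from lcmvbench import (
    CovarianceEstimate,
    LCMVBeamformer,
    NoiseModel,
    build_grid,
    compute_leadfield,
    optimal_orientation,
    point_gain,
    scalar_nai,
    vector_nai,
    vector_power,
    vector_weights,
)
from lcmvbench.beamformer import PRESETS, get_config
from lcmvbench.errors import (
    InvalidArgumentError,
    SilentSourceError,
    SingularModelError,
)


def random_system(rng, m=12, k=3):
    L = rng.normal(size=(m, k))
    a = rng.normal(size=(m, 3 * m))
    C = a @ a.T / (3 * m)
    return L, C


class TestVectorOps:
    def test_identity_covariance_orthonormal_leadfield(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(12, 3)))
        wt = vector_weights(q, np.eye(12))
        np.testing.assert_allclose(wt, q.T, atol=1e-12)
        assert vector_power(q, np.eye(12)) == pytest.approx(3.0)

    def test_unit_gain_identity(self, rng):
        for _ in range(10):
            L, C = random_system(rng)
            wt = vector_weights(L, np.linalg.inv(C))
            np.testing.assert_allclose(wt @ L, np.eye(3), atol=1e-8)

    def test_weights_solve_constrained_minimization(self, rng):
        """Eq-style weights match a generic quadratic-program solution of
        min Tr(W^T C W) subject to W^T L = I."""
        from scipy.optimize import minimize

        L, C = random_system(rng, m=8, k=2)
        C_inv = np.linalg.inv(C)
        wt = vector_weights(L, C_inv)

        def objective(wflat):
            w = wflat.reshape(8, 2)
            return np.trace(w.T @ C @ w)

        cons = {"type": "eq",
                "fun": lambda wflat: (wflat.reshape(8, 2).T @ L -
                                      np.eye(2)).ravel()}
        res = minimize(objective, rng.normal(size=16), constraints=[cons],
                       method="SLSQP", options={"maxiter": 500, "ftol": 1e-14})
        assert res.success
        np.testing.assert_allclose(res.x.reshape(8, 2).T, wt, atol=1e-5)

    def test_power_homogeneity_and_oracle(self, rng):
        L, C = random_system(rng)
        C_inv = np.linalg.inv(C)
        p = vector_power(L, C_inv)
        assert vector_power(L, np.linalg.inv(3.0 * C)) == pytest.approx(
            3 * p, rel=1e-12)
        gram = L.T @ C_inv @ L
        assert p == pytest.approx(np.trace(np.linalg.inv(gram)), rel=1e-9)

    def test_nai_closed_forms(self, rng):
        L, C = random_system(rng)
        C_inv = np.linalg.inv(C)
        assert vector_nai(L, C_inv, C_inv) == pytest.approx(1.0, rel=1e-12)
        assert vector_nai(L, np.linalg.inv(2 * C), C_inv) == pytest.approx(
            2.0, rel=1e-12)

    def test_singular_gram_raises(self):
        L = np.zeros((6, 3))
        L[:, 0] = 1.0  # rank-1 leadfield
        with pytest.raises(SingularModelError):
            vector_weights(L, np.eye(6))


class TestOptimalOrientation:
    def test_recovers_known_orientation(self, rng):
        """Noiseless single-dipole covariance with small loading: the
        estimated orientation matches the true one."""
        L = rng.normal(size=(20, 3))
        eta = np.array([0.6, -0.64, 0.48])
        eta /= np.linalg.norm(eta)
        signal = L @ eta
        C = 25.0 * np.outer(signal, signal) + 1e-4 * np.eye(20)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            eta_opt = optimal_orientation(L, np.linalg.inv(C))
        assert abs(eta_opt @ eta) > 0.999

    def test_beats_one_degree_grid_search(self, rng):
        """No orientation on a dense 1-degree sphere grid achieves a higher
        output-SNR Rayleigh quotient (l'C^-1 l / l'C^-2 l) than eta_opt."""
        L, C = random_system(rng, m=16)
        C_inv = np.linalg.inv(C)
        eta_opt = optimal_orientation(L, C_inv)

        def quotient(eta):
            l = L @ eta
            return (l @ C_inv @ l) / (l @ C_inv @ C_inv @ l)

        best = quotient(eta_opt)
        theta = np.deg2rad(np.arange(0, 180, 1.0))
        phi = np.deg2rad(np.arange(0, 360, 1.0))
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                         np.cos(tt)], axis=-1).reshape(-1, 3)
        l_all = dirs @ L.T
        num = np.einsum("ni,ij,nj->n", l_all, C_inv, l_all)
        den = np.einsum("ni,ij,nj->n", l_all, C_inv @ C_inv, l_all)
        assert num.max() > 0
        grid_best = (num / den).max()
        assert grid_best <= best * (1 + 1e-6)

    def test_unit_norm_and_sign_convention(self, rng):
        L, C = random_system(rng)
        eta = optimal_orientation(L, np.linalg.inv(C))
        assert np.linalg.norm(eta) == pytest.approx(1.0, abs=1e-12)
        assert eta[np.argmax(np.abs(eta))] > 0


class TestScalarNAI:
    def test_equal_covariances_give_unity(self, rng):
        L, C = random_system(rng)
        C_inv = np.linalg.inv(C)
        for _ in range(5):
            eta = rng.normal(size=3)
            eta /= np.linalg.norm(eta)
            assert scalar_nai(L, eta, C_inv, C_inv) == pytest.approx(
                1.0, rel=1e-12)

    def test_quadratic_form_oracle(self, rng):
        L, C = random_system(rng)
        a = rng.normal(size=(12, 36))
        Cn = a @ a.T / 36
        C_inv, Cn_inv = np.linalg.inv(C), np.linalg.inv(Cn)
        eta = rng.normal(size=3)
        eta /= np.linalg.norm(eta)
        l = L @ eta
        oracle = (l @ Cn_inv @ l) / (l @ C_inv @ l)
        assert scalar_nai(L, eta, C_inv, Cn_inv) == pytest.approx(
            oracle, rel=1e-10)

    def test_silent_orientation_raises(self, sphere, small_array):
        src = np.array([0.0, 0.02, 0.05])
        L = point_gain(src, small_array, sphere)
        radial = src / np.linalg.norm(src)
        with pytest.raises(SilentSourceError):
            scalar_nai(L, radial, np.eye(12), np.eye(12))


def _covariances_for(gain, orientation, amplitude, noise_sd, rng,
                     n_samples=4000):
    """Synthetic data/noise covariance pair from a known source pattern."""
    m = gain.shape[0]
    pattern = gain @ orientation
    s = amplitude * rng.normal(size=n_samples)
    noise_d = noise_sd * rng.standard_normal((m, n_samples))
    noise_n = noise_sd * rng.standard_normal((m, n_samples))
    d = pattern[:, None] * s[None, :] + noise_d
    C = CovarianceEstimate(d @ d.T / n_samples, n_samples, 1, kind="data")
    Cn = CovarianceEstimate(noise_n @ noise_n.T / n_samples, n_samples, 1,
                            kind="noise")
    return C, Cn


class TestScan:
    def test_noiseless_dipole_on_grid_point_exact_peak(self, sphere,
                                                       medium_array,
                                                       coarse_grid, rng):
        lf = compute_leadfield(coarse_grid, medium_array, sphere)
        j = coarse_grid.nearest_index([0.0, 0.02, 0.05])
        loc = coarse_grid.points[j]
        radial = loc / np.linalg.norm(loc)
        ori = np.cross(radial, [1.0, 0.0, 0.0])
        ori /= np.linalg.norm(ori)
        gain = point_gain(loc, medium_array, sphere)
        C, Cn = _covariances_for(gain, ori, 1e-8, 1e-15, rng)
        for config in ("mne_like", "brainstorm_like"):
            res = LCMVBeamformer(C, Cn, lf, medium_array, config).fit()
            assert res.map.peak_index == j
            assert res.localization_error(loc) == 0.0

    def test_brainstorm_config_equals_manual_cross_zeroing(
            self, sphere, medium_array, coarse_grid, rng):
        from lcmvbench.preprocessing import zero_cross_sensor_terms

        lf = compute_leadfield(coarse_grid, medium_array, sphere)
        loc = coarse_grid.points[coarse_grid.nearest_index([0.01, 0.0, 0.05])]
        radial = loc / np.linalg.norm(loc)
        ori = np.cross(radial, [0.0, 1.0, 0.0])
        ori /= np.linalg.norm(ori)
        gain = point_gain(loc, medium_array, sphere)
        C, Cn = _covariances_for(gain, ori, 1e-8, 1e-13, rng)
        res = LCMVBeamformer(C, Cn, lf, medium_array, "brainstorm_like").fit()
        Cz = CovarianceEstimate(
            zero_cross_sensor_terms(C.matrix, medium_array), C.n_samples, 1,
            kind="data")
        Cnz = CovarianceEstimate(
            zero_cross_sensor_terms(Cn.matrix, medium_array), Cn.n_samples, 1,
            kind="noise")
        res_manual = LCMVBeamformer(Cz, Cnz, lf, medium_array,
                                    "brainstorm_like").fit()
        np.testing.assert_allclose(res.map.nai, res_manual.map.nai, rtol=1e-10)

    def test_nai_map_unity_when_cov_equals_noise(self, sphere, medium_array,
                                                 coarse_grid, rng):
        lf = compute_leadfield(coarse_grid, medium_array, sphere)
        m = medium_array.n_channels
        a = rng.normal(size=(m, 6 * m))
        C = CovarianceEstimate(a @ a.T / (6 * m), 6 * m, 1, kind="data")
        Cn = CovarianceEstimate(C.matrix.copy(), C.n_samples, 1, kind="noise")
        import warnings

        for config in ("mne_like", "brainstorm_like", "fieldtrip_like"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # flat-map tie
                res = LCMVBeamformer(C, Cn, lf, medium_array, config).fit()
            nai = res.map.nai[res.map.nai > 0]  # silent points excluded
            np.testing.assert_allclose(nai, 1.0, atol=1e-9)

    def test_unit_gain_holds_under_regularized_inverse(self, sphere,
                                                       medium_array, rng):
        """The unit-gain constraint W^T L = I is enforced by the weight
        construction itself, so it holds (to numerical precision) whether
        the inverse is exact or Tikhonov-loaded at any ratio."""
        loc = np.array([0.0, 0.025, 0.05])
        gain = point_gain(loc, medium_array, sphere)
        radial = loc / np.linalg.norm(loc)
        ori = np.cross(radial, [1.0, 0, 0])
        ori /= np.linalg.norm(ori)
        C, _ = _covariances_for(gain, ori, 1e-8, 1e-13, rng)
        u, s, _ = np.linalg.svd(gain, full_matrices=False)
        L2 = u[:, :2] * s[:2]
        for ratio in (1e-2, 1e-4, 1e-6):
            lam = ratio * np.trace(C.matrix) / C.n_channels
            C_inv = np.linalg.inv(C.matrix + lam * np.eye(C.n_channels))
            wt = vector_weights(L2, C_inv)
            assert np.abs(wt @ L2 - np.eye(2)).max() < 1e-8

    def test_scalar_beats_vector_contrast_at_source(self, rng):
        """Optimal-orientation scalar NAI at the true location exceeds the
        vector trace-ratio NAI in nearly all noisy repetitions (the output
        SNR advantage of orientation optimization)."""
        wins = 0
        reps = 100
        base = np.random.default_rng(20)
        L = base.normal(size=(24, 3))
        eta = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        pattern = L @ eta
        for _ in range(reps):
            C, Cn = _covariances_for(
                np.eye(24), pattern / np.linalg.norm(pattern),
                np.sqrt(10.0), 1.0, rng, n_samples=600)
            lam = 0.05 * np.trace(C.matrix) / 24
            lam_n = 0.05 * np.trace(Cn.matrix) / 24
            C_inv = np.linalg.inv(C.matrix + lam * np.eye(24))
            Cn_inv = np.linalg.inv(Cn.matrix + lam_n * np.eye(24))
            eta_opt = optimal_orientation(L, C_inv)
            s = scalar_nai(L, eta_opt, C_inv, Cn_inv)
            v = vector_nai(L, C_inv, Cn_inv)
            wins += s >= v
        assert wins >= 95

    def test_psv_not_sharpened_by_more_regularization(self, sphere,
                                                      medium_array,
                                                      coarse_grid, rng):
        from lcmvbench.beamformer import BeamformerConfig
        from lcmvbench.metrics import point_spread_volume

        lf = compute_leadfield(coarse_grid, medium_array, sphere)
        violations = 0
        for seed in range(10):
            local = np.random.default_rng(seed)
            loc = coarse_grid.points[
                coarse_grid.nearest_index([0.005, 0.015, 0.05])]
            radial = loc / np.linalg.norm(loc)
            ori = np.cross(radial, [1.0, 0, 0])
            ori /= np.linalg.norm(ori)
            gain = point_gain(loc, medium_array, sphere)
            C, Cn = _covariances_for(gain, ori, 3e-9, 2e-12, local,
                                     n_samples=2000)
            psvs = []
            for ratio in (0.05, 0.5):
                cfg = BeamformerConfig(type="scalar", whitening="full",
                                       reg_ratio=ratio)
                res = LCMVBeamformer(C, Cn, lf, medium_array, cfg).fit()
                psvs.append(point_spread_volume(res.map))
            violations += psvs[1] < psvs[0]
        assert violations <= 1

    def test_whitening_invariance_of_peak(self, sphere, medium_array,
                                          coarse_grid, rng):
        """On a well-conditioned system, scanning with full prewhitening finds
        the same peak as scanning raw with the same small loading."""
        from lcmvbench.beamformer import BeamformerConfig

        lf = compute_leadfield(coarse_grid, medium_array, sphere)
        loc = coarse_grid.points[coarse_grid.nearest_index([0.0, -0.02, 0.05])]
        radial = loc / np.linalg.norm(loc)
        ori = np.cross(radial, [0.0, 1.0, 0.0])
        ori /= np.linalg.norm(ori)
        gain = point_gain(loc, medium_array, sphere)
        C, Cn = _covariances_for(gain, ori, 1e-8, 1e-12, rng, n_samples=5000)
        peaks = []
        for mode in ("full", "none"):
            cfg = BeamformerConfig(type="scalar", whitening=mode,
                                   reg_ratio=1e-8)
            res = LCMVBeamformer(C, Cn, lf, medium_array, cfg).fit()
            peaks.append(res.map.peak_index)
        assert peaks[0] == peaks[1]


class TestConfig:
    def test_presets_match_toolbox_settings(self):
        assert PRESETS["mne_like"].type == "scalar"
        assert PRESETS["mne_like"].whitening == "full"
        assert PRESETS["fieldtrip_like"].whitening == "none"
        assert PRESETS["fieldtrip_like"].unit_scale == "si"
        assert PRESETS["spm_like"].unit_scale == "fT_fTmm"
        bst = PRESETS["brainstorm_like"]
        assert bst.type == "vector"
        assert bst.whitening == "block_by_sensor_type"
        assert bst.zero_cross_terms and bst.per_sensor_type_lambda

    def test_unknown_preset_raises(self):
        with pytest.raises(InvalidArgumentError):
            get_config("eeglab_like")

    def test_summary_mentions_variant_and_peak(self, sphere, medium_array,
                                               coarse_grid, rng):
        lf = compute_leadfield(coarse_grid, medium_array, sphere)
        loc = coarse_grid.points[coarse_grid.nearest_index([0.0, 0.02, 0.05])]
        radial = loc / np.linalg.norm(loc)
        ori = np.cross(radial, [1.0, 0, 0])
        ori /= np.linalg.norm(ori)
        C, Cn = _covariances_for(point_gain(loc, medium_array, sphere), ori,
                                 1e-8, 1e-13, rng)
        res = LCMVBeamformer(C, Cn, lf, medium_array, "mne_like").fit()
        text = res.summary()
        assert "mne_like" in text and "peak" in text.lower()
        frame = res.to_frame()
        assert {"x", "y", "z", "nai"}.issubset(frame.columns)
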