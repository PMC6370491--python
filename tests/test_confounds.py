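"""Confound regression: regressor assembly, filtering, despiking, CompCor
and residualization contracts."""

import warnings

import numpy as np
import pytest
from scipy import signal as sps

import dfcbench as d
from dfcbench.confounds import PIPELINES, _expand_quadratic


class TestTemporalDerivative:
    def test_constant_series_zero(self):
        assert np.array_equal(d.temporal_derivative(np.full(10, 3.0)), np.zeros(10))

    def test_hand_example(self):
        assert np.array_equal(
            d.temporal_derivative(np.array([0.0, 1.0, 3.0])), [0.0, 1.0, 2.0]
        )

    def test_unit_ramp(self):
        out = d.temporal_derivative(np.arange(6.0))
        assert np.array_equal(out, [0, 1, 1, 1, 1, 1])


class TestFristonExpansion:
    def test_column_count(self, rng):
        rp6 = rng.standard_normal((50, 6))
        assert d.expand_friston(rp6).shape == (50, 24)

    def test_zero_in_zero_out(self):
        assert not d.expand_friston(np.zeros((20, 6))).any()

    def test_block_definitions(self, rng):
        rp6 = rng.standard_normal((30, 6))
        out = d.expand_friston(rp6)
        i = 2
        assert np.array_equal(out[:, 6 + i], d.temporal_derivative(rp6[:, i]))
        assert np.array_equal(out[:, 12 + i], rp6[:, i] ** 2)
        assert np.array_equal(
            out[:, 18 + i], d.temporal_derivative(rp6[:, i]) ** 2
        )

    def test_wrong_width_rejected(self, rng):
        with pytest.raises(ValueError):
            d.expand_friston(rng.standard_normal((30, 5)))


class TestBandpass:
    def test_dc_rejection(self):
        out = d.bandpass(np.full((200, 1), 5.0), tr=3.0)
        assert np.abs(out).max() < 5.0 * 1e-8

    @pytest.mark.parametrize("freq,lo,hi", [(0.04, 0.9, 1.0), (0.15, 0.0, 0.5)])
    def test_sinusoid_gain_matches_designed_response(self, freq, lo, hi):
        """Oracle: evaluate |H(f)|^2 of the designed filter (filtfilt squares
        the magnitude response) and compare with the measured amplitude."""
        tr, n = 3.0, 480
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * freq * t)
        out = d.bandpass(x[:, None], tr=tr)[:, 0]
        amp = out[n // 4 : -n // 4].std() / x[n // 4 : -n // 4].std()
        nyq = 0.5 / tr
        b, a = sps.butter(1, [0.01 / nyq, 0.08 / nyq], btype="bandpass")
        _, h = sps.freqz(b, a, worN=[freq], fs=1 / tr)
        expected = np.abs(h[0]) ** 2
        assert lo <= amp <= hi
        assert amp == pytest.approx(expected, abs=0.05)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            d.bandpass(np.zeros((50, 1)), tr=3.0, f_hi=0.2)


class TestDespike:
    def _smooth(self, n=120):
        return np.sin(2 * np.pi * np.arange(n) / 60.0)[None, :]

    def test_smooth_series_unchanged(self):
        x = self._smooth()
        assert np.array_equal(d.despike(x), x)

    def test_single_spike_capped(self):
        x = self._smooth().copy()
        med = sps.medfilt(x, (1, 7))
        mad = np.median(np.abs(x - med))
        x_spiked = x.copy()
        x_spiked[0, 60] += 10 * mad
        out = d.despike(x_spiked)
        med2 = sps.medfilt(x_spiked, (1, 7))
        resid = out[0, 60] - med2[0, 60]
        mad2 = np.median(np.abs(x_spiked - med2))
        assert abs(resid) <= 4.0 * mad2 + 1e-12
        # untouched elsewhere
        mask = np.ones(120, dtype=bool)
        mask[60] = False
        assert np.array_equal(out[0, mask], x_spiked[0, mask])

    def test_idempotent(self, rng):
        x = rng.standard_normal((5, 100))
        x[2, 50] += 30.0
        once = d.despike(x)
        assert np.array_equal(d.despike(once), once)

    def test_residuals_within_cap_everywhere(self, rng):
        x = np.cumsum(rng.standard_normal((8, 150)), axis=1)
        x[3, 75] += 50
        out = d.despike(x)
        med = sps.medfilt(out, (1, 7))
        resid = np.abs(out - med)
        mad = np.median(np.abs(x - sps.medfilt(x, (1, 7))), axis=1, keepdims=True)
        assert np.all(resid <= 4.0 * mad + 1e-9)


class TestCompCor:
    def test_rank_one_pool(self, rng):
        base = rng.standard_normal(80)
        pool = np.outer(base, rng.uniform(0.5, 2.0, size=12))
        comps = d.compcor(pool, 1)
        # single component carries all the variance: it reproduces the base
        r = abs(np.corrcoef(comps[:, 0], base)[0, 1])
        assert r > 0.9999

    def test_orthonormal(self, rng):
        comps = d.compcor(rng.standard_normal((100, 40)), 5)
        assert np.allclose(comps.T @ comps, np.eye(5), atol=1e-8)

    def test_acompcor_gives_ten_columns(self, subject):
        rs = d.assemble_regressors(subject, d.PipelineSpec.from_name("ACOMPCOR"))
        assert sum(p == "acompcor" for p in rs.provenance) == 10

    def test_too_many_components_rejected(self, rng):
        base = rng.standard_normal(50)
        pool = np.outer(base, np.arange(1, 6, dtype=float))
        with pytest.raises(ValueError):
            d.compcor(pool, 2)


class TestHighVariancePool:
    def test_identity_at_fraction_one(self, rng):
        x = rng.standard_normal((30, 15))
        assert np.array_equal(d.select_high_variance_pool(x, 1.0), x)

    def test_dominant_channel_kept(self, rng):
        x = rng.standard_normal((60, 50))
        x[:, 17] *= 100
        kept = d.select_high_variance_pool(x, 0.02)
        assert any(np.array_equal(kept[:, j], x[:, 17]) for j in range(kept.shape[1]))

    def test_ceiling_rule(self, rng):
        x = rng.standard_normal((30, 500))
        assert d.select_high_variance_pool(x, 0.02).shape[1] == 10


class TestLocalWM:
    def test_single_channel_in_radius(self, rng):
        wm = rng.standard_normal((40, 1))
        out = d.local_wm_regressor([0, 0, 0], wm, np.array([[5.0, 0, 0]]))
        assert np.array_equal(out, wm[:, 0])

    def test_mean_of_channels_in_radius(self, rng):
        wm = rng.standard_normal((40, 2))
        coords = np.array([[5.0, 0, 0], [0, 5.0, 0]])
        out = d.local_wm_regressor([0, 0, 0], wm, coords)
        assert np.allclose(out, wm.mean(axis=1))

    def test_nearest_fallback_warns(self, rng):
        wm = rng.standard_normal((40, 2))
        coords = np.array([[40.0, 0, 0], [90.0, 0, 0]])
        with pytest.warns(UserWarning, match="nearest"):
            out = d.local_wm_regressor([0, 0, 0], wm, coords)
        assert np.array_equal(out, wm[:, 0])


class TestAssembleAndApply:
    @pytest.mark.parametrize(
        "name,n_cols",
        [("2P", 2), ("6P", 6), ("9P", 9), ("24P", 24), ("36P", 36), ("RAW", 0)],
    )
    def test_registry_column_counts(self, subject, name, n_cols):
        rs = d.assemble_regressors(subject, d.PipelineSpec.from_name(name))
        assert rs.n_columns == n_cols

    def test_gsr_flag_implied(self):
        assert d.PipelineSpec.from_name("9P").gsr
        assert d.PipelineSpec.from_name("36P").gsr
        assert not d.PipelineSpec.from_name("6P").gsr
        assert d.PipelineSpec.from_name("6P+GSR").gsr

    def test_unknown_pipeline_rejected(self):
        with pytest.raises(ValueError):
            d.PipelineSpec.from_name("13P")

    def test_intercept_only_demeans(self, subject):
        res = d.apply_pipeline(subject, "RAW")
        expected = d.bandpass(subject.contaminated_signals, 3.0, axis=1)
        expected -= expected.mean(axis=1, keepdims=True)
        assert np.allclose(res, expected, atol=1e-10)

    @pytest.mark.parametrize("name", sorted(set(PIPELINES) - {"RAW", "WMLOCAL"}))
    def test_residuals_orthogonal_to_design(self, subject, name):
        spec = d.PipelineSpec.from_name(name)
        res = d.apply_pipeline(subject, spec)
        rs = d.assemble_regressors(subject, spec)
        design = d.bandpass(rs.matrix, 3.0, axis=0)
        design /= np.linalg.norm(design, axis=0)
        rn = res / np.linalg.norm(res, axis=1, keepdims=True)
        assert np.abs(rn @ design).max() < 1e-6

    def test_gsr_residual_uncorrelated_with_global(self, subject):
        res = d.apply_pipeline(subject, "9P")
        g = d.bandpass(subject.nuisance.columns("global")[:, 0], 3.0)
        mean_series = res.mean(axis=0)
        # GSR drives the residual node-mean to numerical zero; when any mass
        # remains it must be uncorrelated with the global regressor
        if np.linalg.norm(mean_series) > 1e-10 * np.linalg.norm(res):
            assert abs(np.corrcoef(mean_series, g)[0, 1]) < 1e-6
        else:
            assert np.linalg.norm(mean_series) < 1e-10 * np.linalg.norm(res)

    def test_known_artifact_regressor_recovers_clean(self, atlas60):
        """A pipeline given the exact injected artifact series as regressor
        returns the band-passed clean signals."""
        model = d.ArtifactModel(global_drift_sd=0.0)
        mp = d.generate_motion_profile(120, 0.07, seed=8)
        clean = d.simulate_clean_signals(atlas60, model, seed=9)
        cont, _ = d.inject_artifact(clean, mp, atlas60, model, seed=10)
        artifact = cont - clean  # rank-1: w_i * u(t)
        u = artifact[np.argmax(np.abs(artifact).sum(axis=1))]
        design = np.column_stack([np.ones(120), d.bandpass(u, 3.0)])

        def residual(y):
            beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
            return y - (design @ beta).T

        res = residual(d.bandpass(cont, 3.0, axis=1))
        # the artifact is exactly in the regressor span, so the residual is
        # identical to the clean signal's own residual on the same design
        target = residual(d.bandpass(clean, 3.0, axis=1))
        rms = np.sqrt(np.mean((res - target) ** 2))
        assert rms < 1e-6
        # and what OLS takes from the clean signal itself is incidental
        demeaned = d.bandpass(clean, 3.0, axis=1)
        demeaned -= demeaned.mean(axis=1, keepdims=True)
        assert np.sqrt(np.mean((res - demeaned) ** 2)) < 0.2

    def test_nested_design_never_increases_residual_variance(self, subject):
        v6 = d.apply_pipeline(subject, "6P").var(axis=1)
        v24 = d.apply_pipeline(subject, "24P").var(axis=1)
        assert np.all(v24 <= v6 + 1e-12)

    def test_collinear_columns_dropped_with_warning(self, subject):
        rs = d.assemble_regressors(subject, d.PipelineSpec.from_name("6P"))
        from dfcbench.confounds import _check_rank

        design = np.hstack([rs.matrix, rs.matrix[:, :1]])
        with pytest.warns(UserWarning, match="collinear"):
            kept = _check_rank(design, "test")
        assert kept.shape[1] == np.linalg.matrix_rank(design)

    def test_wmlocal_requires_coordinates(self, subject):
        with pytest.raises(ValueError, match="coord"):
            d.apply_pipeline(subject, "WMLOCAL")

    def test_wmlocal_runs_with_coordinates(self, subject, atlas60):
        res = d.apply_pipeline(
            subject, "WMLOCAL", node_coords_mm=atlas60.coords_mm
        )
        assert res.shape == subject.contaminated_signals.shape
        assert np.all(np.isfinite(res))
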