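"""Normalisation, modulation profiles, latency fit, band power, RF mapping."""

import numpy as np
import pytest
from scipy.stats import norm as norm_dist

from lamflow import (
    AnalysisWindows,
    band_power,
    build_alignment,
    fit_latency,
    modulation_profile,
    normalize_mua,
    rf_from_bar,
)

T = np.arange(-300, 900, 1000.0 / 763.0)
W = AnalysisWindows()


def _session_mua(rng, n_trials=10, n_ch=6, peak=2.0, base=0.5):
    """Toy MUA: baseline + transient peaking inside 50-90 ms."""
    bump = peak * np.exp(-0.5 * ((T - 70) / 8.0) ** 2)
    x = base + bump[None, None, :] + 0.0 * rng.standard_normal((n_trials, n_ch, T.size))
    conds = np.array(["target", "distractor"] * (n_trials // 2))
    return x, conds


class TestNormalizeMUA:
    def test_baseline_identity_maps_to_zero(self, rng):
        x = np.full((6, 4, T.size), 1.3)
        x[:, :, T >= 50] += 1.0  # need a positive peak for a valid divisor
        conds = np.array(["target", "distractor"] * 3)
        out = normalize_mua(x, T, conds)
        assert np.allclose(out.values[:, :, T < 0], 0.0)

    def test_reference_peak_is_one(self, rng):
        x, conds = _session_mua(rng)
        out = normalize_mua(x, T, conds)
        ref = out.values[conds == "distractor"].mean(axis=0)
        mp = (T >= 50) & (T < 90)
        assert np.allclose(ref[:, mp].max(axis=1), 1.0)

    def test_shift_invariance_and_scale_equivariance(self, rng):
        x, conds = _session_mua(rng)
        out = normalize_mua(x, T, conds)
        shifted = normalize_mua(x + 7.0, T, conds)
        assert np.allclose(shifted.values, out.values)
        scaled = normalize_mua(3.0 * x, T, conds)
        assert np.allclose(scaled.values, out.values)

    def test_nonpositive_peak_flags_channel(self, rng):
        x, conds = _session_mua(rng)
        x[:, 2, :] = 1.0  # flat channel: no evoked peak
        out = normalize_mua(x, T, conds)
        assert not out.valid_channels[2]
        assert out.valid_channels[[0, 1, 3, 4, 5]].all()

    def test_missing_reference_condition(self, rng):
        x, _ = _session_mua(rng)
        with pytest.raises(ValueError, match="reference"):
            normalize_mua(x, T, np.array(["target"] * 10))


class TestModulationProfile:
    def test_identical_conditions_give_zero(self, rng):
        x, conds = _session_mua(rng, n_ch=24)
        out = normalize_mua(x, T, conds)
        al = build_alignment(8, 24)
        prof = modulation_profile(out, conds, T, al)
        assert np.allclose(prof.per_channel[out.valid_channels], 0.0)
        assert all(np.isclose(v, 0.0) for v in prof.compartment_means.values())

    def test_compartment_means_are_member_channel_means(self, rng):
        x, conds = _session_mua(rng, n_ch=24)
        x[conds == "target"] += 0.5  # uniform target gain
        out = normalize_mua(x, T, conds)
        al = build_alignment(8, 24)
        prof = modulation_profile(out, conds, T, al)
        for comp in ("deep", "layer4", "superficial"):
            sel = (al.compartment == comp) & out.valid_channels
            assert np.isclose(
                prof.compartment_means[comp], np.nanmean(prof.per_channel[sel])
            )

    def test_missing_condition_rejected(self, rng):
        x, conds = _session_mua(rng, n_ch=24)
        out = normalize_mua(x, T, conds)
        al = build_alignment(8, 24)
        with pytest.raises(ValueError, match="missing"):
            modulation_profile(out, conds, T, al, pair=("target", "target_adjacent"))


class TestLatency:
    def test_cumulative_gaussian_closed_form(self):
        # latency of a pure cumulative Gaussian = mu + s * z(0.33)
        t = np.arange(0, 200, 1000.0 / 763.0)
        y = norm_dist.cdf((t - 60.0) / 5.0)
        fit = fit_latency(y, t)
        expect = 60.0 + 5.0 * norm_dist.ppf(0.33)
        assert abs(fit.latency_ms - expect) < 1000.0 / 763.0
        assert fit.r_squared > 0.999

    def test_transient_plus_sustained_shape(self):
        t = np.arange(-50, 300, 1000.0 / 763.0)
        y = (
            0.1
            + 1.2 * np.exp(-0.5 * ((t - 70) / 12.0) ** 2)
            + 0.5 * norm_dist.cdf((t - 55.0) / 6.0)
        )
        fit = fit_latency(y, t)
        assert 35.0 < fit.latency_ms < 70.0
        assert fit.r_squared > 0.99

    def test_flat_response_rejected(self):
        t = np.arange(0, 100, 2.0)
        with pytest.raises(ValueError, match="rise"):
            fit_latency(np.zeros_like(t), t)


class TestBandPower:
    def test_single_tone_lands_in_its_band(self):
        fs = 763.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 50.0 * t)
        gamma = band_power(x, fs, (30, 90))
        alpha = band_power(x, fs, (5, 15))
        assert gamma > 100 * alpha

    def test_white_noise_power_tracks_bandwidth(self, rng):
        fs = 763.0
        x = rng.standard_normal((200, int(2 * fs)))
        p_wide = band_power(x, fs, (30, 90)).mean()
        p_half = band_power(x, fs, (30, 60)).mean()
        assert abs(p_wide / p_half - 2.0) < 0.2

    def test_additive_over_disjoint_bands(self):
        fs = 763.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 50 * t)
        total = band_power(x, fs, (5, 90))
        parts = band_power(x, fs, (5, 40)) + band_power(x, fs, (40, 90))
        assert np.isclose(total, parts, rtol=0.05)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros(100), 250.0, (30, 200))


class TestRFFromBar:
    def _sweeps(self, center, width, height, latency_s=0.0, speed=2.0):
        """Boxcar responses of a rectangular RF to 8 bar sweeps."""
        t_ms = np.arange(0, 8000.0, 4.0)
        t_s = t_ms / 1000.0
        responses, origins = {}, {}
        half = {0: width / 2, 90: height / 2, 180: width / 2, 270: height / 2}
        for d in range(0, 360, 45):
            u = np.array([np.cos(np.deg2rad(d)), np.sin(np.deg2rad(d))])
            origin = np.asarray(center) - 8.0 * u  # start 8 deg before centre
            s = (origin + speed * t_s[:, None] * u) @ u
            c = np.asarray(center) @ u
            h = half.get(d % 180 if d % 90 == 0 else -1, None)
            if h is None:  # diagonal sweeps: project the box onto the axis
                h = (
                    abs(width / 2 * u[0]) + abs(height / 2 * u[1])
                )
            inside = np.abs(s - c) <= h
            resp = np.zeros_like(t_s)
            lag = int(round(latency_s * 1000.0 / 4.0))
            resp[np.flatnonzero(inside) + lag] = 1.0
            responses[d] = resp
            origins[d] = tuple(origin)
        return responses, t_ms, origins, speed

    def test_boxcar_rf_width_recovered_exactly(self):
        responses, t_ms, origins, speed = self._sweeps((3.0, -2.0), 1.4, 1.4)
        rf = rf_from_bar(responses, t_ms, origins, speed)
        assert abs(rf.width_deg - 1.4) < 0.02
        assert abs(rf.height_deg - 1.4) < 0.02
        assert np.allclose(rf.center_deg, (3.0, -2.0), atol=0.02)
        assert abs(rf.eccentricity_deg - np.hypot(3, 2)) < 0.05

    def test_latency_bias_cancels_in_midpoints(self):
        no_lag = rf_from_bar(*self._sweeps((1.0, 1.0), 1.4, 1.0, latency_s=0.0))
        lagged = rf_from_bar(*self._sweeps((1.0, 1.0), 1.4, 1.0, latency_s=0.2))
        assert np.allclose(lagged.center_deg, no_lag.center_deg, atol=0.02)
        assert abs(lagged.width_deg - no_lag.width_deg) < 0.02

    def test_missing_direction_rejected(self):
        responses, t_ms, origins, speed = self._sweeps((0.0, 0.0), 1.0, 1.0)
        del responses[135]
        with pytest.raises(ValueError, match="missing"):
            rf_from_bar(responses, t_ms, origins, speed)
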