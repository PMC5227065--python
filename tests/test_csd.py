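"""CSD operator, forward model, template and modulation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamflow import (
    CSDParams,
    abs_csd_modulation,
    compute_csd,
    lfp_from_csd,
    make_template,
    ncsd_timecourse,
    normalize_csd,
)

P = CSDParams()
DEPTHS = 0.1 * np.arange(24)


class TestComputeCSD:
    def test_quadratic_potential_closed_form(self):
        # phi = x^2 (mV, x in mm): second difference is exact for quadratics,
        # CSD = -sigma * 2 = -0.8 at every valid channel
        phi = (DEPTHS**2)[:, None] * np.ones((1, 5))
        csd = compute_csd(phi, P)
        assert np.allclose(csd.values[csd.valid_channels], -0.8)

    @given(
        offset=st.floats(-5, 5),
        slope=st.floats(-5, 5),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_potentials_annihilated(self, offset, slope):
        phi = offset + slope * DEPTHS
        csd = compute_csd(phi, P)
        assert np.allclose(csd.values[csd.valid_channels], 0.0, atol=1e-9)

    def test_linearity(self, rng):
        a, b = rng.standard_normal((2, 24, 11))
        lhs = compute_csd(3.0 * a - 2.0 * b, P).values
        rhs = 3.0 * compute_csd(a, P).values - 2.0 * compute_csd(b, P).values
        assert np.allclose(lhs, rhs, equal_nan=True)

    def test_edge_channels_masked_not_zeroed(self, rng):
        csd = compute_csd(rng.standard_normal((24, 4)), P)
        assert np.isnan(csd.values[:2]).all() and np.isnan(csd.values[-2:]).all()
        assert csd.valid_channels.sum() == 20

    def test_h_one_spacing_uses_nearest_neighbours(self):
        params = CSDParams(h_mm=0.1)
        phi = (DEPTHS**2)[:, None]
        csd = compute_csd(phi, params)
        assert np.allclose(csd.values[csd.valid_channels], -0.8)
        assert csd.valid_channels.sum() == 22

    def test_too_few_channels(self):
        with pytest.raises(ValueError, match="channels"):
            compute_csd(np.zeros((4, 3)), P)

    def test_h_must_be_multiple_of_spacing(self):
        with pytest.raises(ValueError, match="multiple"):
            CSDParams(h_mm=0.15)

    def test_sigma_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            CSDParams(sigma_s_per_m=-0.4)


class TestForwardModel:
    def test_roundtrip_exact_at_interior(self, rng):
        C = rng.standard_normal((24, 50))
        back = compute_csd(lfp_from_csd(C, P), P)
        v = back.valid_channels
        assert np.allclose(back.values[v], C[v], atol=1e-10)

    def test_zero_csd_zero_boundaries_gives_zero_lfp(self):
        phi = lfp_from_csd(np.zeros((24, 5)), P, boundary_values=(0.0, 0.0))
        assert np.all(phi == 0.0)

    def test_linearity(self, rng):
        C = rng.standard_normal((24, 7))
        assert np.allclose(lfp_from_csd(2 * C, P), 2 * lfp_from_csd(C, P))

    def test_boundary_values_respected(self, rng):
        C = rng.standard_normal((24, 3))
        phi = lfp_from_csd(C, P, boundary_values=(1.5, -0.5))
        assert np.allclose(phi[0], 1.5) and np.allclose(phi[-1], -0.5)

    def test_nonfinite_rejected(self):
        C = np.zeros((24, 2))
        C[3, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            lfp_from_csd(C, P)


class TestTemplateAndNCSD:
    def _csd(self, values):
        return compute_csd(values, P)

    def test_single_sink_template(self):
        phi_like = np.zeros((24, 10))
        phi_like[10] = -5.0  # constant-in-time profile with one sink
        csd = self._csd(lfp_from_csd(phi_like, P))
        t = np.linspace(0, 9, 10)
        tpl = make_template(csd, (0, 10), times_ms=t)
        w = tpl.weights[tpl.valid_channels]
        assert np.isclose(w.min(), -1.0)
        assert np.nanargmin(tpl.weights) == 10

    def test_template_formula(self, rng):
        C = rng.standard_normal((24, 12))
        csd = self._csd(lfp_from_csd(C, P))
        t = np.arange(12.0)
        tpl = make_template(csd, (2, 9), times_ms=t)
        prof = csd.values[:, (t >= 2) & (t < 9)].mean(axis=1)
        expect = prof / abs(prof[csd.valid_channels].min())
        assert np.allclose(tpl.weights, expect, equal_nan=True)

    def test_all_zero_window_rejected(self):
        csd = self._csd(np.zeros((24, 5)))
        with pytest.raises(ValueError, match="zero"):
            make_template(csd, (0, 5), times_ms=np.arange(5.0))

    def test_ncsd_brute_force(self, rng):
        C = rng.standard_normal((24, 7))
        csd = self._csd(lfp_from_csd(C, P))
        t = np.arange(7.0)
        tpl = make_template(csd, (0, 7), times_ms=t)
        got = ncsd_timecourse(csd, tpl)
        v = csd.valid_channels
        expect = [
            sum(tpl.weights[c] * csd.values[c, j] for c in np.flatnonzero(v))
            for j in range(7)
        ]
        assert np.allclose(got, expect)

    def test_ncsd_channel_mismatch(self, rng):
        C = rng.standard_normal((24, 7))
        csd = self._csd(lfp_from_csd(C, P))
        t = np.arange(7.0)
        tpl = make_template(csd, (0, 7), times_ms=t)
        other = compute_csd(lfp_from_csd(C, CSDParams(h_mm=0.1)), CSDParams(h_mm=0.1))
        with pytest.raises(ValueError, match="channel"):
            ncsd_timecourse(other, tpl)


class TestAbsModulation:
    def test_identical_conditions_zero(self, rng):
        C = rng.standard_normal((24, 10))
        csd = compute_csd(lfp_from_csd(C, P), P)
        t = np.arange(10.0)
        assert abs_csd_modulation(csd, csd, (0, 10), times_ms=t) == 0.0

    def test_antisymmetric_difference_does_not_cancel(self):
        # +d on half the valid channels, -d on the other half -> result d
        d = 0.7
        diff = np.zeros((24, 6))
        diff[2:12] = +d
        diff[12:22] = -d
        a = compute_csd(lfp_from_csd(diff, P), P)
        b = compute_csd(lfp_from_csd(np.zeros((24, 6)), P), P)
        t = np.arange(6.0)
        assert np.isclose(abs_csd_modulation(a, b, (0, 6), times_ms=t), d)

    def test_shape_mismatch(self, rng):
        a = compute_csd(rng.standard_normal((24, 5)), P)
        b = compute_csd(rng.standard_normal((24, 6)), P)
        with pytest.raises(ValueError, match="shape"):
            abs_csd_modulation(a, b, (0, 5), times_ms=np.arange(5.0))


def test_normalize_csd_unit_peak(rng):
    C = rng.standard_normal((24, 20))
    csd = compute_csd(lfp_from_csd(C, P), P, times_ms=np.arange(20.0))
    out = normalize_csd(csd, csd, (0, 20))
    assert np.isclose(np.nanmax(np.abs(out.values)), 1.0)
    assert out.units == "normalized"
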