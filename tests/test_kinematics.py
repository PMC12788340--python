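"""Resultant velocity, differentiation, filtering, residual analysis, gaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strideval.kinematics import (
    KinematicSeries,
    butterworth_lowpass,
    central_difference,
    fill_gaps,
    residual_analysis,
    resultant_magnitude,
)


def series(values, rate=100.0, label=""):
    return KinematicSeries.from_values(np.asarray(values, dtype=float), rate, label=label)


class TestResultant:
    def test_345_triangle(self):
        out = resultant_magnitude(series([3.0] * 5), series([4.0] * 5), series([0.0] * 5))
        assert np.allclose(out.values, 5.0)

    def test_single_component_identity(self):
        v = series([-2.0, 1.0, 3.0])
        out = resultant_magnitude(v, series([0, 0, 0]), series([0, 0, 0]))
        assert np.allclose(out.values, np.abs(v.values))

    def test_matches_scalar_oracle_and_dominates_components(self, rng):
        vx, vy, vz = (series(rng.normal(size=200)) for _ in range(3))
        out = resultant_magnitude(vx, vy, vz)
        oracle = [
            (a * a + b * b + c * c) ** 0.5
            for a, b, c in zip(vx.values, vy.values, vz.values)
        ]
        assert np.allclose(out.values, oracle, rtol=1e-12)
        stacked = np.abs(np.vstack([vx.values, vy.values, vz.values]))
        assert np.all(out.values >= stacked.max(axis=0) - 1e-12)

    def test_mismatched_time_bases_rejected(self):
        a = series([1.0, 2.0, 3.0])
        b = KinematicSeries.from_values(np.ones(3), 100.0, t0=0.5)
        with pytest.raises(ValueError):
            resultant_magnitude(a, a, b)


class TestCentralDifference:
    def test_linear_ramp_exact(self):
        t = np.arange(100) / 100.0
        out = central_difference(series(2.0 * t))
        assert np.allclose(out.values, 2.0, atol=1e-9)

    def test_constant_is_zero_and_length_preserved(self):
        out = central_difference(series(np.full(50, 3.3)))
        assert np.allclose(out.values, 0.0)
        assert len(out) == 50

    def test_sine_error_within_taylor_bound(self):
        f, rate = 1.0, 100.0
        t = np.arange(1000) / rate
        w = 2 * np.pi * f
        out = central_difference(series(np.sin(w * t), rate))
        bound = w**3 / rate**2 / 6.0
        err = np.abs(out.values[1:-1] - w * np.cos(w * t[1:-1]))
        assert err.max() < bound

    def test_linearity(self, rng):
        u, w = rng.normal(size=64), rng.normal(size=64)
        lhs = central_difference(series(2.5 * u - 1.5 * w)).values
        rhs = 2.5 * central_difference(series(u)).values - 1.5 * central_difference(series(w)).values
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            central_difference(series([1.0, 2.0]))


class TestButterworth:
    def _attenuation(self, f_sig, cutoff, rate=1000.0, n=8192):
        t = np.arange(n) / rate
        s = series(np.sin(2 * np.pi * f_sig * t), rate)
        out = butterworth_lowpass(s, cutoff)
        freqs = np.fft.rfftfreq(n, 1 / rate)
        amp_in = np.abs(np.fft.rfft(s.values))
        amp_out = np.abs(np.fft.rfft(out.values))
        k = np.argmin(np.abs(freqs - f_sig))
        return amp_out[k] / amp_in[k]

    def test_dc_gain_unity(self):
        s = series(np.full(500, 4.2))
        out = butterworth_lowpass(s, 7.32)
        assert np.allclose(out.values, 4.2, atol=1e-9)

    def test_passband_nearly_transparent(self):
        assert self._attenuation(0.2 * 10.0, 10.0) > 0.99

    def test_stopband_heavily_attenuated(self):
        assert self._attenuation(5 * 10.0, 10.0) < 0.01

    def test_minus_3db_at_nominal_cutoff(self):
        gain = self._attenuation(10.0, 10.0)
        assert gain == pytest.approx(2**-0.5, abs=0.01)

    def test_band_limited_signal_nearly_unchanged(self):
        rate = 100.0
        t = np.arange(4096) / rate
        s = series(np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 2.0 * t), rate)
        out = butterworth_lowpass(s, 15.0)
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert abs(rms(out.values) - rms(s.values)) / rms(s.values) < 0.01

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(series(np.ones(100)), 60.0, order=4)


class TestResidualAnalysis:
    def test_pure_low_frequency_signal_preserved_at_chosen_cutoff(self):
        """Noiseless 2 Hz sine: the extrapolated noise floor is ~0, so the
        rule selects the cutoff at which passband distortion of the 2 Hz
        component vanishes; the signal survives essentially intact there."""
        rate = 100.0
        t = np.arange(4000) / rate
        s = series(np.sin(2 * np.pi * 2.0 * t), rate)
        curve = residual_analysis(s)
        assert 4.0 <= curve.chosen_cutoff <= 20.0
        assert curve.noise_intercept < 1e-3
        idx = np.argmin(np.abs(curve.candidate_cutoffs - curve.chosen_cutoff))
        assert curve.residual_rms[idx] < 1e-3

    def test_chosen_cutoff_respects_range_under_noise(self, rng):
        rate = 100.0
        t = np.arange(2000) / rate
        for _ in range(10):
            s = series(np.sin(2 * np.pi * 2 * t) + rng.normal(0, 0.3, len(t)), rate)
            curve = residual_analysis(s)
            assert 4.0 <= curve.chosen_cutoff <= 20.0

    def test_noise_intercept_estimates_noise_rms(self, rng):
        """Monte-Carlo oracle: the 0 Hz extrapolation of the residual line
        estimates the white-noise RMS for a fully in-band signal."""
        rate, n, sigma = 100.0, 10_000, 0.05
        t = np.arange(n) / rate
        intercepts = []
        for _ in range(50):
            s = series(np.sin(2 * np.pi * 2 * t) + rng.normal(0, sigma, n), rate)
            intercepts.append(residual_analysis(s).noise_intercept)
        assert np.mean(intercepts) == pytest.approx(sigma, rel=0.15)

    def test_degenerate_constant_signal(self):
        curve = residual_analysis(series(np.full(1000, 2.0)))
        assert curve.chosen_cutoff == 4.0
        assert np.allclose(curve.residual_rms, 0.0)


class TestFillGaps:
    def test_one_frame_gap_linear_exact(self):
        x = np.arange(40.0)
        x[17] = np.nan
        filled, missing = fill_gaps(x)
        assert not missing.any()
        assert filled[17] == pytest.approx(17.0, abs=1e-9)

    def test_three_frame_gap_cubic_exact(self):
        t = np.linspace(0, 1, 60)
        x = 2 - t + 3 * t**2 - 0.5 * t**3
        y = x.copy()
        y[20:23] = np.nan
        filled, missing = fill_gaps(y)
        assert not missing.any()
        assert np.allclose(filled, x, atol=1e-9)

    def test_six_frame_gap_untouched(self):
        x = np.arange(40.0)
        x[10:16] = np.nan
        filled, missing = fill_gaps(x, max_gap_frames=5)
        assert missing[10:16].all()
        assert np.isnan(filled[10:16]).all()

    def test_boundary_gap_left_missing(self):
        x = np.arange(20.0)
        x[:2] = np.nan
        filled, missing = fill_gaps(x)
        assert missing[:2].all()


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_resultant_pointwise_dominance_property(seed):
    rng = np.random.default_rng(seed)
    comps = [KinematicSeries.from_values(rng.normal(size=32), 100.0) for _ in range(3)]
    out = resultant_magnitude(*comps)
    for c in comps:
        assert np.all(out.values + 1e-12 >= np.abs(c.values))
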