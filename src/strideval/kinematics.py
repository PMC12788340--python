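"""Kinematic signal derivation and filtering.

Implements the criterion-side processing chain: resultant centre-of-mass
velocity from its three components, numerical differentiation by central
differences, zero-phase low-pass Butterworth smoothing with a cascade
correction so the -3 dB point of the forward-backward filter sits at the
nominal cutoff, residual-analysis cutoff selection (Winter's procedure over
4-20 Hz), and short-gap interpolation of marker trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "KinematicSeries",
    "ResidualCurve",
    "resultant_magnitude",
    "central_difference",
    "butterworth_lowpass",
    "residual_analysis",
    "select_cutoff",
    "fill_gaps",
]


@dataclass(frozen=True)
class KinematicSeries:
    """A uniformly sampled scalar kinematic signal."""

    times: np.ndarray
    values: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(t) >= 2:
            period = 1.0 / self.rate
            if np.max(np.abs(np.diff(t) - period)) > 1e-6 * period:
                raise ValueError("sampling is not uniform at the stated rate")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_values(
        cls, values: np.ndarray, rate: float, t0: float = 0.0, label: str = ""
    ) -> "KinematicSeries":
        values = np.asarray(values, dtype=float)
        times = t0 + np.arange(len(values)) / rate
        return cls(times, values, rate, label)

    def replace_values(self, values: np.ndarray, label: str | None = None) -> "KinematicSeries":
        return KinematicSeries(
            self.times, values, self.rate, self.label if label is None else label
        )

    def slice_time(self, t_lo: float, t_hi: float) -> "KinematicSeries":
        keep = (self.times >= t_lo - 1e-12) & (self.times <= t_hi + 1e-12)
        idx = np.flatnonzero(keep)
        return KinematicSeries(
            self.times[idx], self.values[idx], self.rate, self.label
        )


@dataclass(frozen=True)
class ResidualCurve:
    """Residual-versus-cutoff curve with the selected Winter cutoff."""

    candidate_cutoffs: np.ndarray
    residual_rms: np.ndarray
    chosen_cutoff: float
    noise_intercept: float
    fit_region: tuple[float, float] = field(default=(0.75, 1.0))


def _same_time_base(*series: KinematicSeries) -> None:
    ref = series[0]
    for s in series[1:]:
        if len(s) != len(ref) or s.rate != ref.rate:
            raise ValueError("series have mismatched time bases")
        if len(ref) and np.max(np.abs(s.times - ref.times)) > 1e-9 / ref.rate:
            raise ValueError("series have mismatched time bases")


def resultant_magnitude(
    vx: KinematicSeries, vy: KinematicSeries, vz: KinematicSeries
) -> KinematicSeries:
    """Elementwise Euclidean magnitude of three velocity components."""
    _same_time_base(vx, vy, vz)
    mag = np.sqrt(vx.values**2 + vy.values**2 + vz.values**2)
    return vx.replace_values(mag, label="resultant")


def central_difference(v: KinematicSeries) -> KinematicSeries:
    """Differentiate by central differences; endpoints use first-order
    one-sided differences so the output keeps the input's time base."""
    if len(v) < 3:
        raise ValueError("need at least three samples to differentiate")
    dv = np.gradient(v.values, 1.0 / v.rate, edge_order=1)
    return v.replace_values(dv, label=f"d({v.label})/dt")


def _design_sos(cutoff: float, rate: float, order: int) -> np.ndarray:
    if not 0 < cutoff < rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    if order < 2 or order % 2:
        raise ValueError("effective order must be a positive even integer")
    # Forward-backward filtering doubles the order, so design at order/2 per
    # pass and push the design cutoff up so the double-pass -3 dB point lands
    # on the requested frequency.
    per_pass = order // 2
    corr = (2**0.5 - 1) ** (-1.0 / (2 * per_pass))
    fc = cutoff * corr
    if fc >= rate / 2:
        raise ValueError("cascade-corrected cutoff reaches Nyquist")
    return signal.butter(per_pass, fc, btype="low", fs=rate, output="sos")


def butterworth_lowpass(
    s: KinematicSeries, cutoff: float, order: int = 4
) -> KinematicSeries:
    """Zero-phase low-pass Butterworth filter of the given effective order."""
    sos = _design_sos(cutoff, s.rate, order)
    out = signal.sosfiltfilt(sos, s.values)
    return s.replace_values(out, label=f"{s.label}|lp{cutoff:g}")


def residual_analysis(
    s: KinematicSeries,
    fc_min: float = 4.0,
    fc_max: float = 20.0,
    n_candidates: int = 33,
    order: int = 4,
    fit_region: tuple[float, float] = (0.75, 1.0),
) -> ResidualCurve:
    """Winter residual analysis over a candidate cutoff range.

    For each candidate cutoff the RMS of raw-minus-filtered residual is
    computed; a line fitted to the noise-dominated upper region of the curve
    (``fit_region`` as fractions of ``fc_max``) is extrapolated to 0 Hz to
    estimate the noise floor, and the chosen cutoff is the lowest candidate
    whose residual does not exceed that floor.
    """
    if s.rate <= 2 * fc_max:
        raise ValueError("sampling rate must exceed twice fc_max")
    candidates = np.linspace(fc_min, fc_max, n_candidates)
    if np.std(s.values) < 1e-12:
        return ResidualCurve(
            candidates, np.zeros_like(candidates), float(fc_min), 0.0, fit_region
        )
    residuals = np.array(
        [
            float(np.sqrt(np.mean((s.values - butterworth_lowpass(s, fc, order).values) ** 2)))
            for fc in candidates
        ]
    )
    chosen, intercept = select_cutoff(candidates, residuals, fc_max, fit_region)
    chosen = float(np.clip(chosen, fc_min, fc_max))
    return ResidualCurve(candidates, residuals, chosen, intercept, fit_region)


def select_cutoff(
    candidates: np.ndarray,
    residuals: np.ndarray,
    fc_max: float | None = None,
    fit_region: tuple[float, float] = (0.75, 1.0),
) -> tuple[float, float]:
    """Apply Winter's criterion to a residual curve (possibly averaged over
    trials); returns (chosen cutoff, extrapolated noise intercept)."""
    if fc_max is None:
        fc_max = float(candidates[-1])
    lo, hi = fit_region[0] * fc_max, fit_region[1] * fc_max
    sel = (candidates >= lo - 1e-12) & (candidates <= hi + 1e-12)
    if sel.sum() < 2:
        raise ValueError("fit region contains fewer than two candidates")
    slope, intercept = np.polyfit(candidates[sel], residuals[sel], 1)
    ok = np.flatnonzero(residuals <= intercept)
    chosen = float(candidates[ok[0]]) if len(ok) else float(fc_max)
    return chosen, float(intercept)


def fill_gaps(
    values: np.ndarray, max_gap_frames: int = 5, n_support: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate short missing stretches (NaN runs) of a trajectory.

    Gaps of at most ``max_gap_frames`` interior frames are filled with a
    quintic spline through the ``n_support`` nearest valid frames on each
    side.  Longer gaps and gaps touching either boundary are left missing.
    Returns ``(filled, still_missing)``.
    """
    x = np.asarray(values, dtype=float).copy()
    missing = ~np.isfinite(x)
    still = missing.copy()
    if not missing.any():
        return x, still
    idx = np.arange(len(x))
    runs = []
    in_run = False
    for i, m in enumerate(missing):
        if m and not in_run:
            start, in_run = i, True
        elif not m and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(x)))
    for s, e in runs:
        if e - s > max_gap_frames or s == 0 or e == len(x):
            continue
        left = idx[:s][np.isfinite(x[:s])][-n_support:]
        right = idx[e:][np.isfinite(x[e:])][:n_support]
        support = np.concatenate([left, right])
        if len(left) < n_support or len(right) < n_support:
            k = min(5, len(support) - 1)
            if k < 1:
                continue
        else:
            k = 5
        spl = interpolate.make_interp_spline(support, x[support], k=k)
        x[s:e] = spl(idx[s:e])
        still[s:e] = False
    return x, still
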