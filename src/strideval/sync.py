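"""Cross-device synchronization: upsampling, rigid lag alignment, stride
matching.

The device stream is upsampled to the mocap rate, shifted onto the criterion
clock by exhaustively searching integer-sample lags for the smallest RMSE
against the criterion velocity, and stride-level records from the two
systems are then matched one-to-one by nearest event time on the same foot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import KinematicSeries

__all__ = [
    "AlignmentResult",
    "MatchedStridePairs",
    "upsample",
    "align_min_rmse",
    "match_stride_events",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a min-RMSE lag search.

    ``lag`` is the shift of the target stream relative to the reference
    clock: subtracting ``lag`` from the target's timestamps brings it onto
    the reference clock.
    """

    lag: float
    rmse_at_lag: float
    overlap_samples: int
    searched_lags: np.ndarray
    searched_rmse: np.ndarray


@dataclass(frozen=True)
class MatchedStridePairs:
    """One-to-one stride pairing between device and criterion records."""

    pairs: pd.DataFrame  # device_* and criterion_* columns plus time_offset
    n_unmatched_device: int
    n_unmatched_criterion: int


def upsample(
    s: KinematicSeries, target_rate: float = 100.0, kind: str = "linear"
) -> KinematicSeries:
    """Resample onto a finer grid spanning the same time range.

    ``target_rate`` must be an integer multiple of the source rate; original
    samples are preserved exactly.  ``kind`` is ``linear`` (default) or
    ``cubic`` for sensitivity checks.
    """
    ratio = target_rate / s.rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("target rate must be an integer multiple of the source rate")
    ratio = int(round(ratio))
    n_new = (len(s) - 1) * ratio + 1
    times = s.times[0] + np.arange(n_new) / target_rate
    if kind == "linear":
        values = np.interp(times, s.times, s.values)
    elif kind == "cubic":
        from scipy.interpolate import CubicSpline

        values = CubicSpline(s.times, s.values)(times)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    values[::ratio] = s.values  # exact preservation of source samples
    return KinematicSeries(times, values, target_rate, s.label)


def align_min_rmse(
    reference: KinematicSeries,
    target: KinematicSeries,
    max_lag: float = 2.0,
    lag_step: int = 1,
    min_overlap: int = 20,
    demean: bool = False,
) -> AlignmentResult:
    """Exhaustive integer-sample lag search minimising RMSE on the overlap.

    Ties are broken towards the smallest ``|lag|``, then negative before
    positive.  Raises if no searched lag achieves ``min_overlap`` samples.

    With ``demean=True`` each overlap segment has its own mean removed
    before the RMSE is computed, so the search keys on signal shape alone.
    A device with a systematic velocity offset would otherwise pull the lag
    towards wherever the offset can be traded against the velocity trend.
    """
    if abs(reference.rate - target.rate) > 1e-9:
        raise ValueError("reference and target must share a sampling rate")
    dt = 1.0 / reference.rate
    ref = reference.values
    tgt = target.values
    offset0 = int(round((target.times[0] - reference.times[0]) / dt))
    k_max = int(round(max_lag / dt))
    ks = sorted(range(-k_max, k_max + 1, lag_step), key=lambda k: (abs(k), k))

    best: tuple[float, int, int] | None = None  # (rmse, k, overlap)
    lags, rmses = [], []
    for k in ks:
        m0 = max(0, k - offset0)
        m1 = min(len(tgt), k - offset0 + len(ref))
        overlap = m1 - m0
        if overlap < min_overlap:
            continue
        j0 = m0 + offset0 - k
        a = ref[j0 : j0 + overlap]
        b = tgt[m0:m1]
        d = (a - np.mean(a)) - (b - np.mean(b)) if demean else a - b
        rmse = float(np.sqrt(np.mean(d * d)))
        lags.append(k * dt)
        rmses.append(rmse)
        if best is None or rmse < best[0]:
            best = (rmse, k, overlap)
    if best is None:
        raise ValueError("insufficient overlap at every searched lag")
    order = np.argsort(lags)
    return AlignmentResult(
        lag=best[1] * dt,
        rmse_at_lag=best[0],
        overlap_samples=best[2],
        searched_lags=np.array(lags)[order],
        searched_rmse=np.array(rmses)[order],
    )


def match_stride_events(
    device_strides: pd.DataFrame,
    criterion_strides: pd.DataFrame,
    tolerance: float = 0.10,
) -> MatchedStridePairs:
    """Greedy nearest-time one-to-one matching of stride records.

    Both tables need ``time`` and ``foot`` columns; device timestamps must
    already be shifted onto the criterion clock.  Candidate pairs on the same
    foot within ``tolerance`` seconds are accepted in order of increasing
    time offset, each record used at most once.
    """
    dev = device_strides.reset_index(drop=True)
    crit = criterion_strides.reset_index(drop=True)
    candidates = []
    for i, (td, fd) in enumerate(zip(dev.get("time", []), dev.get("foot", []))):
        for j, (tc, fc) in enumerate(zip(crit.get("time", []), crit.get("foot", []))):
            if fd == fc and abs(td - tc) <= tolerance:
                candidates.append((abs(td - tc), i, j))
    candidates.sort()
    used_d: set[int] = set()
    used_c: set[int] = set()
    rows = []
    for _, i, j in candidates:
        if i in used_d or j in used_c:
            continue
        used_d.add(i)
        used_c.add(j)
        row = {f"device_{c}": dev.at[i, c] for c in dev.columns}
        row.update({f"criterion_{c}": crit.at[j, c] for c in crit.columns})
        row["time_offset"] = dev.at[i, "time"] - crit.at[j, "time"]
        rows.append(row)
    pairs = pd.DataFrame(rows)
    if len(rows):
        pairs = pairs.sort_values("criterion_time", kind="mergesort").reset_index(
            drop=True
        )
    return MatchedStridePairs(
        pairs=pairs,
        n_unmatched_device=len(dev) - len(used_d),
        n_unmatched_criterion=len(crit) - len(used_c),
    )
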