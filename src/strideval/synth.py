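"""Synthetic paired criterion/device sprint trials with known ground truth.

The generator emulates a 10 m fly sprint recorded simultaneously by a
marker-based motion-capture system with in-ground force plates (the
criterion) and a foot-mounted inertial device (the device under test).  The
centre of mass accelerates towards a plateau velocity along an exponential
rise, oscillates vertically and in forward speed at step frequency, and each
foot alternates stationary stance phases (producing a vertical GRF bump on
its own force plate) with cosine-eased swing phases.  A configurable error
model then degrades the ground truth into the 10 Hz velocity/acceleration
streams and event-based stride records a wearable device reports.

Two independent random streams are used: the criterion-side stream (gait
parameter jitter, marker noise) is derived from ``SprintParams.seed`` and the
device-side stream from ``DeviceErrorModel.seed``, so changing the error
model never changes the underlying gait.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import FOOT_STRIKE, TOE_OFF, GaitEvent

__all__ = [
    "SprintParams",
    "DeviceErrorModel",
    "CriterionTrial",
    "DeviceTrial",
    "CohortFixture",
    "TrialTruth",
    "simulate_criterion_trial",
    "degrade_to_device",
    "generate_cohort",
    "load_cohort_fixture",
]

MOCAP_RATE = 100.0  # Hz, infrared camera rate
GRF_RATE = 1000.0  # Hz, force-plate rate
DEVICE_RATE = 10.0  # Hz, rate at which the device exports velocity/acceleration

MARKERS = ("com", "left_device", "right_device", "left_toe", "right_toe")
TOE_AHEAD = 0.15  # m, toe marker sits ahead of the device marker
FOOT_LATERAL = 0.10  # m, lateral offset of each foot from the midline


@dataclass(frozen=True)
class SprintParams:
    """Kinematic parameters of one simulated sprint trial.

    Defaults are simulator choices representative of a maximal 10 m fly by a
    trained field-sport athlete (plateau speed just under 8 m/s, stride
    period ~0.47 s), not estimates of any particular cohort.
    """

    peak_velocity: float = 7.8  # m/s, plateau of the exponential rise
    tau: float = 1.2  # s, velocity rise time constant
    approach_length: float = 10.0  # m of run-up before the zone
    zone_length: float = 10.0  # m fly zone
    stride_frequency: float = 2.11  # Hz, full gait cycles per second per foot
    duty_factor: float = 0.25  # stance fraction of the stride period
    body_weight: float = 700.0  # N
    seed: int = 0
    # secondary shape parameters
    grf_peak_factor: float = 2.2  # peak vertical GRF in body weights
    grf_shape_exponent: float = 0.5  # sin^q bump; q<1 gives sprint-like steep loading
    vertical_amplitude: float = 0.02  # m, COM vertical oscillation amplitude
    speed_oscillation: float = 0.25  # m/s, intra-step forward speed oscillation
    swing_height: float = 0.12  # m, peak foot lift during swing
    marker_noise_sd: float = 0.001  # m, mocap marker noise per axis
    com_height: float = 0.95  # m, mean COM marker height
    first_stance_time: float = 0.10  # s, onset of the first left stance
    overrun: float = 6.0  # m simulated past the zone exit (> one stride, so
    # the trailing foot always plants beyond the exit line)

    def __post_init__(self) -> None:
        if self.peak_velocity <= 0:
            raise ValueError("peak_velocity must be positive")
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must lie in (0, 1)")
        if self.zone_length <= 0:
            raise ValueError("zone_length must be positive")
        if self.stride_frequency <= 0:
            raise ValueError("stride_frequency must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        # stance windows on one foot must not overlap
        if self.duty_factor / self.stride_frequency >= 1.0 / self.stride_frequency:
            raise ValueError("stance windows overlap on the same foot")


@dataclass(frozen=True)
class DeviceErrorModel:
    """Error structure injected when degrading ground truth to device output.

    Defaults emulate a heavily smoothed (Kalman-filtered) device stream: a
    systematic velocity underestimate with small white noise, a constant
    stream lag, millisecond-scale event-timing jitter, and a small stride
    length underestimate.
    """

    velocity_bias: float = -0.50  # m/s additive
    velocity_scale: float = 1.0  # multiplicative
    velocity_noise_sd: float = 0.05  # m/s
    velocity_drift: float = 0.0  # m/s per s, linear drift added to velocity
    accel_noise_sd: float = 0.30  # m/s^2
    lag: float = 0.30  # s, device clock lags the criterion clock
    event_jitter_sd: float = 0.005  # s
    stride_length_bias: float = -0.07  # m
    stride_length_noise_sd: float = 0.12  # m
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "velocity_noise_sd",
            "accel_noise_sd",
            "event_jitter_sd",
            "stride_length_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def identity(cls, seed: int = 0) -> "DeviceErrorModel":
        return cls(
            velocity_bias=0.0,
            velocity_scale=1.0,
            velocity_noise_sd=0.0,
            velocity_drift=0.0,
            accel_noise_sd=0.0,
            lag=0.0,
            event_jitter_sd=0.0,
            stride_length_bias=0.0,
            stride_length_noise_sd=0.0,
            seed=seed,
        )


class TrialTruth:
    """Closed-form ground truth of a simulated trial."""

    def __init__(self, params: SprintParams, stances: dict[str, pd.DataFrame]):
        self.params = params
        self.stances = stances  # foot -> DataFrame(onset, offset, x)
        p = params
        self._omega = 2.0 * np.pi * (2.0 * p.stride_frequency)  # step frequency

    # forward (x) kinematics: v = p*u(t) + A*u(t)*sin(w t), u = 1 - exp(-t/tau)
    def forward_velocity(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        u = 1.0 - np.exp(-t / p.tau)
        return p.peak_velocity * u + p.speed_oscillation * u * np.sin(self._omega * t)

    def forward_position(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        w = self._omega
        base = p.peak_velocity * (t + p.tau * (np.exp(-t / p.tau) - 1.0))
        int_sin = (1.0 - np.cos(w * t)) / w
        a = 1.0 / p.tau
        int_exp_sin = (w - np.exp(-a * t) * (w * np.cos(w * t) + a * np.sin(w * t))) / (
            w * w + a * a
        )
        return -p.approach_length + base + p.speed_oscillation * (int_sin - int_exp_sin)

    def forward_acceleration(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        w = self._omega
        u = 1.0 - np.exp(-t / p.tau)
        du = np.exp(-t / p.tau) / p.tau
        return p.peak_velocity * du + p.speed_oscillation * (
            du * np.sin(w * t) + u * w * np.cos(w * t)
        )

    # vertical (z) kinematics of the COM
    def vertical_position(self, t):
        p = self.params
        return p.com_height + p.vertical_amplitude * np.cos(self._omega * np.asarray(t))

    def vertical_velocity(self, t):
        p = self.params
        w = self._omega
        return -p.vertical_amplitude * w * np.sin(w * np.asarray(t))

    def vertical_acceleration(self, t):
        p = self.params
        w = self._omega
        return -p.vertical_amplitude * w * w * np.cos(w * np.asarray(t))

    def resultant_velocity(self, t):
        return np.hypot(self.forward_velocity(t), self.vertical_velocity(t))

    def resultant_acceleration(self, t):
        vx = self.forward_velocity(t)
        vz = self.vertical_velocity(t)
        ax = self.forward_acceleration(t)
        az = self.vertical_acceleration(t)
        r = np.hypot(vx, vz)
        # at standstill the speed derivative degenerates to |a|
        return np.where(r > 1e-12, (vx * ax + vz * az) / np.where(r > 1e-12, r, 1.0), np.hypot(ax, az))

    def zone_entry_exit_com(self) -> tuple[float, float]:
        """Times at which the COM itself crosses the zone boundaries."""
        from scipy.optimize import brentq

        p = self.params
        t_hi = self.duration()
        entry = brentq(lambda t: self.forward_position(t) - 0.0, 1e-6, t_hi)
        exit_ = brentq(lambda t: self.forward_position(t) - p.zone_length, entry, t_hi)
        return float(entry), float(exit_)

    def duration(self) -> float:
        from scipy.optimize import brentq

        p = self.params
        target = p.zone_length + p.overrun
        t = 1.0
        while self.forward_position(t) < target:
            t *= 1.5
            if t > 120:
                raise RuntimeError("sprint never reaches the zone exit")
        return float(brentq(lambda s: self.forward_position(s) - target, 1e-6, t)) + 0.3

    def true_stride_records(self, foot: str) -> pd.DataFrame:
        """Noise-free stride records (time of completing strike, duration,
        length, cadence) for one foot."""
        st = self.stances[foot]
        on = st["onset"].to_numpy()
        x = st["x"].to_numpy()
        rows = {
            "time": on[1:],
            "start_time": on[:-1],
            "duration": np.diff(on),
            "length": np.diff(x),
        }
        df = pd.DataFrame(rows)
        df["cadence"] = 60.0 / df["duration"]
        df["foot"] = foot
        return df


@dataclass
class CriterionTrial:
    """One trial as seen by the criterion system."""

    trial_id: str
    participant_id: str
    marker_positions: pd.DataFrame  # frame, marker, x, y, z @ MOCAP_RATE
    grf_traces: pd.DataFrame  # time, foot, fz @ GRF_RATE
    zone_start: float
    zone_end: float
    mocap_rate: float = MOCAP_RATE
    grf_rate: float = GRF_RATE
    true_events: list[GaitEvent] = field(default_factory=list)
    truth: TrialTruth | None = None

    def __post_init__(self) -> None:
        frames = self.marker_positions["frame"].to_numpy()
        per_marker = self.marker_positions.groupby("marker")["frame"]
        if not all(np.all(np.diff(g.to_numpy()) > 0) for _, g in per_marker):
            raise ValueError("frame indices must be strictly increasing per marker")
        del frames
        for _, g in self.grf_traces.groupby("foot"):
            if not np.all(np.diff(g["time"].to_numpy()) > 0):
                raise ValueError("GRF time must be strictly increasing")
        if np.min(self.grf_traces["fz"].to_numpy()) < -1.0:
            raise ValueError("vertical force below -1 N")

    def marker(self, name: str) -> pd.DataFrame:
        df = self.marker_positions[self.marker_positions["marker"] == name]
        return df.reset_index(drop=True)

    def grf(self, foot: str) -> pd.DataFrame:
        df = self.grf_traces[self.grf_traces["foot"] == foot]
        return df.reset_index(drop=True)


@dataclass
class DeviceTrial:
    """One trial as exported by the foot-mounted device."""

    trial_id: str
    participant_id: str
    velocity_series: pd.DataFrame  # time, value @ DEVICE_RATE (device clock)
    acceleration_series: pd.DataFrame  # time, value
    stride_records: pd.DataFrame  # time, foot, length, duration, cadence
    device_rate: float = DEVICE_RATE

    def __post_init__(self) -> None:
        for df in (self.velocity_series, self.acceleration_series):
            if not np.all(np.diff(df["time"].to_numpy()) > 0):
                raise ValueError("series times must be strictly increasing")
        if len(self.stride_records):
            if (self.stride_records["duration"] <= 0).any():
                raise ValueError("stride duration must be positive")
            if (self.stride_records["length"] <= 0).any():
                raise ValueError("stride length must be positive")


def _stance_schedule(params: SprintParams, truth_duration: float):
    p = params
    period = 1.0 / p.stride_frequency
    stance = p.duty_factor * period
    out = {}
    for foot, t0 in (("left", p.first_stance_time), ("right", p.first_stance_time + period / 2)):
        onsets = []
        t = t0
        while t + stance <= truth_duration - 0.05:
            onsets.append(t)
            t += period
        out[foot] = (np.array(onsets), stance)
    return out


def simulate_criterion_trial(
    params: SprintParams, trial_id: str = "T1", participant_id: str = "P01"
) -> CriterionTrial:
    """Simulate the criterion side of a 10 m fly sprint trial."""
    p = params
    rng = np.random.default_rng(np.random.SeedSequence([int(p.seed), 17]))

    # provisional truth (without stance table) to get the trial duration
    truth = TrialTruth(p, {})
    t_total = truth.duration()
    schedule = _stance_schedule(p, t_total)

    stances: dict[str, pd.DataFrame] = {}
    events: list[GaitEvent] = []
    for foot, (onsets, stance) in schedule.items():
        x_stance = truth.forward_position(onsets + stance / 2.0)
        stances[foot] = pd.DataFrame(
            {"onset": onsets, "offset": onsets + stance, "x": x_stance}
        )
        for on in onsets:
            events.append(GaitEvent(float(on), foot, FOOT_STRIKE))
            events.append(GaitEvent(float(on + stance), foot, TOE_OFF))
    events.sort(key=lambda e: e.time)
    truth = TrialTruth(p, stances)

    # marker trajectories at the mocap rate
    n_frames = int(np.floor(t_total * MOCAP_RATE)) + 1
    t_frames = np.arange(n_frames) / MOCAP_RATE
    foot_xz = {foot: _foot_trajectory(stances[foot], p, t_frames) for foot in stances}

    records = []
    com_x = truth.forward_position(t_frames)
    com_z = truth.vertical_position(t_frames)
    coords = {
        "com": (com_x, np.zeros(n_frames), com_z),
    }
    for foot, sign in (("left", 1.0), ("right", -1.0)):
        fx, fz = foot_xz[foot]
        y = np.full(n_frames, sign * FOOT_LATERAL)
        coords[f"{foot}_device"] = (fx, y, fz + 0.05)
        coords[f"{foot}_toe"] = (fx + TOE_AHEAD, y, fz + 0.02)
    for marker in MARKERS:
        x, y, z = coords[marker]
        noise = rng.normal(0.0, p.marker_noise_sd, size=(3, n_frames))
        records.append(
            pd.DataFrame(
                {
                    "frame": np.arange(n_frames),
                    "marker": marker,
                    "x": x + noise[0],
                    "y": y + noise[1],
                    "z": z + noise[2],
                }
            )
        )
    marker_positions = pd.concat(records, ignore_index=True)

    # per-foot vertical GRF at the force-plate rate
    n_grf = int(np.floor(t_total * GRF_RATE)) + 1
    t_grf = np.arange(n_grf) / GRF_RATE
    grf_frames = []
    peak = p.grf_peak_factor * p.body_weight
    for foot in ("left", "right"):
        fz = np.zeros(n_grf)
        for _, row in stances[foot].iterrows():
            inside = (t_grf > row["onset"]) & (t_grf < row["offset"])
            u = (t_grf[inside] - row["onset"]) / (row["offset"] - row["onset"])
            fz[inside] = peak * np.sin(np.pi * u) ** p.grf_shape_exponent
        grf_frames.append(pd.DataFrame({"time": t_grf, "foot": foot, "fz": fz}))
    grf_traces = pd.concat(grf_frames, ignore_index=True)

    return CriterionTrial(
        trial_id=trial_id,
        participant_id=participant_id,
        marker_positions=marker_positions,
        grf_traces=grf_traces,
        zone_start=0.0,
        zone_end=p.zone_length,
        true_events=events,
        truth=truth,
    )


def _foot_trajectory(stance_df: pd.DataFrame, p: SprintParams, t: np.ndarray):
    """Piecewise stance-hold / cosine-eased-swing foot trajectory."""
    on = stance_df["onset"].to_numpy()
    off = stance_df["offset"].to_numpy()
    xs = stance_df["x"].to_numpy()
    x = np.empty_like(t)
    z = np.zeros_like(t)
    x[:] = xs[0]
    for i in range(len(on)):
        hold = (t >= on[i]) & (t <= off[i])
        x[hold] = xs[i]
        z[hold] = 0.0
        if i + 1 < len(on):
            swing = (t > off[i]) & (t < on[i + 1])
            u = (t[swing] - off[i]) / (on[i + 1] - off[i])
            x[swing] = xs[i] + (xs[i + 1] - xs[i]) * 0.5 * (1.0 - np.cos(np.pi * u))
            z[swing] = p.swing_height * np.sin(np.pi * u)
    x[t > off[-1]] = xs[-1]
    return x, z


def degrade_to_device(trial: CriterionTrial, em: DeviceErrorModel) -> DeviceTrial:
    """Degrade a simulated trial's ground truth into device-side exports.

    The device clock lags the criterion clock by ``em.lag``: a sample with
    device timestamp ``t`` reflects the true state at ``t - lag``.
    """
    if trial.truth is None or not trial.true_events:
        raise ValueError("trial carries no ground truth to degrade")
    truth = trial.truth
    rng = np.random.default_rng(np.random.SeedSequence([int(em.seed), 29]))
    t_total = truth.duration()

    r = np.arange(int(np.floor(t_total * DEVICE_RATE)) + 1) / DEVICE_RATE
    v_true = truth.resultant_velocity(r)
    v = (
        em.velocity_scale * v_true
        + em.velocity_bias
        + em.velocity_drift * r
        + rng.normal(0.0, em.velocity_noise_sd, size=r.shape)
    )
    a = truth.resultant_acceleration(r) + rng.normal(
        0.0, em.accel_noise_sd, size=r.shape
    )
    velocity = pd.DataFrame({"time": r + em.lag, "value": v})
    acceleration = pd.DataFrame({"time": r + em.lag, "value": a})

    stride_frames = []
    for foot in ("left", "right"):
        st = truth.stances[foot]
        on = st["onset"].to_numpy()
        xs = st["x"].to_numpy()
        jit = on + rng.normal(0.0, em.event_jitter_sd, size=on.shape)
        jit.sort()  # keep strikes ordered even under extreme jitter
        dur = np.diff(jit)
        length = (
            np.diff(xs)
            + em.stride_length_bias
            + rng.normal(0.0, em.stride_length_noise_sd, size=len(xs) - 1)
        )
        stride_frames.append(
            pd.DataFrame(
                {
                    "time": jit[1:] + em.lag,
                    "foot": foot,
                    "length": length,
                    "duration": dur,
                    "cadence": 60.0 / dur,
                }
            )
        )
    strides = (
        pd.concat(stride_frames, ignore_index=True)
        .sort_values("time", kind="mergesort")
        .reset_index(drop=True)
    )

    return DeviceTrial(
        trial_id=trial.trial_id,
        participant_id=trial.participant_id,
        velocity_series=velocity,
        acceleration_series=acceleration,
        stride_records=strides,
    )


def generate_cohort(
    n_participants: int,
    trials_per_participant: int,
    params: SprintParams | None = None,
    em: DeviceErrorModel | None = None,
    seed: int = 0,
) -> list[tuple[CriterionTrial, DeviceTrial]]:
    """Generate a cohort of paired trials with participant-level jitter.

    Participant ability (plateau velocity, stride frequency, rise constant,
    duty factor, body weight) is drawn once per participant around the base
    parameters; each trial adds a small within-participant perturbation.
    Fully reproducible from ``seed``.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    base = params or SprintParams()
    base_em = em or DeviceErrorModel()
    rng = np.random.default_rng(seed)
    pairs: list[tuple[CriterionTrial, DeviceTrial]] = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        pv = max(4.0, rng.normal(base.peak_velocity, 0.6))
        tau = max(0.5, rng.normal(base.tau, 0.08))
        freq = max(1.2, rng.normal(base.stride_frequency, 0.06))
        duty = float(np.clip(rng.normal(base.duty_factor, 0.01), 0.12, 0.45))
        bw = max(350.0, rng.normal(base.body_weight, 90.0))
        for j in range(trials_per_participant):
            tid = f"{pid}-T{j + 1}"
            trial_params = dataclasses.replace(
                base,
                peak_velocity=pv * (1.0 + rng.normal(0.0, 0.01)),
                tau=tau,
                stride_frequency=freq * (1.0 + rng.normal(0.0, 0.005)),
                duty_factor=duty,
                body_weight=bw,
                seed=int(rng.integers(2**31)),
            )
            trial_em = dataclasses.replace(base_em, seed=int(rng.integers(2**31)))
            crit = simulate_criterion_trial(trial_params, tid, pid)
            pairs.append((crit, degrade_to_device(crit, trial_em)))
    return pairs


@dataclass(frozen=True)
class CohortFixture:
    """Per-participant trial and stride counts of the packaged study cohort."""

    rows: pd.DataFrame  # participant_id, sport, trials, left_strides, right_strides

    @property
    def totals(self) -> pd.Series:
        return self.rows[["trials", "left_strides", "right_strides"]].sum()

    @property
    def total_strides(self) -> int:
        t = self.totals
        return int(t["left_strides"] + t["right_strides"])

    def by_sport(self) -> pd.DataFrame:
        return self.rows.groupby("sport", sort=True).agg(
            participants=("participant_id", "size"),
            trials=("trials", "sum"),
            left_strides=("left_strides", "sum"),
            right_strides=("right_strides", "sum"),
        )


def load_cohort_fixture() -> CohortFixture:
    """Load the packaged per-participant trial/stride count table."""
    from importlib import resources

    with resources.files("strideval.data").joinpath("cohort_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    required = {"participant_id", "sport", "trials", "left_strides", "right_strides"}
    if not required.issubset(df.columns):
        raise ValueError("cohort fixture is corrupted: missing columns")
    totals = df[df["participant_id"] == "Total"]
    body = df[df["participant_id"] != "Total"].reset_index(drop=True)
    if len(totals) != 1:
        raise ValueError("cohort fixture is corrupted: totals row missing")
    cols = ["trials", "left_strides", "right_strides"]
    if not (body[cols].sum().to_numpy() == totals[cols].iloc[0].to_numpy()).all():
        raise ValueError("cohort fixture is corrupted: totals do not match")
    if (body[cols] < 0).to_numpy().any():
        raise ValueError("cohort fixture is corrupted: negative counts")
    return CohortFixture(rows=body)
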