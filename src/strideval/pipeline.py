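"""End-to-end validation runs: simulate -> detect -> derive -> filter ->
synchronize -> match -> report.

:func:`run_validation` executes the whole chain on a synthetic cohort and
writes per-trial intermediates (events, strides, alignment), the agreement
report for the six study variables (stride duration/length/cadence, peak
velocity, instantaneous velocity, instantaneous acceleration) and
Bland–Altman plots, plus a manifest with artifact checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import kinematics as kin
from . import sync
from .agreement import MethodComparison, MethodComparisonResults, build_report
from .synth import (
    CriterionTrial,
    DeviceErrorModel,
    DeviceTrial,
    SprintParams,
    generate_cohort,
    load_cohort_fixture,
)

log = logging.getLogger("strideval")

VARIABLES = (
    ("stride_duration", "s"),
    ("stride_length", "m"),
    ("stride_cadence", "strides/min"),
    ("peak_velocity", "m/s"),
    ("instantaneous_velocity", "m/s"),
    ("instantaneous_acceleration", "m/s^2"),
)
# the log-ratio analysis assumes strictly positive values
NO_LOG_BA = {"instantaneous_acceleration"}


@dataclass(frozen=True)
class FilterConfig:
    order: int = 4
    cutoff_velocity: float | None = None  # None -> residual analysis
    cutoff_acceleration: float | None = None
    cutoff_mode: str = "global"  # or "per_trial"
    fc_min: float = 4.0
    fc_max: float = 20.0
    n_candidates: int = 33
    fit_region: tuple[float, float] = (0.75, 1.0)
    filter_device: bool = False  # symmetric filtering for sensitivity checks


@dataclass(frozen=True)
class SyncConfig:
    max_lag: float = 2.0
    upsample_kind: str = "linear"
    matching_tolerance: float = 0.10
    min_overlap: int = 20


@dataclass(frozen=True)
class RunConfig:
    n_participants: int = 23
    trials_per_participant: int = 4
    sprint: SprintParams = field(default_factory=SprintParams)
    error_model: DeviceErrorModel = field(default_factory=DeviceErrorModel)
    filters: FilterConfig = field(default_factory=FilterConfig)
    sync: SyncConfig = field(default_factory=SyncConfig)
    loa_mode: str = "both"  # first_trial | pooled | both
    outdir: str = "results"
    seed: int = 1
    make_plots: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("sprint", SprintParams),
            ("error_model", DeviceErrorModel),
            ("filters", FilterConfig),
            ("sync", SyncConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if "fit_region" in sub:
                    sub["fit_region"] = tuple(sub["fit_region"])
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def loa_modes(self) -> tuple[str, ...]:
        if self.loa_mode == "both":
            modes: tuple[str, ...] = ("first_trial", "pooled")
        else:
            modes = (self.loa_mode,)
        if self.n_participants < 2 and "first_trial" in modes:
            modes = tuple(m for m in modes if m != "first_trial") or ("pooled",)
        return modes


@dataclass
class TrialPrep:
    """Criterion-side derivations shared between the cutoff-selection pass
    and the main processing pass."""

    crit: CriterionTrial
    dev: DeviceTrial
    com_velocity_raw: kin.KinematicSeries
    zone: ev.ZoneEvents
    gait_events: list[ev.GaitEvent]
    criterion_strides: list[ev.StrideMetrics]
    marker_trajs: dict[str, pd.DataFrame]
    velocity_residual: kin.ResidualCurve

    @property
    def entry_time(self) -> float:
        return self.zone.entry_frame / self.crit.mocap_rate

    @property
    def exit_time(self) -> float:
        return self.zone.exit_frame / self.crit.mocap_rate


@dataclass
class TrialResult:
    prep: TrialPrep
    lag: float
    alignment_rmse: float
    overlap: int
    cutoff_velocity: float
    cutoff_acceleration: float
    matched_strides: sync.MatchedStridePairs
    pairs: dict[str, pd.DataFrame]  # variable -> rows with device/criterion


def _marker_wide(crit: CriterionTrial, name: str) -> pd.DataFrame:
    df = crit.marker(name)
    out = {"frame": df["frame"].to_numpy()}
    for axis in ("x", "y", "z"):
        filled, _ = kin.fill_gaps(df[axis].to_numpy(dtype=float))
        out[axis] = filled
    return pd.DataFrame(out)


def prepare_trial(crit: CriterionTrial, dev: DeviceTrial, cfg: RunConfig) -> TrialPrep:
    """Gap-fill markers, derive the resultant COM velocity, detect gait
    events and criterion strides, and locate the capture zone."""
    markers = {m: _marker_wide(crit, m) for m in ("com", "left_device", "right_device")}
    toes = {m: _marker_wide(crit, m) for m in ("left_toe", "right_toe")}

    rate = crit.mocap_rate
    com = markers["com"]
    comps = []
    for axis in ("x", "y", "z"):
        series = kin.KinematicSeries.from_values(com[axis].to_numpy(), rate, label=axis)
        comps.append(kin.central_difference(series))
    v_res = kin.resultant_magnitude(*comps)

    zone = ev.zone_crossings(
        [toes["left_toe"]["x"].to_numpy(), toes["right_toe"]["x"].to_numpy()],
        crit.zone_start,
        crit.zone_end,
    )

    gait_events: list[ev.GaitEvent] = []
    for foot in ("left", "right"):
        g = crit.grf(foot)
        gait_events.extend(
            ev.detect_foot_contacts(g["time"].to_numpy(), g["fz"].to_numpy(), foot)
        )
    gait_events.sort(key=lambda e: e.time)

    foot_markers = {"left": markers["left_device"], "right": markers["right_device"]}
    strides = ev.stride_metrics_table(gait_events, foot_markers, rate)

    f = cfg.filters
    residual = kin.residual_analysis(
        v_res, f.fc_min, f.fc_max, f.n_candidates, f.order, f.fit_region
    )
    return TrialPrep(
        crit=crit,
        dev=dev,
        com_velocity_raw=v_res,
        zone=zone,
        gait_events=gait_events,
        criterion_strides=strides,
        marker_trajs=foot_markers,
        velocity_residual=residual,
    )


def _select_global_cutoff(curves: list[kin.ResidualCurve], cfg: FilterConfig) -> float:
    candidates = curves[0].candidate_cutoffs
    mean_res = np.mean([c.residual_rms for c in curves], axis=0)
    chosen, _ = kin.select_cutoff(candidates, mean_res, cfg.fc_max, cfg.fit_region)
    return float(np.clip(chosen, cfg.fc_min, cfg.fc_max))


def _acceleration_residual(prep: TrialPrep, cutoff_v: float, cfg: FilterConfig):
    vel_f = kin.butterworth_lowpass(prep.com_velocity_raw, cutoff_v, cfg.order)
    acc_raw = kin.central_difference(vel_f)
    return acc_raw, kin.residual_analysis(
        acc_raw, cfg.fc_min, cfg.fc_max, cfg.n_candidates, cfg.order, cfg.fit_region
    )


def process_trial(
    prep: TrialPrep, cutoff_v: float, cutoff_a: float, cfg: RunConfig
) -> TrialResult:
    """Filter the criterion streams, align the device stream, match strides
    and extract the per-trial paired observations for every variable."""
    crit, dev = prep.crit, prep.dev
    rate = crit.mocap_rate
    f, s = cfg.filters, cfg.sync

    vel_f = kin.butterworth_lowpass(prep.com_velocity_raw, cutoff_v, f.order)
    acc_f = kin.butterworth_lowpass(kin.central_difference(vel_f), cutoff_a, f.order)

    entry_t, exit_t = prep.entry_time, prep.exit_time
    vel_zone = vel_f.slice_time(entry_t, exit_t)

    dev_vel = kin.KinematicSeries(
        dev.velocity_series["time"].to_numpy(),
        dev.velocity_series["value"].to_numpy(),
        dev.device_rate,
        "device velocity",
    )
    if f.filter_device:
        dev_vel = kin.butterworth_lowpass(dev_vel, min(cutoff_v, dev.device_rate / 2 * 0.8), f.order)
    dev_vel_up = sync.upsample(dev_vel, rate, s.upsample_kind)
    # Shape-based lag search over the full shared trace.  Demeaning stops
    # the device's systematic velocity offset being traded against the
    # velocity trend; using the whole trial (not just the near-plateau zone)
    # keeps the steep approach-phase slope in the objective, without which
    # the periodic step ripple leaves one-step-period lag ambiguities.
    alignment = sync.align_min_rmse(
        vel_f,
        dev_vel_up,
        s.max_lag,
        min_overlap=max(s.min_overlap, int(0.6 * len(vel_f))),
        demean=True,
    )
    lag = alignment.lag

    # native-rate device instants mapped onto the criterion clock
    def native_pairs(series_df: pd.DataFrame, criterion: kin.KinematicSeries) -> pd.DataFrame:
        t_aligned = series_df["time"].to_numpy() - lag
        keep = (t_aligned >= entry_t) & (t_aligned <= exit_t)
        rows = []
        for t, val in zip(t_aligned[keep], series_df["value"].to_numpy()[keep]):
            idx = int(round(t * rate)) - int(round(criterion.times[0] * rate))
            if 0 <= idx < len(criterion):
                rows.append({"device": val, "criterion": criterion.values[idx]})
        return pd.DataFrame(rows)

    vel_pairs = native_pairs(dev.velocity_series, vel_f)
    acc_pairs = native_pairs(dev.acceleration_series, acc_f)

    # peak velocity inside the zone, per system
    t_dev_aligned = dev.velocity_series["time"].to_numpy() - lag
    in_zone = (t_dev_aligned >= entry_t) & (t_dev_aligned <= exit_t)
    peak_pairs = pd.DataFrame()
    if in_zone.any() and len(vel_zone):
        peak_pairs = pd.DataFrame(
            [
                {
                    "device": float(np.max(dev.velocity_series["value"].to_numpy()[in_zone])),
                    "criterion": float(np.max(vel_zone.values)),
                }
            ]
        )

    # criterion strides restricted to the capture zone; matched to the
    # device's event-based records on the completing foot strike
    eps = 1.5 / crit.grf_rate + 1.0 / rate
    zone_strides = [
        st
        for st in prep.criterion_strides
        if st.start_time >= entry_t - eps and st.end_time <= exit_t + eps
    ]
    crit_table = pd.DataFrame(
        [
            {
                "time": st.end_time,
                "foot": st.foot,
                "start_time": st.start_time,
                "duration": st.duration,
                "length": st.length,
                "cadence": st.cadence,
            }
            for st in zone_strides
        ]
    )
    dev_table = prep.dev.stride_records.copy()
    if len(dev_table):
        dev_table["time"] = dev_table["time"] - lag
    matched = sync.match_stride_events(dev_table, crit_table, s.matching_tolerance)

    pairs = {
        "instantaneous_velocity": vel_pairs,
        "instantaneous_acceleration": acc_pairs,
        "peak_velocity": peak_pairs,
    }
    for var in ("stride_duration", "stride_length", "stride_cadence"):
        col = var.removeprefix("stride_")
        if len(matched.pairs):
            pairs[var] = pd.DataFrame(
                {
                    "device": matched.pairs[f"device_{col}"],
                    "criterion": matched.pairs[f"criterion_{col}"],
                }
            )
        else:
            pairs[var] = pd.DataFrame()
    for df in pairs.values():
        df["participant_id"] = crit.participant_id
        df["trial_id"] = crit.trial_id
    return TrialResult(
        prep=prep,
        lag=lag,
        alignment_rmse=alignment.rmse_at_lag,
        overlap=alignment.overlap_samples,
        cutoff_velocity=cutoff_v,
        cutoff_acceleration=cutoff_a,
        matched_strides=matched,
        pairs=pairs,
    )


def process_cohort(
    cohort: list[tuple[CriterionTrial, DeviceTrial]], cfg: RunConfig
) -> tuple[list[TrialResult], dict[str, float]]:
    """Run both passes (cutoff selection, then processing) over a cohort."""
    preps = []
    for crit, dev in cohort:
        log.info("preparing trial %s", crit.trial_id)
        preps.append(prepare_trial(crit, dev, cfg))

    f = cfg.filters
    if f.cutoff_velocity is not None:
        cutoff_v_global = f.cutoff_velocity
    elif f.cutoff_mode == "global":
        cutoff_v_global = _select_global_cutoff([p.velocity_residual for p in preps], f)
    else:
        cutoff_v_global = None

    results = []
    acc_curves = []
    trial_cutoffs = []
    for p in preps:
        cv = cutoff_v_global if cutoff_v_global is not None else p.velocity_residual.chosen_cutoff
        trial_cutoffs.append(cv)
        if f.cutoff_acceleration is None:
            _, curve = _acceleration_residual(p, cv, f)
            acc_curves.append(curve)
    if f.cutoff_acceleration is not None:
        cutoff_a_global = f.cutoff_acceleration
    elif f.cutoff_mode == "global":
        cutoff_a_global = _select_global_cutoff(acc_curves, f)
    else:
        cutoff_a_global = None

    for i, p in enumerate(preps):
        cv = trial_cutoffs[i]
        ca = cutoff_a_global if cutoff_a_global is not None else acc_curves[i].chosen_cutoff
        log.info("processing trial %s (cutoffs %.2f/%.2f Hz)", p.crit.trial_id, cv, ca)
        results.append(process_trial(p, cv, ca, cfg))

    cutoffs = {
        "velocity": float(np.mean([r.cutoff_velocity for r in results])),
        "acceleration": float(np.mean([r.cutoff_acceleration for r in results])),
    }
    return results, cutoffs


def fit_agreement(
    results: list[TrialResult], modes: tuple[str, ...]
) -> dict[str, MethodComparisonResults]:
    """Pool per-trial pairs and fit the agreement model per variable."""
    fitted: dict[str, MethodComparisonResults] = {}
    for var, units in VARIABLES:
        frames = [r.pairs[var] for r in results if len(r.pairs[var])]
        if not frames:
            log.warning("no pairs for %s; skipped", var)
            continue
        data = pd.concat(frames, ignore_index=True)
        if len(data) < 2:
            log.warning("fewer than two pairs for %s; skipped", var)
            continue
        model = MethodComparison.from_dataframe(
            data, variable=var, units=units, log_ba=var not in NO_LOG_BA
        )
        fitted[var] = model.fit(loa_modes=modes)
    return fitted


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_validation(config: RunConfig, write_raw: bool = False) -> dict:
    """Execute an end-to-end validation run and write all artifacts.

    Returns the manifest (also written to ``<outdir>/manifest.json``) listing
    every artifact with a SHA-256 checksum, the selected filter cutoffs and
    the number of trials processed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info(
        "simulating cohort: %d participants x %d trials",
        config.n_participants,
        config.trials_per_participant,
    )
    cohort = generate_cohort(
        config.n_participants,
        config.trials_per_participant,
        config.sprint,
        config.error_model,
        config.seed,
    )
    if write_raw:
        from . import io as sio

        raw = outdir / "raw"
        for crit, dev in cohort:
            sio.write_criterion_trial(crit, raw)
            sio.write_device_trial(dev, raw)

    results, cutoffs = process_cohort(cohort, config)
    fitted = fit_agreement(results, config.loa_modes())
    report, _ = build_report(fitted)

    artifacts: list[Path] = []

    events_rows = [
        {"trial_id": r.prep.crit.trial_id, "time": e.time, "foot": e.foot, "kind": e.kind}
        for r in results
        for e in r.prep.gait_events
    ]
    path = outdir / "events.csv"
    pd.DataFrame(events_rows).to_csv(path, index=False, float_format="%.6f")
    artifacts.append(path)

    stride_rows = [
        {
            "trial_id": r.prep.crit.trial_id,
            "foot": st.foot,
            "start_time": st.start_time,
            "duration": st.duration,
            "length": st.length,
            "cadence": st.cadence,
        }
        for r in results
        for st in r.prep.criterion_strides
    ]
    path = outdir / "criterion_strides.csv"
    pd.DataFrame(stride_rows).to_csv(path, index=False, float_format="%.6f")
    artifacts.append(path)

    align_rows = [
        {
            "trial_id": r.prep.crit.trial_id,
            "lag_s": r.lag,
            "rmse": r.alignment_rmse,
            "overlap": r.overlap,
            "matched_strides": len(r.matched_strides.pairs),
            "unmatched_device": r.matched_strides.n_unmatched_device,
            "unmatched_criterion": r.matched_strides.n_unmatched_criterion,
        }
        for r in results
    ]
    path = outdir / "alignment.csv"
    pd.DataFrame(align_rows).to_csv(path, index=False, float_format="%.6f")
    artifacts.append(path)

    path = outdir / "report.csv"
    report.to_csv(path, index=False, float_format="%.6f")
    artifacts.append(path)

    report_json = {
        "cutoffs_hz": cutoffs,
        "n_trials": len(results),
        "variables": {var: res.to_rows() for var, res in fitted.items()},
        "normality": {
            var: {
                name: None
                if r is None
                else {"statistic": r.statistic, "p_value": r.p_value, "normal": r.normal}
                for name, r in res.normality.items()
            }
            for var, res in fitted.items()
        },
    }
    path = outdir / "report.json"
    path.write_text(json.dumps(report_json, indent=2, sort_keys=True, allow_nan=True))
    artifacts.append(path)

    plot_paths: list[Path] = []
    if config.make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plotdir = outdir / "plots"
        plotdir.mkdir(exist_ok=True)
        for var, res in fitted.items():
            ax = res.plot_bland_altman()
            p = plotdir / f"bland_altman_{var}.png"
            ax.figure.savefig(p, dpi=120)
            plt.close(ax.figure)
            plot_paths.append(p)

    manifest = {
        "seed": config.seed,
        "n_trials": len(results),
        "cutoffs_hz": cutoffs,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
        "plots": [str(p.relative_to(outdir)) for p in plot_paths],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def summarize_fixture() -> dict:
    """Totals and per-sport counts of the packaged cohort table."""
    fixture = load_cohort_fixture()
    totals = fixture.totals
    return {
        "participants": int(len(fixture.rows)),
        "trials": int(totals["trials"]),
        "left_strides": int(totals["left_strides"]),
        "right_strides": int(totals["right_strides"]),
        "total_strides": fixture.total_strides,
        "by_sport": {
            sport: {k: int(v) for k, v in row.items()}
            for sport, row in fixture.by_sport().iterrows()
        },
    }
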