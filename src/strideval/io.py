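"""CSV writers/readers for the pipeline's data interchange formats.

All formats are plain headered CSV: marker trajectories (frame, marker,
x, y, z), vertical GRF traces (time, foot, fz), device velocity and
acceleration series (time, value), stride records (time, foot, length,
duration, cadence), detected events and stride metrics.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synth import CriterionTrial, DeviceTrial

FLOAT_FORMAT = "%.12g"


def write_criterion_trial(trial: CriterionTrial, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    markers = directory / f"{trial.trial_id}_markers.csv"
    grf = directory / f"{trial.trial_id}_grf.csv"
    trial.marker_positions.to_csv(markers, index=False, float_format=FLOAT_FORMAT)
    trial.grf_traces.to_csv(grf, index=False, float_format=FLOAT_FORMAT)
    return [markers, grf]


def write_device_trial(trial: DeviceTrial, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("velocity", trial.velocity_series),
        ("acceleration", trial.acceleration_series),
        ("strides", trial.stride_records),
    ):
        path = directory / f"{trial.trial_id}_device_{name}.csv"
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        paths.append(path)
    return paths


def read_criterion_trial(
    directory: str | Path, trial_id: str, participant_id: str = "", zone_length: float = 10.0
) -> CriterionTrial:
    directory = Path(directory)
    markers = pd.read_csv(directory / f"{trial_id}_markers.csv")
    grf = pd.read_csv(directory / f"{trial_id}_grf.csv")
    return CriterionTrial(
        trial_id=trial_id,
        participant_id=participant_id,
        marker_positions=markers,
        grf_traces=grf,
        zone_start=0.0,
        zone_end=zone_length,
    )


def read_device_trial(
    directory: str | Path, trial_id: str, participant_id: str = ""
) -> DeviceTrial:
    directory = Path(directory)
    return DeviceTrial(
        trial_id=trial_id,
        participant_id=participant_id,
        velocity_series=pd.read_csv(directory / f"{trial_id}_device_velocity.csv"),
        acceleration_series=pd.read_csv(
            directory / f"{trial_id}_device_acceleration.csv"
        ),
        stride_records=pd.read_csv(directory / f"{trial_id}_device_strides.csv"),
    )
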