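"""Delimited-text readers and writers for the pipeline's data formats.

All on-disk formats are plain CSV: EMG (time_s, ch1..chN), label schedules
(start_s, end_s, label), pose landmarks (time_s plus x,y per landmark in the
fixed order left_shoulder, right_shoulder, left_elbow, right_elbow), feature
frames, intention streams and trial records.  Landmark loading supports
pixel-space input via a cm-per-pixel scale, a y-flip and a tabletop offset,
since video pose estimators report pixels from the top-left screen corner
while the analysis works in y-up centimetres above the tabletop.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import TrialRecord
from .features import EmgStream, FeatureFrame, feature_matrix
from .kinematics import LANDMARK_ORDER, LandmarkSeries
from .synthetic import LabelSchedule

_LANDMARK_COLS = [f"{short}_{ax}" for short in ("lshoulder", "rshoulder", "lelbow", "relbow") for ax in ("x", "y")]


def write_emg_csv(stream: EmgStream, path) -> None:
    cols = {"time_s": stream.times}
    for c in range(stream.n_channels):
        cols[f"ch{c + 1}"] = stream.samples[c]
    if stream.labels is not None:
        cols["label"] = stream.labels
    pd.DataFrame(cols).to_csv(path, index=False)


def read_emg_csv(path, sample_rate: float | None = None, rate_tol: float = 0.01) -> EmgStream:
    """Read an EMG CSV; the sample rate is inferred from the median time step
    and cross-checked against ``sample_rate`` when given."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("EMG CSV must have a time_s column")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError("EMG CSV must contain at least 2 samples")
    inferred = 1.0 / float(np.median(np.diff(times)))
    if sample_rate is not None and abs(inferred - sample_rate) / sample_rate > rate_tol:
        raise ValueError(f"inferred rate {inferred:.1f} Hz conflicts with declared {sample_rate} Hz")
    rate = sample_rate if sample_rate is not None else inferred
    chans = [c for c in df.columns if c.startswith("ch")]
    if not chans:
        raise ValueError("EMG CSV must have ch1..chN columns")
    samples = df[chans].to_numpy(dtype=float).T
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return EmgStream(sample_rate=rate, samples=samples, labels=labels)


def write_schedule_csv(schedule: LabelSchedule, path) -> None:
    pd.DataFrame(schedule.segments, columns=["start_s", "end_s", "label"]).to_csv(path, index=False)


def read_schedule_csv(path) -> LabelSchedule:
    df = pd.read_csv(path)
    segs = tuple(
        (float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples(index=False)
    )
    return LabelSchedule(segs)


def write_landmarks_csv(lms: LandmarkSeries, path) -> None:
    flat = lms.positions.reshape(lms.n_frames, 8)
    df = pd.DataFrame(flat, columns=_LANDMARK_COLS)
    df.insert(0, "time_s", lms.timestamps)
    df.to_csv(path, index=False)


def read_landmarks_csv(
    path,
    side: str = "right",
    scale_cm_per_px: float | None = None,
    flip_y: bool = False,
    table_y: float = 0.0,
) -> LandmarkSeries:
    """Read a landmark CSV, optionally converting pixel coordinates.

    Pixel-mode input (screen coordinates, y down from the top-left corner)
    is converted with ``y_cm = (table_y - y_px) * scale`` when ``flip_y`` is
    set, so the tabletop row ``table_y`` maps to 0 cm and height grows
    upward.
    """
    df = pd.read_csv(path)
    missing = [c for c in ["time_s", *_LANDMARK_COLS] if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns: {missing}")
    pos = df[_LANDMARK_COLS].to_numpy(dtype=float).reshape(-1, 4, 2)
    if flip_y:
        pos[:, :, 1] = table_y - pos[:, :, 1]
    elif table_y:
        pos[:, :, 1] = pos[:, :, 1] - table_y
    if scale_cm_per_px is not None:
        pos = pos * scale_cm_per_px
    return LandmarkSeries(timestamps=df["time_s"].to_numpy(dtype=float), positions=pos, side=side)


def write_features_csv(frames: list[FeatureFrame], path) -> None:
    times, X = feature_matrix(frames)
    df = pd.DataFrame(X, columns=[f"f{j + 1:02d}" for j in range(X.shape[1])])
    df.insert(0, "frame_time_s", times)
    df.to_csv(path, index=False)


def read_features_csv(path) -> list[FeatureFrame]:
    df = pd.read_csv(path)
    fcols = [c for c in df.columns if c.startswith("f") and c != "frame_time_s"]
    edges = np.array([])
    return [
        FeatureFrame(frame_time=float(t), values=row, band_edges=edges)
        for t, row in zip(df["frame_time_s"].to_numpy(), df[fcols].to_numpy(dtype=float))
    ]


def write_intention_csv(times, raw, stabilized, commands, path) -> None:
    pd.DataFrame(
        {"frame_time_s": times, "raw": raw, "stabilized": stabilized, "hand_command": commands}
    ).to_csv(path, index=False)


def write_trial_records_csv(records: list[TrialRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "participant": r.participant,
                "condition": r.condition,
                "duration_s": r.duration_s,
                "max_angle_deg": r.max_angle_deg,
                "distortion": r.distortion,
                "base_cm": r.base_cm,
                "end_cm": r.end_cm,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_trial_records_csv(path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    return [
        TrialRecord(
            participant=str(r.participant),
            condition=str(r.condition),
            duration_s=float(r.duration_s),
            max_angle_deg=float(r.max_angle_deg),
            distortion=float(r.distortion),
            base_cm=float(r.base_cm),
            end_cm=float(r.end_cm),
        )
        for r in df.itertuples(index=False)
    ]


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")
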