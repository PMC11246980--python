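"""Trunk-angle and elbow-trajectory analysis of pose-landmark streams.

Compensatory movement is quantified from four landmarks (both shoulders and
both elbows).  The trunk angle at each frame is the signed angle of the
inter-shoulder line against the horizontal; the distortion level of a trial
is the sum of absolute trunk angles over its frames, an energy-like burden
measure.  Elbow trajectories are summarised by resampling every trial to the
longest one, averaging pointwise, and attaching per-axis standard deviations
at the six boundaries of five equal parts, plus elbow heights at the grasp
(base) and release (end) frames.

Coordinates are y-up centimetres with the tabletop at y = 0; loaders for
pixel data must apply a scale and a y-flip before these functions are used.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LANDMARK_ORDER = ("left_shoulder", "right_shoulder", "left_elbow", "right_elbow")
CHECKPOINT_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class LandmarkSeries:
    """Timestamped 2-D positions of the four tracked landmarks.

    ``positions`` has shape (n_frames, 4, 2) in the fixed order
    left_shoulder, right_shoulder, left_elbow, right_elbow; ``side`` names
    the task arm.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (4, 2):
            raise ValueError("positions must have shape (n_frames, 4, 2)")
        if self.timestamps.shape[0] != self.positions.shape[0]:
            raise ValueError("timestamps and positions must have equal frame counts")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("all coordinates must be finite")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def landmark(self, name: str) -> np.ndarray:
        return self.positions[:, LANDMARK_ORDER.index(name), :]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class TrajectorySummary:
    """Condition-level elbow-path and height summary across trials."""

    mean_path: np.ndarray
    checkpoints: np.ndarray        # (6, 2) points at five-equal-part boundaries
    checkpoint_sd: np.ndarray      # (6, 2) per-axis SD across trials
    n_trials: int
    base_height_mean: float | None = None
    base_height_sd: float | None = None
    end_height_mean: float | None = None
    end_height_sd: float | None = None


def trunk_angle_series(lms: LandmarkSeries) -> np.ndarray:
    """Signed trunk angle (degrees) per frame from the inter-shoulder line.

    The angle of the left-to-right shoulder line against the horizontal,
    mapped to (-90, 90]; positive when the right shoulder is higher.
    Invariant to translating both shoulders, sign-flipping under mirroring.
    """
    left = lms.landmark("left_shoulder")
    right = lms.landmark("right_shoulder")
    d = right - left
    if np.any(np.hypot(d[:, 0], d[:, 1]) < 1e-12):
        raise ValueError("coincident shoulder landmarks; trunk angle undefined")
    theta = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    # line angle, not vector angle: fold into (-90, 90]
    theta = (theta + 90.0) % 180.0 - 90.0
    return theta


def distortion_level(theta: np.ndarray, dt: float = 1.0) -> float:
    """Distortion level D(Theta) = dt * sum_k |theta_k|.

    The default dt = 1 gives the plain frame sum over the trial; passing the
    frame interval converts to angle-time units.
    """
    theta = np.asarray(theta, dtype=float)
    return float(dt * np.sum(np.abs(theta)))


def resample_trajectory(path: np.ndarray, target_len: int) -> np.ndarray:
    """Linearly resample a 2-D path to ``target_len`` points.

    Interpolation is uniform in normalised sample index; the endpoints are
    preserved exactly, and resampling at the current length is the identity.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
        raise ValueError("path must be an (n >= 2, 2) array")
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    u_src = np.linspace(0.0, 1.0, path.shape[0])
    u_dst = np.linspace(0.0, 1.0, target_len)
    out = np.column_stack([np.interp(u_dst, u_src, path[:, j]) for j in range(2)])
    out[0], out[-1] = path[0], path[-1]
    return out


def average_trajectory(paths: list[np.ndarray]) -> TrajectorySummary:
    """Mean elbow path with SD checkpoints at five equal parts.

    The longest trial sets the common length; every path is linearly
    resampled to it and averaged per index.  Checkpoints sit at fractions
    0, 0.2, ..., 1.0 of the resampled path and carry the per-axis standard
    deviation (n-1 denominator) across trials.
    """
    if not paths:
        raise ValueError("need at least one trial path")
    target = max(np.asarray(p).shape[0] for p in paths)
    stacked = np.stack([resample_trajectory(np.asarray(p, dtype=float), target) for p in paths])
    mean_path = stacked.mean(axis=0)
    idx = np.round(np.asarray(CHECKPOINT_FRACTIONS) * (target - 1)).astype(int)
    checkpoints = mean_path[idx]
    if stacked.shape[0] > 1:
        sd = stacked[:, idx, :].std(axis=0, ddof=1)
    else:
        sd = np.zeros((len(idx), 2))
    return TrajectorySummary(
        mean_path=mean_path,
        checkpoints=checkpoints,
        checkpoint_sd=sd,
        n_trials=len(paths),
    )


def elbow_path(lms: LandmarkSeries, side: str | None = None) -> np.ndarray:
    """Task-side elbow positions as an (n_frames, 2) path."""
    side = side or lms.side
    return lms.landmark(f"{side}_elbow")


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def elbow_height_summary(trials: list, side: str | None = None) -> dict:
    """Base/end elbow heights (mean, SD) across annotated trials.

    Each trial must expose ``landmarks``, ``grasp_frame`` and
    ``release_frame``; the base height is the task-side elbow y at the grasp
    frame, the end height at the release frame, both in cm above the
    tabletop.
    """
    if not trials:
        raise ValueError("need at least one trial")
    base, end = [], []
    for tr in trials:
        for attr in ("landmarks", "grasp_frame", "release_frame"):
            if not hasattr(tr, attr):
                raise ValueError(f"trial lacks required annotation '{attr}'")
        path = elbow_path(tr.landmarks, side)
        base.append(path[tr.grasp_frame, 1])
        end.append(path[tr.release_frame, 1])
    base_m, base_sd = _mean_sd(np.array(base))
    end_m, end_sd = _mean_sd(np.array(end))
    return {"base": (base_m, base_sd), "end": (end_m, end_sd), "n": len(trials)}


def summarize_trials(trials: list, side: str | None = None) -> TrajectorySummary:
    """Full condition summary: mean path, checkpoint SDs, base/end heights."""
    summary = average_trajectory([elbow_path(tr.landmarks, side) for tr in trials])
    heights = elbow_height_summary(trials, side)
    summary.base_height_mean, summary.base_height_sd = heights["base"]
    summary.end_height_mean, summary.end_height_sd = heights["end"]
    return summary
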