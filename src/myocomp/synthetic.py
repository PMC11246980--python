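"""Seeded generators for EMG recordings and pick-and-place task kinematics.

The generators emulate the two data modalities of a socket-comparison
experiment: (a) 3-channel surface EMG in which each motion class expresses a
distinct per-channel gain and spectral envelope over 20-400 Hz, on top of
broadband noise and mains interference; (b) pose-landmark streams (both
shoulders, both elbows, sampled every 0.11 s) for pick-and-place trials in
which the elbow travels from a high grasp region to a low release region
while the trunk tilts by a smooth half-sine bump.  The "conventional"
condition presets place the elbow higher and tilt the trunk more than the
"separate" (wrist-sparing) presets, which is the contrast the downstream
analysis is designed to detect.

Everything is deterministic given the seed, so the full pipeline is testable
without recorded human data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import signal

from .features import EmgStream
from .kinematics import LandmarkSeries

MOTION_LABELS = ("rest", "grip", "open", "wrist_flex", "wrist_extend")

# Per-class (per-channel RMS gain, spectral band) over the three electrode
# sites: CH1 extensor carpi radialis brevis, CH2 flexor carpi ulnaris,
# CH3 flexor carpi radialis.  Chosen for class separability in band-power
# space; not a physiological model.
DEFAULT_CLASS_PROFILES: dict[str, dict] = {
    "rest": {"gains": (0.05, 0.05, 0.05), "band": (20.0, 380.0)},
    "grip": {"gains": (0.9, 1.2, 0.9), "band": (50.0, 150.0)},
    "open": {"gains": (1.2, 0.4, 0.9), "band": (100.0, 300.0)},
    "wrist_flex": {"gains": (0.3, 1.0, 1.4), "band": (30.0, 120.0)},
    "wrist_extend": {"gains": (1.4, 0.8, 0.3), "band": (150.0, 350.0)},
}


@dataclass(frozen=True)
class EmgSimParams:
    """Parameters of the EMG generator.

    ``class_profiles`` maps a motion label to per-channel RMS gains and a
    spectral band (Hz); the activation component of a labelled segment is
    band-limited Gaussian noise at that gain, ramped on/off over
    ``rise_s`` seconds.  ``crosstalk`` linearly mixes a fraction of the mean
    of the other channels' activations into each channel.
    """

    sample_rate: float = 2000.0
    n_channels: int = 3
    class_profiles: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROFILES))
    noise_sigma: float = 0.05
    line_hz: float = 50.0
    line_amplitude: float = 0.1
    crosstalk: float = 0.05
    rise_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or not np.isfinite(self.sample_rate):
            raise ValueError("sample_rate must be positive and finite")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0 <= self.crosstalk < 1:
            raise ValueError("crosstalk must lie in [0, 1)")
        if self.noise_sigma < 0 or self.line_amplitude < 0:
            raise ValueError("noise_sigma and line_amplitude must be >= 0")
        for label, prof in self.class_profiles.items():
            gains = np.asarray(prof["gains"], dtype=float)
            lo, hi = prof["band"]
            if gains.shape[0] != self.n_channels:
                raise ValueError(f"profile '{label}' must give {self.n_channels} gains")
            if np.any(gains < 0) or not np.all(np.isfinite(gains)):
                raise ValueError(f"profile '{label}' gains must be finite and >= 0")
            if not 0 < lo < hi:
                raise ValueError(f"profile '{label}' band must satisfy 0 < lo < hi")
            if self.sample_rate <= 2 * hi:
                raise ValueError("sample_rate must exceed twice the highest profile frequency")


@dataclass(frozen=True)
class LabelSchedule:
    """Ordered, non-overlapping (start_s, end_s, label) segments."""

    segments: tuple = ()

    def __post_init__(self) -> None:
        segs = tuple((float(s), float(e), str(lab)) for s, e, lab in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = -np.inf
        for s, e, lab in segs:
            if not (np.isfinite(s) and np.isfinite(e) and s < e):
                raise ValueError("each segment needs finite start < end")
            if s < prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = e

    @property
    def end(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    @property
    def labels(self) -> tuple:
        return tuple(dict.fromkeys(lab for _, _, lab in self.segments))

    def label_at(self, t: float, default: str = "rest") -> str:
        for s, e, lab in self.segments:
            if s <= t < e:
                return lab
        return default


def _smooth_gate(n: int, start: int, end: int, rise: int) -> np.ndarray:
    """On/off envelope: 0 outside [start, end), half-cosine ramps of ``rise``."""
    env = np.zeros(n)
    end = min(end, n)
    if start >= end:
        return env
    env[start:end] = 1.0
    r = min(rise, end - start)
    if r > 1:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / (r - 1)))
        env[start : start + r] = ramp
        env[end - r : end] *= ramp[::-1]
    return env


def _bandlimited_noise(rng: np.random.Generator, n: int, band: tuple, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_emg(params: EmgSimParams, schedule: LabelSchedule, duration: float) -> EmgStream:
    """Generate a labelled multi-channel EMG stream.

    During a segment labelled ``y`` each channel carries broadband noise,
    mains interference at ``line_hz``, and band-shaped activation scaled by
    class ``y``'s per-channel gain; samples outside all segments are
    labelled rest.  Deterministic given ``params.seed``.
    """
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError("duration must be positive and finite")
    if schedule.segments and schedule.end > duration + 1e-12:
        raise ValueError("schedule extends past the requested duration")
    fs = params.sample_rate
    n = int(np.ceil(duration * fs))
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / fs

    out = rng.normal(0.0, params.noise_sigma, size=(params.n_channels, n))
    if params.line_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += params.line_amplitude * np.sin(2 * np.pi * params.line_hz * t + phase)

    labels = np.full(n, "rest", dtype=object)
    rise = max(int(round(params.rise_s * fs)), 1)
    activation = np.zeros_like(out)
    for s, e, lab in schedule.segments:
        if lab not in params.class_profiles:
            raise ValueError(f"no class profile for label '{lab}'")
        prof = params.class_profiles[lab]
        gains = np.asarray(prof["gains"], dtype=float)
        i0, i1 = int(round(s * fs)), min(int(round(e * fs)), n)
        labels[i0:i1] = lab
        gate = _smooth_gate(n, i0, i1, rise)
        for c in range(params.n_channels):
            if gains[c] == 0:
                continue
            seg_len = i1 - i0
            carrier = _bandlimited_noise(rng, seg_len, prof["band"], fs)
            activation[c, i0:i1] += gains[c] * carrier * gate[i0:i1]
    if params.crosstalk > 0 and params.n_channels > 1:
        mixed = np.empty_like(activation)
        for c in range(params.n_channels):
            others = np.delete(activation, c, axis=0).mean(axis=0)
            mixed[c] = (1 - params.crosstalk) * activation[c] + params.crosstalk * others
        activation = mixed
    out += activation
    labels = labels.astype(str)
    return EmgStream(sample_rate=fs, samples=out, labels=labels)


@dataclass(frozen=True)
class TaskSimParams:
    """Parameters of the pick-and-place kinematics generator (cm, s, deg)."""

    condition: str = "conventional"
    n_trials: int = 10
    frame_interval: float = 0.11
    trial_duration_mean: float = 4.2
    trial_duration_sd: float = 0.6
    base_height_mean: float = 45.1
    base_height_sd: float = 1.38
    end_height_mean: float = 27.6
    end_height_sd: float = 1.37
    tilt_amplitude_mean: float = 7.9
    tilt_amplitude_sd: float = 2.6
    side: str = "right"
    landmark_noise_sd: float = 0.3
    timestamp_jitter: bool = False
    seed: int = 0
    shoulder_height: float = 62.0
    shoulder_halfspan: float = 18.0
    elbow_x_start: float = 8.0
    elbow_x_end: float = 58.0

    def __post_init__(self) -> None:
        if self.condition not in ("conventional", "separate"):
            raise ValueError("condition must be 'conventional' or 'separate'")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for name in ("trial_duration_mean", "base_height_mean", "end_height_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "trial_duration_sd",
            "base_height_sd",
            "end_height_sd",
            "tilt_amplitude_sd",
            "landmark_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedTrial:
    """One generated trial: landmark series plus ground-truth annotations."""

    landmarks: LandmarkSeries
    grasp_frame: int
    release_frame: int
    true_tilt_profile: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        if not 0 <= self.grasp_frame < self.release_frame < len(self.landmarks.timestamps):
            raise ValueError("need 0 <= grasp_frame < release_frame < n_frames")

    @property
    def duration(self) -> float:
        return float(self.landmarks.timestamps[-1] - self.landmarks.timestamps[0])


def simulate_task_landmarks(params: TaskSimParams) -> list[SimulatedTrial]:
    """Generate pick-and-place trials as landmark streams.

    Per trial: duration, grasp/release elbow heights, and a half-sine trunk
    tilt peak are drawn from the configured normals (heights/durations
    truncated to stay positive, tilt at zero); shoulders rotate rigidly about
    a fixed mid-point by the tilt angle, and the task-side elbow eases from
    the base height to the end height between the grasp and release frames.
    Isotropic Gaussian noise of ``landmark_noise_sd`` cm is added to every
    coordinate.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    trials: list[SimulatedTrial] = []
    fi = params.frame_interval
    for _ in range(params.n_trials):
        duration = max(rng.normal(params.trial_duration_mean, params.trial_duration_sd), 10 * fi)
        n = int(round(duration / fi))  # frames are indexed 0..n
        timestamps = np.arange(n + 1) * fi
        if params.timestamp_jitter:
            timestamps = timestamps + fi * rng.uniform(-0.005, 0.005, size=n + 1)
            timestamps[0] = 0.0
        base_h = max(rng.normal(params.base_height_mean, params.base_height_sd), 1.0)
        end_h = max(rng.normal(params.end_height_mean, params.end_height_sd), 0.5)
        peak = max(rng.normal(params.tilt_amplitude_mean, params.tilt_amplitude_sd), 0.0)

        k = np.arange(n + 1)
        theta = peak * np.sin(np.pi * k / n)  # half-sine bump, zero at both ends
        rad = np.deg2rad(theta)

        grasp = int(round(0.15 * n))
        release = int(round(0.85 * n))
        release = max(release, grasp + 1)

        # rigid shoulder line rotating about a fixed mid-point
        mid = np.array([0.0, params.shoulder_height])
        offs = params.shoulder_halfspan * np.stack([np.cos(rad), np.sin(rad)], axis=1)
        right_sh = mid + offs
        left_sh = mid - offs

        # task-side elbow: hold base, cosine-ease to end between grasp/release
        s = np.clip((k - grasp) / (release - grasp), 0.0, 1.0)
        ease = 0.5 * (1 - np.cos(np.pi * s))
        elbow_y = base_h + (end_h - base_h) * ease
        elbow_x = params.elbow_x_start + (params.elbow_x_end - params.elbow_x_start) * ease
        task_elbow = np.stack([elbow_x, elbow_y], axis=1)
        rest_elbow = np.tile(np.array([-25.0, 35.0]), (n + 1, 1))

        if params.side == "right":
            left_el, right_el = rest_elbow, task_elbow
        else:
            left_el, right_el = task_elbow, rest_elbow
        positions = np.stack([left_sh, right_sh, left_el, right_el], axis=1)
        if params.side == "left":
            # mirror the scene; anatomical slots keep their identity
            positions = positions.copy()
            positions[:, :, 0] *= -1.0
        if params.landmark_noise_sd > 0:
            positions = positions + rng.normal(0.0, params.landmark_noise_sd, size=positions.shape)

        lms = LandmarkSeries(timestamps=timestamps, positions=positions, side=params.side)
        trials.append(
            SimulatedTrial(
                landmarks=lms,
                grasp_frame=grasp,
                release_frame=release,
                true_tilt_profile=theta if params.side == "right" else -theta,
                condition=params.condition,
            )
        )
    return trials


def training_schedule(
    labels: tuple = MOTION_LABELS, segment_s: float = 3.0, rounds: int = 2
) -> LabelSchedule:
    """Instruction schedule cycling through the motion classes."""
    segs = []
    t = 0.0
    for _ in range(rounds):
        for lab in labels:
            segs.append((t, t + segment_s, lab))
            t += segment_s
    return LabelSchedule(tuple(segs))


# Presets named after the printed summary tables they stylize.  Heights and
# their SDs are the printed values; durations and tilt-peak distributions are
# stylized to reproduce the printed distortion summaries under the half-sine
# tilt model (see docs/methods.md).
_PRESETS: dict[str, dict] = {
    "table1_C": {
        "side": "right",
        "conventional": dict(
            trial_duration_mean=4.2, trial_duration_sd=0.6,
            base_height_mean=45.1, base_height_sd=1.38,
            end_height_mean=27.6, end_height_sd=1.37,
            tilt_amplitude_mean=7.9, tilt_amplitude_sd=2.6,
        ),
        "separate": dict(
            trial_duration_mean=3.8, trial_duration_sd=0.6,
            base_height_mean=22.2, base_height_sd=1.94,
            end_height_mean=10.0, end_height_sd=1.58,
            tilt_amplitude_mean=4.05, tilt_amplitude_sd=2.29,
        ),
    },
    "table2_D": {
        "side": "left",
        "conventional": dict(
            trial_duration_mean=4.20, trial_duration_sd=0.6,
            base_height_mean=26.4, base_height_sd=2.58,
            end_height_mean=14.8, end_height_sd=3.68,
            tilt_amplitude_mean=15.2, tilt_amplitude_sd=2.3,
        ),
        "separate": dict(
            trial_duration_mean=4.68, trial_duration_sd=0.6,
            base_height_mean=20.1, base_height_sd=2.78,
            end_height_mean=11.25, end_height_sd=2.92,
            tilt_amplitude_mean=12.9, tilt_amplitude_sd=2.8,
        ),
    },
}


@dataclass
class Scenario:
    """A fully specified benchmark scenario: EMG + schedule + both task arms."""

    name: str
    emg_params: EmgSimParams
    schedule: LabelSchedule
    task_params: dict  # condition -> TaskSimParams

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "emg_params": asdict(self.emg_params),
            "schedule": list(self.schedule.segments),
            "task_params": {k: asdict(v) for k, v in self.task_params.items()},
        }
        return json.dumps(payload, indent=2)


def available_presets() -> tuple:
    return tuple(sorted(_PRESETS))


def make_benchmark_scenario(name: str = "table1_C", seed: int = 0, n_trials: int = 10) -> Scenario:
    """Build a named preset scenario with per-condition task parameters."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset '{name}'; available: {', '.join(available_presets())}")
    preset = _PRESETS[name]
    emg = EmgSimParams(seed=seed)
    schedule = training_schedule()
    task = {
        cond: TaskSimParams(
            condition=cond,
            n_trials=n_trials,
            side=preset["side"],
            seed=seed + (1 if cond == "conventional" else 2),
            **preset[cond],
        )
        for cond in ("conventional", "separate")
    }
    return Scenario(name=name, emg_params=emg, schedule=schedule, task_params=task)
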