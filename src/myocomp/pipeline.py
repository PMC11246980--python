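"""End-to-end runs: simulate -> features -> control, and simulate -> motion analysis.

Both entry points consume a single RunConfig, write their artefacts under an
output directory, and record a manifest (config hash, seeds, version) so a
run can be reproduced bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from . import io
from .evaluation import TrialRecord, compare_conditions, throughput
from .features import FeatureConfig, extract_feature_stream, feature_matrix
from .intention import (
    RsfConfig,
    build_teacher_dataset,
    command_events,
    map_to_hand_command,
    stabilize_intentions,
    switch_count,
    train_pattern_model,
)
from .kinematics import distortion_level, summarize_trials, trunk_angle_series
from .synthetic import make_benchmark_scenario, simulate_emg, simulate_task_landmarks

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single configuration for the orchestrated runs."""

    preset: str = "table1_C"
    seed: int = 0
    n_trials: int = 10
    out_dir: str | None = None
    buffer_s: float = 2.0
    skip_s: float = 0.5
    rsf_window: int = 10
    rsf_threshold: float = 0.6
    max_duration_s: float = 10.0
    slow_threshold_s: float = 4.0
    bin_width: float = 50.0
    sig_figs: int = 3
    session_window_s: float = 30.0
    inter_trial_s: float = 2.0
    plots: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(config: RunConfig, out_dir: Path, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    io.write_json(manifest, out_dir / "manifest.json")


def run_control_sim(config: RunConfig) -> dict:
    """Closed-loop control simulation: EMG -> features -> train -> stabilised commands.

    A training recording is generated from the preset's instruction schedule,
    the pattern model is fitted on buffered teacher data, and a held-out
    recording (same schedule, independent noise) is pushed through
    prediction, stabilization and hand-command mapping.  Returns the summary
    dict; artefacts are written when ``config.out_dir`` is set.
    """
    scenario = make_benchmark_scenario(config.preset, seed=config.seed, n_trials=config.n_trials)
    schedule = scenario.schedule
    fcfg = FeatureConfig()

    logger.info("simulating training EMG (%.1f s)", schedule.end)
    train_stream = simulate_emg(scenario.emg_params, schedule, duration=schedule.end)
    train_frames = extract_feature_stream(train_stream, fcfg)
    teacher = build_teacher_dataset(train_frames, schedule, config.buffer_s, config.skip_s)
    model = train_pattern_model(teacher, seed=config.seed)

    heldout_params = replace(scenario.emg_params, seed=scenario.emg_params.seed + 10_000)
    test_stream = simulate_emg(heldout_params, schedule, duration=schedule.end)
    test_frames = extract_feature_stream(test_stream, fcfg)
    times, X = feature_matrix(test_frames)
    raw = list(model.predict_batch(X))
    stabilized = stabilize_intentions(raw, RsfConfig(config.rsf_window, config.rsf_threshold))
    commands = [map_to_hand_command(o) for o in stabilized]

    heldout = build_teacher_dataset(test_frames, schedule, config.buffer_s, config.skip_s)
    heldout_acc = float(np.mean(model.predict_batch(heldout.X) == heldout.y))

    summary = {
        "preset": scenario.name,
        "seed": config.seed,
        "feature_dim": int(X.shape[1]),
        "n_teacher_examples": int(teacher.n_examples),
        "classes": list(model.classes),
        "train_accuracy": model.train_accuracy,
        "heldout_accuracy": heldout_acc,
        "raw_switches": switch_count(raw),
        "stabilized_switches": switch_count(stabilized),
        "command_events": command_events(commands),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_features_csv(train_frames, out / "features.csv")
        model.save(out / "model.json")
        io.write_intention_csv(times, raw, stabilized, commands, out / "intention.csv")
        io.write_json(summary, out / "control_summary.json")
        _write_manifest(config, out)
    return summary


def trials_to_records(trials: list, participant: str = "sim") -> list[TrialRecord]:
    """Derive per-trial scalar records from simulated landmark trials."""
    records = []
    for tr in trials:
        theta = trunk_angle_series(tr.landmarks)
        path = tr.landmarks.landmark(f"{tr.landmarks.side}_elbow")
        records.append(
            TrialRecord(
                participant=participant,
                condition=tr.condition,
                duration_s=tr.duration,
                max_angle_deg=float(np.max(np.abs(theta))),
                distortion=distortion_level(theta),
                base_cm=float(path[tr.grasp_frame, 1]),
                end_cm=float(path[tr.release_frame, 1]),
            )
        )
    return records


def session_throughput(trials: list, window: float = 30.0, inter_trial_s: float = 2.0) -> int:
    """Blocks moved in one session window assembled from consecutive trials.

    Completion times accumulate trial durations plus a fixed reach-back
    interval between trials; trials are cycled if the session outlasts them.
    """
    durations = [tr.duration for tr in trials]
    if not durations:
        return 0
    times, t, i = [], 0.0, 0
    while t <= window:
        t += durations[i % len(durations)]
        if t > window:
            break
        times.append(t)
        t += inter_trial_s
        i += 1
    return throughput(times, window)


def run_move_analysis(config: RunConfig) -> dict:
    """Motion analysis of both socket conditions on a preset scenario.

    Simulates landmark trials per condition, derives trunk angles,
    distortions and elbow summaries, filters and flags trials, and assembles
    the comparison report (t-test, histograms, height differences,
    throughput).
    """
    scenario = make_benchmark_scenario(config.preset, seed=config.seed, n_trials=config.n_trials)
    trials = {c: simulate_task_landmarks(p) for c, p in scenario.task_params.items()}
    records = [r for c in trials for r in trials_to_records(trials[c])]

    report = compare_conditions(
        records,
        max_duration=config.max_duration_s,
        slow_threshold=config.slow_threshold_s,
        bin_width=config.bin_width,
        sig=config.sig_figs,
    )
    report.throughput_blocks = {
        c: session_throughput(trials[c], config.session_window_s, config.inter_trial_s)
        for c in trials
    }
    traj = {c: summarize_trials(trials[c]) for c in trials}

    result = report.to_dict()
    result["preset"] = scenario.name
    result["seed"] = config.seed
    result["trajectory"] = {
        c: {
            "checkpoints": t.checkpoints.tolist(),
            "checkpoint_sd": t.checkpoint_sd.tolist(),
            "n_trials": t.n_trials,
        }
        for c, t in traj.items()
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_trial_records_csv(records, out / "trials.csv")
        io.write_json(result, out / "report.json")
        _write_manifest(config, out)
        if config.plots:
            _write_plots(trials, report, out)
    return result


def _write_plots(trials: dict, report, out: Path) -> None:
    """Elbow-path and distortion-histogram figures (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for c, trs in trials.items():
        summary = summarize_trials(trs)
        axes[0].plot(summary.mean_path[:, 0], summary.mean_path[:, 1], label=c)
        axes[0].scatter(summary.checkpoints[:, 0], summary.checkpoints[:, 1], marker="x")
    axes[0].set_xlabel("x (cm)")
    axes[0].set_ylabel("height above tabletop (cm)")
    axes[0].legend()
    for c, h in report.histograms.items():
        centers = h.bin_edges[:-1] + h.bin_width / 2
        axes[1].bar(centers, h.counts, width=h.bin_width * 0.9, alpha=0.5, label=c)
    axes[1].set_xlabel("distortion level")
    axes[1].set_ylabel("trials per bin")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out / "figures.png", dpi=120)
    plt.close(fig)
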