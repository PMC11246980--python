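"""Condition-level comparison of compensatory movement between socket types.

Trials are filtered by a maximum duration, distortion levels are compared by
t-test and summarised as fixed-width histograms with fitted normal overlays,
base/end elbow-height differences are computed per condition, and throughput
is counted as completions within a fixed session window.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

CONDITIONS = ("conventional", "separate")


@dataclass
class TrialRecord:
    """One trial's scalar outcomes."""

    participant: str
    condition: str
    duration_s: float
    max_angle_deg: float
    distortion: float
    base_cm: float
    end_cm: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.distortion < 0:
            raise ValueError("distortion must be >= 0")


def filter_trials(trials: list, max_duration: float = 10.0) -> tuple[list, list]:
    """Partition trials into retained (duration <= cutoff) and excluded.

    The cutoff is read strictly: only trials needing *more* than
    ``max_duration`` seconds are excluded, so a trial at exactly the cutoff
    is retained.
    """
    if max_duration <= 0:
        raise ValueError("max_duration must be positive")
    retained = [t for t in trials if t.duration_s <= max_duration]
    excluded = [t for t in trials if t.duration_s > max_duration]
    return retained, excluded


def flag_slow_trials(trials: list, threshold: float = 4.0) -> np.ndarray:
    """Boolean flags for trials slower than ``threshold`` seconds (plot annotation)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.array([t.duration_s > threshold for t in trials], dtype=bool)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report precision)."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def condition_difference(mean_conventional: float, mean_separate: float, sig: int = 3) -> float:
    """Conventional minus separate mean, at report precision."""
    if not (math.isfinite(mean_conventional) and math.isfinite(mean_separate)):
        raise ValueError("means must be finite")
    return round_sig(mean_conventional - mean_separate, sig)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str
    n_a: int
    n_b: int


def t_test(a, b, variant: str = "paired") -> TTestResult:
    """Two-sided t-test between two samples.

    Variants: ``paired`` (df = n-1), ``pooled`` (equal-variance two-sample,
    df = n_a + n_b - 2) and ``welch`` (Welch-Satterthwaite df).  Identical
    paired samples give t = 0, p = 1; constant nonzero paired differences
    have no defined statistic and raise a zero-variance error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if variant == "paired":
        if a.shape != b.shape or a.size < 2:
            raise ValueError("paired test requires equal-length samples of size >= 2")
        d = a - b
        if np.std(d, ddof=1) == 0:
            if np.all(d == 0):
                return TTestResult(0.0, a.size - 1, 1.0, variant, a.size, b.size)
            raise ValueError("zero variance in paired differences; t undefined")
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(a.size - 1), float(res.pvalue), variant, a.size, b.size)
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'paired', 'pooled' or 'welch'")
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample test requires each sample size >= 2")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if variant == "pooled" else float(a.size + b.size - 2)
            return TTestResult(0.0, float(df), 1.0, variant, a.size, b.size)
        raise ValueError("zero variance in both samples; t undefined")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(a.size + b.size - 2)
    else:
        df = float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue), variant, a.size, b.size)


@dataclass
class Histogram:
    """Fixed-width histogram from 0 with a moment-fitted normal overlay."""

    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    normal_mean: float
    normal_sd: float
    n: int


def distortion_histogram(values, bin_width: float = 50.0) -> Histogram:
    """Histogram of distortion levels in bins [0, w), [w, 2w), ...

    Bins start at 0 (distortion is non-negative) and extend to cover the
    maximum value; the overlay parameters are the sample mean and SD.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if np.any(values < 0):
        raise ValueError("distortion values must be >= 0")
    n_bins = max(int(np.floor(values.max() / bin_width)) + 1, 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return Histogram(
        bin_width=float(bin_width),
        bin_edges=edges,
        counts=counts,
        normal_mean=float(values.mean()),
        normal_sd=sd,
        n=int(values.size),
    )


def throughput(completion_times, window: float = 30.0) -> int:
    """Blocks moved within a session window: completions at time <= window."""
    if window <= 0:
        raise ValueError("window must be positive")
    times = np.asarray(list(completion_times), dtype=float)
    if times.size == 0:
        return 0
    return int(np.sum(times <= window))


@dataclass
class ComparisonReport:
    """Machine-readable condition comparison."""

    n_input: dict
    n_retained: dict
    n_excluded: dict
    distortion_mean: dict
    distortion_sd: dict
    ttest: TTestResult
    histograms: dict
    base_height: dict      # condition -> (mean, sd)
    end_height: dict
    base_height_difference: float
    end_height_difference: float
    slow_flags: dict       # condition -> count of trials slower than the flag threshold
    throughput_blocks: dict | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ttest"] = asdict(self.ttest)
        d["histograms"] = {
            c: {
                "bin_width": h.bin_width,
                "bin_edges": h.bin_edges.tolist(),
                "counts": h.counts.tolist(),
                "normal_mean": h.normal_mean,
                "normal_sd": h.normal_sd,
                "n": h.n,
            }
            for c, h in self.histograms.items()
        }
        return d


def compare_conditions(
    records: list,
    max_duration: float = 10.0,
    slow_threshold: float = 4.0,
    bin_width: float = 50.0,
    sig: int = 3,
) -> ComparisonReport:
    """Full condition comparison from per-trial records.

    Trials slower than ``max_duration`` are excluded before any statistic.
    The distortion t-test is paired by trial index when the retained counts
    match (consistent with reporting df = n-1 over n trial pairs) and Welch
    otherwise; the variant used is recorded in the report.
    """
    by_cond = {c: [r for r in records if r.condition == c] for c in CONDITIONS}
    retained, excluded, flags = {}, {}, {}
    for c in CONDITIONS:
        kept, dropped = filter_trials(by_cond[c], max_duration)
        retained[c], excluded[c] = kept, dropped
        flags[c] = int(flag_slow_trials(kept, slow_threshold).sum()) if kept else 0

    dist = {c: np.array([r.distortion for r in retained[c]]) for c in CONDITIONS}
    if any(v.size < 2 for v in dist.values()):
        raise ValueError("need >= 2 retained trials per condition")
    variant = "paired" if dist["conventional"].size == dist["separate"].size else "welch"
    ttest = t_test(dist["conventional"], dist["separate"], variant=variant)

    base = {c: _summary(np.array([r.base_cm for r in retained[c]])) for c in CONDITIONS}
    end = {c: _summary(np.array([r.end_cm for r in retained[c]])) for c in CONDITIONS}

    return ComparisonReport(
        n_input={c: len(by_cond[c]) for c in CONDITIONS},
        n_retained={c: len(retained[c]) for c in CONDITIONS},
        n_excluded={c: len(excluded[c]) for c in CONDITIONS},
        distortion_mean={c: round_sig(float(dist[c].mean()), sig) for c in CONDITIONS},
        distortion_sd={c: round_sig(float(dist[c].std(ddof=1)), sig) for c in CONDITIONS},
        ttest=ttest,
        histograms={c: distortion_histogram(dist[c], bin_width) for c in CONDITIONS},
        base_height=base,
        end_height=end,
        base_height_difference=condition_difference(base["conventional"][0], base["separate"][0], sig),
        end_height_difference=condition_difference(end["conventional"][0], end["separate"][0], sig),
        slow_flags=flags,
    )


def _summary(values: np.ndarray) -> tuple[float, float]:
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd
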