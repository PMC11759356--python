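"""Pupil-area trace summarization.

Traces are recorded at 500 Hz in raw pixel-area units with white/black
reference screens at both ends of each trial (used for QC only — areas are
reported in raw units, and black > task > white is the expected ordering).
Blink dropouts are repaired by linear interpolation when short, marked
missing otherwise; trials with more than half their samples missing are
flagged unusable.  Group summaries are per-trial task-period means averaged
within group, with the percent difference between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from sapm.synth import PupilTrace

__all__ = [
    "PupilSummary",
    "repair_blinks",
    "reference_qc",
    "group_mean_area",
    "percent_difference",
    "average_trace",
]


def repair_blinks(
    trace: PupilTrace, drop_threshold: float = 0.5, max_gap: float = 0.5
) -> PupilTrace:
    """Interpolate blink dropouts; flag the trial unusable if > 50% missing.

    Samples whose area falls at or below ``drop_threshold`` times the trace
    median are dropouts; runs of dropouts no longer than ``max_gap`` seconds
    are linearly interpolated, longer runs become NaN.
    """
    area = np.asarray(trace.area, float).copy()
    n = area.size
    med = float(np.median(area))
    bad = area <= drop_threshold * max(med, 1e-12)

    usable = bool(bad.mean() <= 0.5)
    out = area.copy()
    if bad.any() and usable:
        idx = np.flatnonzero(bad)
        # group consecutive dropouts
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            gap_s = run.size / trace.fs
            lo, hi = run[0] - 1, run[-1] + 1
            if gap_s <= max_gap and lo >= 0 and hi < n:
                out[run] = np.interp(run, [lo, hi], [area[lo], area[hi]])
            else:
                out[run] = np.nan
    elif not usable:
        out[bad] = np.nan
    repaired = replace(trace, area=out)
    repaired.usable = usable
    return repaired


def reference_qc(trace: PupilTrace) -> bool:
    """QC check on reference screens: mean black area > mean task area >
    mean white area (pupil constricts to light)."""
    a = np.asarray(trace.area, float)
    s = np.asarray(trace.screen_state)
    means = {k: np.nanmean(a[s == k]) for k in ("white", "black", "task")}
    return means["black"] > means["task"] > means["white"]


@dataclass
class PupilSummary:
    """Group mean pupil areas over the task period and their % difference."""

    group_means: dict
    n_trials: dict
    n_participants: dict
    percent_difference: float
    reference_groups: tuple


def percent_difference(mean_a: float, mean_b: float) -> float:
    """100 * (mean_a - mean_b) / mean_b."""
    return 100.0 * (mean_a - mean_b) / mean_b


def group_mean_area(traces: list, period: str = "task") -> PupilSummary:
    """Per-trial mean area over ``period`` samples, averaged within group.

    The percent difference uses the first two groups encountered (A vs B,
    relative to B).  Unusable trials (flagged by :func:`repair_blinks`) are
    excluded; an error is raised if a group has none left.
    """
    by_group: dict[str, list[float]] = {}
    participants: dict[str, set] = {}
    for tr in traces:
        by_group.setdefault(tr.group, [])
        participants.setdefault(tr.group, set())
        if not getattr(tr, "usable", True):
            continue
        mask = np.asarray(tr.screen_state) == period
        m = float(np.nanmean(np.asarray(tr.area, float)[mask]))
        by_group[tr.group].append(m)
        participants[tr.group].add(tr.participant)
    if not by_group or any(len(v) == 0 for v in by_group.values()):
        raise ValueError("no usable trials in at least one group")
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    groups = list(means)
    pd_val = (
        percent_difference(means[groups[0]], means[groups[1]]) if len(groups) >= 2 else 0.0
    )
    return PupilSummary(
        group_means=means,
        n_trials={g: len(v) for g, v in by_group.items()},
        n_participants={g: len(p) for g, p in participants.items()},
        percent_difference=pd_val,
        reference_groups=tuple(groups[:2]) if len(groups) >= 2 else tuple(groups),
    )


def average_trace(
    traces: list, grid_fs: float = 50.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-locked mean +/- sem trace, resampled to a common paradigm clock.

    All traces must share their paradigm timing (equal durations).  Returns
    (times, mean, sem) on a ``grid_fs``-Hz grid; resampling is linear
    interpolation over non-missing samples.
    """
    if not traces:
        raise ValueError("need at least one trace")
    durations = {round(tr.area.size / tr.fs, 6) for tr in traces}
    if len(durations) != 1:
        raise ValueError(f"incompatible trial timing: durations {sorted(durations)}")
    duration = durations.pop()
    grid = np.arange(0.0, duration, 1.0 / grid_fs)
    rows = []
    for tr in traces:
        t = tr.times
        a = np.asarray(tr.area, float)
        ok = np.isfinite(a)
        rows.append(np.interp(grid, t[ok], a[ok]))
    stacked = np.stack(rows)
    mean = stacked.mean(axis=0)
    sem = stats.sem(stacked, axis=0, ddof=1) if len(rows) > 1 else np.zeros_like(mean)
    return grid, mean, sem
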