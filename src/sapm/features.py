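"""Bespoke BOLD time-course features.

* Initial rise: the increase in signal over roughly the first 40 s of a run,
  before any stimulus — quantified as the mean over a plateau window
  (default 40-60 s, ending before the 60-s inform cue) minus the value at the
  first retained volume.  The companion "starting point" is the first
  retained value of the mean-centered course (the plotting-axis convention in
  which a rise appears as a negative start); both are reported to avoid sign
  ambiguity.
* Event responses: signal increase after stimulation onset and offset —
  maximum over the 15 s following the event minus the mean over the 10 s
  preceding it (standard hemodynamic latency windows; configurable).
* Baseline alignment for group overlays: one course is shifted vertically so
  both start at the same value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sapm.synth import ParadigmSpec

__all__ = [
    "TimecourseFeatures",
    "EventResponses",
    "initial_rise",
    "event_responses",
    "align_baselines",
]


@dataclass
class TimecourseFeatures:
    """Initial-rise quantification for one time course."""

    initial_rise: float
    starting_point: float
    region: str = ""
    participant: str = ""
    condition: str = ""


def initial_rise(
    tc: np.ndarray,
    TR: float,
    n_masked: int = 0,
    rise_window: tuple[float, float] = (0.0, 40.0),
    plateau_window: tuple[float, float] = (40.0, 60.0),
    **meta,
) -> TimecourseFeatures:
    """Quantify the initial rise of a percent-signal-change time course.

    ``n_masked`` initial volumes were replaced during preparation; the first
    retained volume (index ``n_masked``) is the rise's starting value.
    """
    tc = np.asarray(tc, float)
    t = np.arange(tc.size) * TR
    run_end = tc.size * TR
    for name, (lo, hi) in (("rise_window", rise_window), ("plateau_window", plateau_window)):
        if lo < 0 or hi > run_end or hi <= lo:
            raise ValueError(f"{name} {lo, hi} outside run [0, {run_end}]")
    first_retained = n_masked
    if first_retained * TR >= rise_window[1]:
        raise ValueError(
            f"rise window ends at {rise_window[1]} s but the first retained volume "
            f"is at {first_retained * TR} s (masked-only data)"
        )
    plateau = (t >= plateau_window[0]) & (t < plateau_window[1])
    if not plateau.any():
        raise ValueError("plateau window contains no volumes")
    start_value = tc[first_retained]
    rise = float(tc[plateau].mean() - start_value)
    centered = tc - tc.mean()
    return TimecourseFeatures(
        initial_rise=rise, starting_point=float(centered[first_retained]), **meta
    )


@dataclass
class EventResponses:
    """Stimulation onset/offset response magnitudes; undefined for No-Pain."""

    onset_response: float
    offset_response: float
    defined: bool = True


def event_responses(
    tc: np.ndarray,
    paradigm: ParadigmSpec,
    post_window: float = 15.0,
    baseline_window: float = 10.0,
) -> EventResponses:
    """Response = max over [event, event + 15 s] minus the mean over the
    10 s preceding the event, for stimulation onset and offset."""
    if paradigm.condition != "Pain":
        return EventResponses(onset_response=np.nan, offset_response=np.nan, defined=False)
    tc = np.asarray(tc, float)
    t = np.arange(tc.size) * paradigm.TR

    def one(event: float) -> float:
        post = (t >= event) & (t <= event + post_window)
        base = (t >= event - baseline_window) & (t < event)
        if not post.any() or not base.any():
            raise ValueError(f"event at {event} s has empty response/baseline window")
        return float(tc[post].max() - tc[base].mean())

    return EventResponses(
        onset_response=one(paradigm.stimulus_onset),
        offset_response=one(paradigm.stimulus_offset),
    )


def align_baselines(tc_a: np.ndarray, tc_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shift ``tc_b`` vertically so both courses share ``tc_a``'s starting
    value; differences between the aligned courses are offset-invariant."""
    tc_a = np.asarray(tc_a, float)
    tc_b = np.asarray(tc_b, float)
    if tc_a.shape != tc_b.shape:
        raise ValueError(f"length mismatch: {tc_a.shape} vs {tc_b.shape}")
    return tc_a, tc_b + (tc_a[0] - tc_b[0])
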