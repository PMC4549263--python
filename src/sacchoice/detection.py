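"""Offline velocity-threshold saccade detection and trial rejection.

The detector works backwards from the behaviourally decisive event: the
first sample after stimulus onset where the horizontal eye position
crosses an inner image border fixes the saccade's direction. Candidate
onsets are the samples whose 2-D point-to-point speed exceeds a
threshold of ``velocity_sigma`` (default 3) standard deviations of the
speed during the 200 ms pre-stimulus blank. Among the candidates, the
onset is the one at which the sign of the horizontal velocity last
changed and then stayed constant up to the border crossing — i.e. the
start of the final monotone sweep toward the chosen image.

Trials are rejected as anticipations (onset earlier than 80 ms after
stimulus onset), fixation failures (gaze leaving a radius around screen
center within the first 80 ms), or when no saccade is found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .synthetic import GazeTrace, SimulatedDataset


@dataclass(frozen=True)
class DetectionConfig:
    """Detector thresholds and screen layout.

    ``border_x_left``/``border_x_right`` are the inner image borders in
    px; gaze at or beyond a border counts as a crossing. ``min_srt`` is
    the anticipation cutoff: onsets strictly earlier are rejected, an
    onset exactly at the cutoff is accepted.
    """

    baseline_window: float = 200.0  # ms of blank used for the velocity baseline
    velocity_sigma: float = 3.0
    min_srt: float = 80.0
    fixation_window: float = 80.0
    fixation_radius_deg: float = 2.0
    border_x_left: float = DEFAULT_GEOMETRY.border_x_left
    border_x_right: float = DEFAULT_GEOMETRY.border_x_right
    screen_center: tuple[float, float] = DEFAULT_GEOMETRY.center
    px_per_deg: float = DEFAULT_GEOMETRY.px_per_deg

    def __post_init__(self):
        if min(self.baseline_window, self.velocity_sigma, self.min_srt,
               self.fixation_window, self.fixation_radius_deg) <= 0:
            raise ValueError("all detection parameters must be positive")
        cx = self.screen_center[0]
        if not np.isclose(cx - self.border_x_left, self.border_x_right - cx):
            raise ValueError("image borders must be symmetric about screen center")

    @classmethod
    def from_geometry(cls, geometry: ScreenGeometry, **kwargs) -> "DetectionConfig":
        return cls(
            border_x_left=geometry.border_x_left,
            border_x_right=geometry.border_x_right,
            screen_center=geometry.center,
            px_per_deg=geometry.px_per_deg,
            **kwargs,
        )

    @property
    def fixation_radius_px(self) -> float:
        return self.fixation_radius_deg * self.px_per_deg


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected saccade: onset and direction from the border crossing."""

    onset: float  # ms from stimulus onset
    direction: str  # "left" | "right"
    border_crossing: float  # ms from stimulus onset

    def __post_init__(self):
        if self.onset > self.border_crossing:
            raise ValueError("onset must not be later than the border crossing")


@dataclass(frozen=True)
class TrialResult:
    """Per-trial detection outcome."""

    status: str  # accepted | rejected_anticipation | rejected_fixation |
    #              rejected_no_saccade | rejected_error
    srt: float | None = None
    direction: str | None = None
    correct: bool | None = None
    reason: str = ""


def compute_velocity(trace: GazeTrace) -> np.ndarray:
    """Point-to-point 2-D speed (px/ms), aligned to the later sample.

    Returns an array of length ``n - 1``; element ``i`` is the Euclidean
    displacement between samples ``i`` and ``i + 1``. Requires a uniform
    1 ms timestamp step.
    """
    t = np.asarray(trace.t)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if not np.all(dt == dt[0]):
        raise ValueError("timestamps must be uniformly spaced")
    return np.hypot(np.diff(trace.x), np.diff(trace.y)) / float(dt[0])


def find_border_crossing(
    trace: GazeTrace, config: DetectionConfig
) -> tuple[float, str] | None:
    """Earliest post-onset sample at or beyond an inner image border.

    Returns ``(time_ms, direction)`` or ``None`` if the horizontal
    position never reaches a border within the trace.
    """
    post = trace.post_onset
    x = trace.x[post]
    t = trace.t[post]
    hit = (x <= config.border_x_left) | (x >= config.border_x_right)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return None
    i = idx[0]
    direction = "left" if x[i] <= config.border_x_left else "right"
    return float(t[i]), direction


def detect_onset(trace: GazeTrace, config: DetectionConfig) -> SaccadeEvent | None:
    """Find the saccade onset for a trace whose gaze crosses a border.

    The onset is where the sign of the horizontal velocity last changed
    before the border crossing — the start of the terminal monotone
    sweep toward the chosen image — validated by the sweep containing
    at least one supra-threshold velocity sample. Returns ``None`` when
    no border crossing exists, when no sample between stimulus onset
    and the crossing exceeds the velocity threshold, or when the
    terminal sweep contains no supra-threshold sample (the crossing was
    not produced by a saccade-speed movement). If the horizontal
    velocity has no sign change at all before the crossing (a monotone
    sweep from stimulus onset), the first supra-threshold candidate is
    the onset.
    """
    crossing = find_border_crossing(trace, config)
    if crossing is None:
        return None
    t_cross, direction = crossing

    v = compute_velocity(trace)
    t_v = np.asarray(trace.t)[1:]  # velocity timestamps (later sample)
    baseline = (t_v >= trace.stimulus_onset - config.baseline_window) & (
        t_v < trace.stimulus_onset
    )
    if not np.any(baseline):
        raise ValueError("trace does not cover the pre-stimulus baseline window")
    threshold = config.velocity_sigma * float(np.std(v[baseline]))

    window = (t_v >= trace.stimulus_onset) & (t_v <= t_cross)
    widx = np.flatnonzero(window)
    candidates = widx[v[widx] > threshold]
    if candidates.size == 0:
        return None

    # last sign change of dx before the crossing, constant sign after
    dx_sign = np.sign(np.diff(trace.x))
    start, cross_i = widx[0], widx[-1]
    final_sign = -1.0 if direction == "left" else 1.0
    mismatch = np.flatnonzero(dx_sign[start : cross_i + 1] != final_sign)
    if mismatch.size == 0:
        chosen = candidates[0]  # monotone from stimulus onset
    else:
        last_change = start + mismatch[-1] + 1
        if last_change > cross_i or not np.any(candidates >= last_change):
            return None  # crossing not reached by a supra-threshold sweep
        chosen = last_change
    onset = float(t_v[chosen]) - trace.stimulus_onset
    return SaccadeEvent(onset=onset, direction=direction,
                        border_crossing=t_cross - trace.stimulus_onset)


def apply_rejection_filters(
    event: SaccadeEvent | None,
    trace: GazeTrace,
    config: DetectionConfig,
    target_hemifield: str,
) -> TrialResult:
    """Classify a trial given its (possibly absent) detected saccade.

    Precedence: anticipation (onset before ``min_srt``), then fixation
    failure (gaze farther than ``fixation_radius_deg`` from center in
    the first ``fixation_window`` ms after stimulus onset), then missing
    saccade; otherwise accepted with ``srt = onset`` and correctness
    judged against the target hemifield.
    """
    if event is not None and event.onset < config.min_srt:
        return TrialResult(status="rejected_anticipation", srt=event.onset,
                           direction=event.direction, reason="onset before cutoff")
    t = np.asarray(trace.t) - trace.stimulus_onset
    fix = (t >= 0) & (t < config.fixation_window)
    cx, cy = config.screen_center
    dist = np.hypot(trace.x[fix] - cx, trace.y[fix] - cy)
    if np.any(dist > config.fixation_radius_px):
        return TrialResult(status="rejected_fixation", reason="fixation not held")
    if event is None:
        return TrialResult(status="rejected_no_saccade", reason="no saccade detected")
    return TrialResult(
        status="accepted",
        srt=event.onset,
        direction=event.direction,
        correct=event.direction == target_hemifield,
    )


def detect_trial(
    trace: GazeTrace, config: DetectionConfig, target_hemifield: str
) -> TrialResult:
    """Detect and classify a single trial; errors become rejections."""
    window = np.asarray(trace.t) >= trace.stimulus_onset - config.baseline_window
    if np.any(~np.isfinite(trace.x[window])) or np.any(~np.isfinite(trace.y[window])):
        return TrialResult(status="rejected_error", reason="missing samples in analysis window")
    try:
        event = detect_onset(trace, config)
    except ValueError as exc:
        return TrialResult(status="rejected_error", reason=str(exc))
    return apply_rejection_filters(event, trace, config, target_hemifield)


def detect_all(dataset: SimulatedDataset, config: DetectionConfig | None = None) -> pd.DataFrame:
    """Run detection over a dataset; one result row per trial."""
    if config is None:
        config = DetectionConfig.from_geometry(dataset.traces[0].geometry)
    rows = []
    for spec, trace in zip(dataset.design.trials, dataset.traces):
        res = detect_trial(trace, config, spec.target_hemifield)
        rows.append(
            {
                "subject": spec.subject,
                "block": spec.block,
                "trial_index": spec.trial_index,
                "target_category": spec.task[0],
                "distractor_category": spec.task[1],
                "task": spec.task_label,
                "target_hemifield": spec.target_hemifield,
                "target_image": spec.target_image,
                "distractor_image": spec.distractor_image,
                "status": res.status,
                "srt": res.srt,
                "direction": res.direction,
                "correct": res.correct,
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows)


def rejection_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Rejection counts per task condition (supplementary-table layout)."""
    tab = (
        results.groupby(["task", "status"]).size().unstack(fill_value=0).reset_index()
    )
    tab["total"] = tab.drop(columns="task").sum(axis=1)
    rejected = [c for c in tab.columns if str(c).startswith("rejected")]
    tab["rejected"] = tab[rejected].sum(axis=1) if rejected else 0
    return tab
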