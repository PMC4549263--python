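"""Synthetic 1000 Hz gaze traces with planted ground truth.

Each simulated trial reproduces the task's recording window: the 200 ms
blank before stimulus onset plus the 400 ms stimulus window, sampled at
1 kHz. The eye fixates screen center with Gaussian jitter until a planted
saccade onset, then follows a smooth logistic displacement profile toward
the left or right image (amplitude = image-center eccentricity). The
planted onset latency, direction and artifact flags are recorded so every
downstream stage can be validated against ground truth.

Latency distributions, error rates and artifact probabilities are
configurable per task; the defaults emulate the published study
conditions (Table-1-style accuracies and mean SRTs per task, ~3%
anticipations and ~3% fixation breaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .design import ExperimentDesign, TrialSpec, TASKS
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry

# ---------------------------------------------------------------------------
# Component models


@dataclass(frozen=True)
class ShiftedLogNormalLatency:
    """Shifted log-normal saccade latency (ms).

    ``latency = shift + LogNormal(mu, sigma)`` with ``mu`` chosen so the
    distribution mean equals ``mean_ms``. Samples are truncated to
    ``max_ms`` so the saccade completes within the stimulus window.
    """

    mean_ms: float = 190.0
    sigma: float = 0.30
    shift: float = 80.0
    max_ms: float = 340.0

    def __post_init__(self):
        if self.mean_ms <= self.shift:
            raise ValueError("mean_ms must exceed shift")

    @property
    def mu(self) -> float:
        return float(np.log(self.mean_ms - self.shift) - self.sigma**2 / 2.0)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        x = self.shift + rng.lognormal(self.mu, self.sigma, size=size)
        return np.minimum(x, self.max_ms)


@dataclass(frozen=True)
class TruncatedNormalLatency:
    """Normal latency truncated below at ``lower`` ms (rejection sampling)."""

    mean_ms: float = 200.0
    sd_ms: float = 25.0
    lower: float = 80.0
    max_ms: float = 340.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        n = 1 if size is None else int(size)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean_ms, self.sd_ms, size=2 * (n - filled))
            draw = draw[draw >= self.lower]
            take = min(len(draw), n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        out = np.minimum(out, self.max_ms)
        return out[0] if size is None else out


@dataclass(frozen=True)
class ConstantError:
    """Latency-independent error probability (toward the distractor)."""

    p_error: float = 0.1

    def p_error_at(self, latency_ms: float) -> float:
        return self.p_error


@dataclass(frozen=True)
class LatencyDependentError:
    """Accuracy rises from chance with latency along a logistic curve.

    ``P(correct | latency) = 0.5 + (asymptote - 0.5) * expit((latency -
    crossover_ms) / width_ms)`` — saccades launched before the planted
    crossover are guesses; later ones approach the asymptotic accuracy.
    """

    asymptote: float = 0.95
    crossover_ms: float = 150.0
    width_ms: float = 10.0

    def p_error_at(self, latency_ms: float) -> float:
        p_correct = 0.5 + (self.asymptote - 0.5) * expit(
            (np.asarray(latency_ms) - self.crossover_ms) / self.width_ms
        )
        return 1.0 - p_correct


@dataclass(frozen=True)
class NoiseModel:
    """Fixation jitter and measurement noise.

    Jitter is a stationary AR(1) (discrete Ornstein-Uhlenbeck) drift
    with positional SD ``jitter_sd_deg`` and per-millisecond
    autocorrelation ``jitter_ar``: fixational eye drift wanders slowly,
    so its sample-to-sample velocity is far smaller than a saccade's.
    ``measurement_sd_px`` adds white tracker noise on top.
    """

    jitter_sd_deg: float = 0.15
    jitter_ar: float = 0.98
    measurement_sd_px: float = 0.0

    def jitter_sd_px(self, geometry: ScreenGeometry) -> float:
        return geometry.deg_to_px(self.jitter_sd_deg)

    def jitter_series(self, n: int, geometry: ScreenGeometry,
                      rng: np.random.Generator) -> np.ndarray:
        """Draw an AR(1) positional jitter series of length ``n`` (px)."""
        sd = self.jitter_sd_px(geometry)
        if sd == 0 or n == 0:
            return np.zeros(n)
        rho = self.jitter_ar
        innov_sd = sd * np.sqrt(1.0 - rho**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        eps[0] = rng.normal(0.0, sd)  # stationary start
        from scipy.signal import lfilter

        return lfilter([1.0], [1.0, -rho], eps)


@dataclass(frozen=True)
class ArtifactModel:
    """Probabilities of trial artifacts exercising the rejection filters."""

    p_anticipation: float = 0.03
    p_fixation_break: float = 0.03
    p_no_saccade: float = 0.0
    anticipation_range_ms: tuple[float, float] = (20.0, 75.0)
    fixation_break_amplitude_deg: float = 3.0


NO_ARTIFACTS = ArtifactModel(0.0, 0.0, 0.0)
NOISELESS = NoiseModel(0.0, 0.0)


@dataclass(frozen=True)
class ConditionParams:
    """Generating parameters for one task (target vs. distractor pair)."""

    latency_model: object
    error_model: object


#: Published per-task accuracies (%) and mean SRTs (ms); the chance-level
#: unknown-vs-familiar task has no reported mean, 191 ms is assumed.
TABLE1_CONDITIONS: dict[tuple[str, str], tuple[float, float]] = {
    ("FamiliarFace", "Object"): (92.72, 172.0),
    ("Object", "FamiliarFace"): (85.59, 216.0),
    ("UnknownFace", "Object"): (92.77, 171.0),
    ("Object", "UnknownFace"): (86.21, 200.0),
    ("FamiliarFace", "UnknownFace"): (61.81, 191.0),
    ("UnknownFace", "FamiliarFace"): (55.28, 191.0),
}


def default_condition_params() -> dict[tuple[str, str], ConditionParams]:
    """Study-condition defaults: one latency/error model per task."""
    return {
        task: ConditionParams(
            latency_model=ShiftedLogNormalLatency(mean_ms=srt),
            error_model=ConstantError(p_error=1.0 - acc / 100.0),
        )
        for task, (acc, srt) in TABLE1_CONDITIONS.items()
    }


# ---------------------------------------------------------------------------
# Trace containers


@dataclass
class GazeTrace:
    """One trial's gaze sample stream at 1 kHz.

    ``t`` holds integer millisecond timestamps relative to stimulus onset
    (t = 0); the trace spans the 200 ms blank (t in [-200, 0)) and the
    400 ms stimulus window (t in [0, 400)).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stimulus_onset: int = 0
    sampling_rate: float = 1000.0
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self):
        self.t = np.asarray(self.t)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")

    @property
    def post_onset(self) -> np.ndarray:
        return self.t >= self.stimulus_onset


@dataclass(frozen=True)
class GroundTruth:
    """Planted trial parameters recorded by the generator."""

    true_onset: float | None  # ms from stimulus onset; None = no saccade
    true_direction: str | None  # "left" | "right"
    correct: bool | None  # direction == target hemifield
    latency_model: str
    anticipation: bool = False
    fixation_break: bool = False


def _logistic_profile(u: np.ndarray, steepness: float = 10.0) -> np.ndarray:
    """Normalized sigmoidal displacement: 0 at u=0, 1 at u=1, monotone."""
    raw = expit(steepness * (u - 0.5))
    lo, hi = expit(-steepness / 2.0), expit(steepness / 2.0)
    return (raw - lo) / (hi - lo)


def saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence duration: ~2.2 ms/deg + 21 ms, clamped to 30-60 ms."""
    return float(np.clip(2.2 * amplitude_deg + 21.0, 30.0, 60.0))


def simulate_trial(
    spec: TrialSpec,
    latency_model,
    error_model,
    noise_model: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    artifact_model: ArtifactModel = NO_ARTIFACTS,
) -> tuple[GazeTrace, GroundTruth]:
    """Simulate one trial's gaze trace with planted ground truth.

    The eye holds fixation (with jitter) until the planted onset, then a
    logistic horizontal displacement of amplitude equal to the image
    eccentricity carries it past the inner image border. With the
    configured probabilities the trial instead contains an anticipatory
    saccade (onset before 80 ms, random direction), a fixation break (a
    vertical excursion inside the first 80 ms), or no saccade at all.

    Raises
    ------
    ValueError
        If the planted saccade could not cross the inner image border
        within the recorded trace.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pre = spec.blank_duration
    n_post = spec.stimulus_duration
    t = np.arange(-n_pre, n_post)
    cx, cy = geometry.center

    anticipation = rng.random() < artifact_model.p_anticipation
    fixation_break = (not anticipation) and rng.random() < artifact_model.p_fixation_break
    no_saccade = rng.random() < artifact_model.p_no_saccade

    if no_saccade:
        onset = None
        direction = None
        correct = None
    elif anticipation:
        lo, hi = artifact_model.anticipation_range_ms
        onset = float(rng.uniform(lo, hi))
        direction = "left" if rng.random() < 0.5 else "right"
        correct = direction == spec.target_hemifield
    else:
        onset = float(np.atleast_1d(latency_model.sample(rng))[0])
        p_err = float(error_model.p_error_at(onset))
        wrong = rng.random() < p_err
        direction = (
            spec.target_hemifield
            if not wrong
            else ("left" if spec.target_hemifield == "right" else "right")
        )
        correct = not wrong

    x = np.full(t.shape, cx)
    y = np.full(t.shape, cy)

    if onset is not None:
        amplitude_px = geometry.deg_to_px(geometry.eccentricity_deg)
        duration = saccade_duration_ms(geometry.eccentricity_deg)
        if onset + duration > n_post:
            raise ValueError(
                f"saccade at {onset:.0f}ms (+{duration:.0f}ms) does not "
                f"complete within the {n_post}ms stimulus window"
            )
        sign = -1.0 if direction == "left" else 1.0
        u = np.clip((t - onset) / duration, 0.0, 1.0)
        x = x + sign * amplitude_px * _logistic_profile(u)
        # crossing must happen inside the trace
        border = geometry.inner_border_px
        if not np.any(np.abs(x - cx) >= border):
            raise ValueError("saccade amplitude never crosses the image border")

    if noise_model.jitter_sd_px(geometry) > 0:
        # drift only while fixating; the saccade segment stays smooth
        fixating = np.ones(t.shape, dtype=bool) if onset is None else (t < onset)
        jx = noise_model.jitter_series(len(t), geometry, rng)
        jy = noise_model.jitter_series(len(t), geometry, rng)
        x = x + np.where(fixating, jx, 0.0)
        y = y + np.where(fixating, jy, 0.0)
    if noise_model.measurement_sd_px > 0:
        x = x + rng.normal(0.0, noise_model.measurement_sd_px, size=t.shape)
        y = y + rng.normal(0.0, noise_model.measurement_sd_px, size=t.shape)

    if fixation_break:
        amp = geometry.deg_to_px(artifact_model.fixation_break_amplitude_deg)
        t_break = float(rng.uniform(10.0, 70.0))
        in_break = (t >= t_break) & (t < t_break + 40.0)
        y = y + np.where(in_break, amp, 0.0)

    trace = GazeTrace(t=t, x=x, y=y, geometry=geometry)
    truth = GroundTruth(
        true_onset=onset,
        true_direction=direction,
        correct=correct,
        latency_model=type(latency_model).__name__,
        anticipation=anticipation,
        fixation_break=fixation_break,
    )
    return trace, truth


@dataclass
class SimulatedDataset:
    """Traces, specs and ground truth for a full simulated experiment."""

    design: ExperimentDesign
    traces: list[GazeTrace]
    ground_truth: list[GroundTruth]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.traces)

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject": [s.subject for s in self.design.trials],
                "trial_index": [s.trial_index for s in self.design.trials],
                "true_onset": [g.true_onset for g in self.ground_truth],
                "true_direction": [g.true_direction for g in self.ground_truth],
                "correct": [g.correct for g in self.ground_truth],
                "latency_model": [g.latency_model for g in self.ground_truth],
                "anticipation": [g.anticipation for g in self.ground_truth],
                "fixation_break": [g.fixation_break for g in self.ground_truth],
            }
        )


def simulate_experiment(
    design: ExperimentDesign,
    condition_params: dict[tuple[str, str], ConditionParams] | None = None,
    seed: int = 0,
    noise_model: NoiseModel = NoiseModel(),
    artifact_model: ArtifactModel = ArtifactModel(),
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
) -> SimulatedDataset:
    """Simulate gaze traces for every trial of a design.

    Deterministic given ``seed``: per-trial generators are spawned from a
    single root ``SeedSequence`` so the output is reproducible regardless
    of trial order.
    """
    if condition_params is None:
        condition_params = default_condition_params()
    missing = {s.task for s in design.trials} - set(condition_params)
    if missing:
        raise ValueError(f"condition_params missing tasks: {sorted(missing)}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(design.trials))
    traces, truths = [], []
    for spec, child in zip(design.trials, children):
        params = condition_params[spec.task]
        trace, truth = simulate_trial(
            spec,
            params.latency_model,
            params.error_model,
            noise_model=noise_model,
            seed=np.random.default_rng(child),
            geometry=geometry,
            artifact_model=artifact_model,
        )
        traces.append(trace)
        truths.append(truth)
    return SimulatedDataset(design=design, traces=traces, ground_truth=truths, seed=seed)
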