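"""Synthetic video-oculography cohorts with known ground truth.

The simulated paradigm is a peripheral two-alternative recognition task: a
central fixation dot, a first target at fixation, then a second target at
55 degrees in the left or right periphery.  The subject shifts gaze to the
peripheral target after a saccadic latency (SL) drawn from a subject- and
task-specific distribution, and presses a yes/no button.  Two task types
alternate: a color task (lower cognitive demand) and a Landolt-ring
orientation task (higher demand).  Trials come in blocks within which task
and side are exactly balanced and randomly ordered.

Saccade kinematics follow the oculomotor main sequence: duration grows
roughly linearly with amplitude while peak velocity saturates.  Each
saccade has a raised-cosine velocity profile, which is smooth, unimodal and
integrates to the amplitude in closed form, so the detector downstream has
physiological velocity waveforms to find.

The per-group latency distributions default to the means and SDs of the
schizophrenia / first-degree-relative / healthy-control cohort this package
models; subject task means are drawn from a correlated bivariate normal per
group (the cross-task correlation is what paired within-group statistics
are sensitive to), and single-trial latencies around the subject mean are
floor-truncated Gaussians (the floor excludes anticipatory saccades).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_SAMPLING_RATE_HZ, GazeTrace

TASKS = ("color", "landolt")
SIDES = ("left", "right")
GROUPS = ("patient", "control", "relative")

#: Hard floor (ms) below which a latency counts as anticipatory.
LATENCY_FLOOR_MS = 80.0


@dataclass(frozen=True)
class GeometryConfig:
    """Stimulus geometry: 80 cm viewing distance, 6 cm (4.3 deg) targets
    at 55 deg eccentricity on the horizontal meridian."""

    viewing_distance_cm: float = 80.0
    target_size_cm: float = 6.0
    target_eccentricity_deg: float = 55.0
    eye_height_offset_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing_distance_cm must be positive")
        if not 0.0 < self.target_eccentricity_deg < 90.0:
            raise ValueError("target_eccentricity_deg must lie in (0, 90)")


@dataclass(frozen=True)
class MainSequenceParams:
    """Amplitude-duration-velocity law for simulated saccades.

    ``duration(A)`` is the larger of the linear law
    ``duration_slope * A + duration_intercept`` and the duration required
    for a raised-cosine profile whose peak obeys the saturating law
    ``vmax_asymptote * (1 - exp(-A / vmax_angular_constant))``.  The second
    term dominates for large amplitudes and keeps peak velocity
    physiological (in particular below the 750 deg/s artifact ceiling).
    """

    duration_slope_ms_per_deg: float = 2.2
    duration_intercept_ms: float = 21.0
    vmax_asymptote_deg_s: float = 600.0
    vmax_angular_constant_deg: float = 16.0

    def __post_init__(self) -> None:
        for name, v in (
            ("duration_slope_ms_per_deg", self.duration_slope_ms_per_deg),
            ("duration_intercept_ms", self.duration_intercept_ms),
            ("vmax_asymptote_deg_s", self.vmax_asymptote_deg_s),
            ("vmax_angular_constant_deg", self.vmax_angular_constant_deg),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    def saturating_peak_velocity(self, amplitude_deg: float) -> float:
        """Main-sequence peak velocity bound (deg/s) for an amplitude."""
        return self.vmax_asymptote_deg_s * (
            1.0 - math.exp(-amplitude_deg / self.vmax_angular_constant_deg)
        )

    def duration_ms(self, amplitude_deg: float) -> float:
        linear = (
            self.duration_slope_ms_per_deg * amplitude_deg
            + self.duration_intercept_ms
        )
        if amplitude_deg <= 0:
            return linear
        consistent = 2000.0 * amplitude_deg / self.saturating_peak_velocity(amplitude_deg)
        return max(linear, consistent)

    def peak_velocity_deg_s(self, amplitude_deg: float) -> float:
        """Actual profile peak, 2A/D for the raised cosine (deg/s)."""
        if amplitude_deg <= 0:
            return 0.0
        return 2000.0 * amplitude_deg / self.duration_ms(amplitude_deg)


@dataclass(frozen=True)
class TrialTiming:
    """Step-paradigm trial timing (ms).  The second target replaces the
    first with no gap; its onset is the reference time for latency."""

    fixation_duration_ms: float = 500.0
    first_target_duration_ms: float = 1000.0
    post_target_window_ms: float = 1400.0

    @property
    def second_target_onset_ms(self) -> float:
        return self.fixation_duration_ms + self.first_target_duration_ms

    @property
    def total_duration_ms(self) -> float:
        return self.second_target_onset_ms + self.post_target_window_ms


@dataclass(frozen=True)
class GroupLatencyModel:
    """Between-/within-subject latency structure for one group.

    ``*_between_sd`` is the SD of subject task means across the group;
    ``within_sd`` the trial-to-trial SD around a subject mean;
    ``cross_task_corr`` the correlation of a subject's color and Landolt
    means, which controls the spread of within-subject task differences.
    """

    color_mean_ms: float
    color_between_sd_ms: float
    landolt_mean_ms: float
    landolt_between_sd_ms: float
    within_sd_ms: float = 50.0
    cross_task_corr: float = 0.0

    def __post_init__(self) -> None:
        for sd in (self.color_between_sd_ms, self.landolt_between_sd_ms, self.within_sd_ms):
            if sd < 0:
                raise ValueError("latency SDs must be non-negative")
        if not -1.0 <= self.cross_task_corr <= 1.0:
            raise ValueError("cross_task_corr must lie in [-1, 1]")

    def mean(self, task: str) -> float:
        return self.color_mean_ms if task == "color" else self.landolt_mean_ms


@dataclass(frozen=True)
class GroupBehaviorModel:
    """Button-response model: per-task accuracy and response-time structure."""

    color_rt_mean_ms: float = 850.0
    landolt_rt_mean_ms: float = 950.0
    rt_between_sd_ms: float = 150.0
    rt_within_sd_ms: float = 250.0
    color_accuracy: float = 0.97
    landolt_accuracy: float = 0.95


# Study-condition defaults.  Means and between-subject SDs are the printed
# group statistics; cross-task correlations are calibrated so that the
# within-group paired contrasts have the dispersion implied by the printed
# paired test statistics (see docs/methods.md).
DEFAULT_LATENCY_MODELS: Mapping[str, GroupLatencyModel] = MappingProxyType({
    "patient": GroupLatencyModel(248.0, 56.0, 232.0, 51.0, 50.0, 0.88),
    "control": GroupLatencyModel(261.0, 100.0, 193.0, 27.0, 50.0, 0.05),
    "relative": GroupLatencyModel(221.0, 49.0, 178.0, 30.0, 50.0, 0.63),
})

# Qualitative behavioral structure: patients slower overall, the Landolt
# task slower for everyone and disproportionately for patients, accuracy
# around 95% and slightly lower in the Landolt task.
DEFAULT_BEHAVIOR_MODELS: Mapping[str, GroupBehaviorModel] = MappingProxyType({
    "patient": GroupBehaviorModel(1000.0, 1280.0, 150.0, 250.0, 0.97, 0.92),
    "control": GroupBehaviorModel(850.0, 952.0, 150.0, 250.0, 0.97, 0.95),
    "relative": GroupBehaviorModel(850.0, 952.0, 150.0, 250.0, 0.97, 0.93),
})

DEFAULT_GROUP_SIZES: Mapping[str, int] = MappingProxyType(
    {"patient": 13, "control": 24, "relative": 10}
)


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a simulated cohort.

    Defaults reproduce the study conditions: 13 patients, 24 controls and
    10 first-degree relatives; 96 trials in 3 balanced blocks of 32; 200 Hz
    sampling; 0.3 deg position noise (consistent with a tracker resolution
    of 0.5-1 deg); latency distributions per ``DEFAULT_LATENCY_MODELS``.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    latency_models: Mapping[str, GroupLatencyModel] = field(
        default_factory=lambda: dict(DEFAULT_LATENCY_MODELS))
    behavior_models: Mapping[str, GroupBehaviorModel] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_MODELS))
    noise_sd_deg: float = 0.3
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    n_trials: int = 96
    n_blocks: int = 3
    latency_floor_ms: float = LATENCY_FLOOR_MS
    latency_family: str = "gaussian"  # or "exgaussian"
    exgauss_tau_ms: float = 60.0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    main_sequence: MainSequenceParams = field(default_factory=MainSequenceParams)
    timing: TrialTiming = field(default_factory=TrialTiming)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks <= 0 or self.n_trials <= 0:
            raise ValueError("n_trials and n_blocks must be positive")
        if self.n_trials % self.n_blocks:
            raise ValueError("n_trials must be divisible by n_blocks")
        if (self.n_trials // self.n_blocks) % (len(TASKS) * len(SIDES)):
            raise ValueError(
                "trials per block must be divisible by 4 so task and side "
                "can be balanced within each block"
            )
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be non-negative")
        if self.latency_family not in ("gaussian", "exgaussian"):
            raise ValueError("latency_family must be 'gaussian' or 'exgaussian'")
        for g in self.group_sizes:
            if g not in self.latency_models:
                raise ValueError(f"no latency model for group {g!r}")

    @property
    def trials_per_block(self) -> int:
        return self.n_trials // self.n_blocks


@dataclass(frozen=True)
class SubjectParams:
    """Latent per-subject parameters (the simulation's ground truth)."""

    subject_id: str
    group: str
    latency_mean_ms: Mapping[str, float]
    within_sd_ms: float
    rt_mean_ms: Mapping[str, float]
    rt_within_sd_ms: float
    accuracy: Mapping[str, float]


@dataclass(frozen=True)
class TrialEvent:
    """One trial's design cell, stimulus timing and button response."""

    subject_id: str
    trial_index: int
    block: int
    task: str
    side: str
    first_target_onset_ms: float
    second_target_onset_ms: float
    response_yes: bool
    correct: bool
    response_time_ms: float


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one trial: what the detector should recover."""

    subject_id: str
    group: str
    trial_index: int
    task: str
    side: str
    true_latency_ms: float
    true_saccade_onset_ms: float
    true_amplitude_deg: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and self.true_latency_ms <= 0:
            raise ValueError("true_latency_ms must be positive")


def simulate_saccade_segment(
    amplitude_deg: float,
    params: MainSequenceParams | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
):
    """Sample a single saccade's position and velocity on a uniform grid.

    Returns ``(time_ms, position_deg, velocity_deg_s)`` relative to
    movement onset.  Position runs monotonically from 0 to ``amplitude_deg``
    following the raised-cosine velocity profile

        v(t) = (2A/D) * (1 - cos(2 pi t / D)) / 2,   0 <= t <= D,

    whose time integral is exactly A.  ``amplitude_deg`` is unsigned;
    direction is applied by the caller.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if amplitude_deg < 0:
        raise ValueError("amplitude_deg must be non-negative")
    params = params or MainSequenceParams()
    duration = params.duration_ms(amplitude_deg)
    n = int(math.floor(duration * sampling_rate / 1000.0)) + 1
    t = np.arange(n) * (1000.0 / sampling_rate)
    if amplitude_deg == 0:
        return t, np.zeros(n), np.zeros(n)
    phase = 2.0 * math.pi * t / duration
    pos = amplitude_deg * (t / duration - np.sin(phase) / (2.0 * math.pi))
    vel = 1000.0 * (amplitude_deg / duration) * (1.0 - np.cos(phase))
    return t, pos, vel


def saccade_position(t_ms, onset_ms: float, amplitude_signed_deg: float,
                     duration_ms: float):
    """Closed-form displacement of a raised-cosine saccade at times ``t_ms``."""
    s = np.clip((np.asarray(t_ms, dtype=float) - onset_ms) / duration_ms, 0.0, 1.0)
    return amplitude_signed_deg * (s - np.sin(2.0 * math.pi * s) / (2.0 * math.pi))


def _draw_truncated(rng, mean, sd, floor, max_retries=1000):
    """Floor-truncated Gaussian by rejection; (value, degenerate) pair."""
    if sd == 0:
        return max(mean, floor), mean < floor
    for _ in range(max_retries):
        x = rng.normal(mean, sd)
        if x >= floor:
            return x, False
    return floor, True


def _draw_latency(rng, mean, sd, floor, family="gaussian", tau=60.0):
    if family == "exgaussian":
        mu = mean - tau
        for _ in range(1000):
            x = rng.normal(mu, sd) + rng.exponential(tau)
            if x >= floor:
                return x, False
        return floor, True
    return _draw_truncated(rng, mean, sd, floor)


def simulate_trial(
    subject: SubjectParams,
    task: str,
    side: str,
    *,
    geometry: GeometryConfig | None = None,
    main_sequence: MainSequenceParams | None = None,
    timing: TrialTiming | None = None,
    noise_sd_deg: float = 0.3,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
    latency_floor_ms: float = LATENCY_FLOOR_MS,
    latency_family: str = "gaussian",
    exgauss_tau_ms: float = 60.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    trial_index: int = 0,
    block: int = 0,
) -> tuple[GazeTrace, TrialEvent, TruthRecord]:
    """Simulate one trial: trace, trial events and the ground truth.

    The gaze sits at 0 deg through fixation and the first target, then,
    a drawn latency after second-target onset, executes a main-sequence
    saccade to +/- the target eccentricity and fixates there.  Gaussian
    position noise of ``noise_sd_deg`` is added to every sample of both
    channels.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    geometry = geometry or GeometryConfig()
    main_sequence = main_sequence or MainSequenceParams()
    timing = timing or TrialTiming()
    if rng is None:
        rng = np.random.default_rng(seed)

    latency, degenerate = _draw_latency(
        rng, subject.latency_mean_ms[task], subject.within_sd_ms,
        latency_floor_ms, latency_family, exgauss_tau_ms,
    )
    t2 = timing.second_target_onset_ms
    onset = t2 + latency
    amplitude = geometry.target_eccentricity_deg
    signed_amp = amplitude if side == "right" else -amplitude
    duration = main_sequence.duration_ms(amplitude)

    dt = 1000.0 / sampling_rate
    n = int(round(timing.total_duration_ms / dt)) + 1
    times = np.arange(n) * dt
    x = saccade_position(times, onset, signed_amp, duration)
    y = np.zeros(n)
    if noise_sd_deg > 0:
        x = x + rng.normal(0.0, noise_sd_deg, n)
        y = y + rng.normal(0.0, noise_sd_deg, n)

    trace = GazeTrace(times, x, y, sampling_rate,
                      subject_id=subject.subject_id, trial_index=trial_index)

    correct = bool(rng.random() < subject.accuracy[task])
    match = bool(rng.random() < 0.5)
    rt, _ = _draw_truncated(rng, subject.rt_mean_ms[task],
                            subject.rt_within_sd_ms, 300.0)
    event = TrialEvent(
        subject_id=subject.subject_id, trial_index=trial_index, block=block,
        task=task, side=side,
        first_target_onset_ms=timing.fixation_duration_ms,
        second_target_onset_ms=t2,
        response_yes=match if correct else not match,
        correct=correct, response_time_ms=rt,
    )
    truth = TruthRecord(
        subject_id=subject.subject_id, group=subject.group,
        trial_index=trial_index, task=task, side=side,
        true_latency_ms=latency, true_saccade_onset_ms=onset,
        true_amplitude_deg=signed_amp, degenerate=degenerate,
    )
    return trace, event, truth


def _draw_subject(rng, subject_id: str, group: str, cfg: CohortConfig) -> SubjectParams:
    lm = cfg.latency_models[group]
    bm = cfg.behavior_models.get(group, GroupBehaviorModel())
    cov = lm.cross_task_corr * lm.color_between_sd_ms * lm.landolt_between_sd_ms
    sigma = np.array([
        [lm.color_between_sd_ms ** 2, cov],
        [cov, lm.landolt_between_sd_ms ** 2],
    ])
    mu = np.array([lm.color_mean_ms, lm.landolt_mean_ms])
    for _ in range(1000):
        means = rng.multivariate_normal(mu, sigma)
        if np.all(means >= cfg.latency_floor_ms):
            break
    else:
        means = np.maximum(mu, cfg.latency_floor_ms)
    rt_color, _ = _draw_truncated(rng, bm.color_rt_mean_ms, bm.rt_between_sd_ms, 300.0)
    rt_shift = rt_color - bm.color_rt_mean_ms
    return SubjectParams(
        subject_id=subject_id, group=group,
        latency_mean_ms={"color": float(means[0]), "landolt": float(means[1])},
        within_sd_ms=lm.within_sd_ms,
        rt_mean_ms={"color": rt_color, "landolt": bm.landolt_rt_mean_ms + rt_shift},
        rt_within_sd_ms=bm.rt_within_sd_ms,
        accuracy={"color": bm.color_accuracy, "landolt": bm.landolt_accuracy},
    )


def _block_schedule(rng, trials_per_block: int) -> list[tuple[str, str]]:
    """Balanced random order: each task x side cell appears equally often."""
    cells = [(t, s) for t in TASKS for s in SIDES]
    reps = trials_per_block // len(cells)
    schedule = cells * reps
    order = rng.permutation(len(schedule))
    return [schedule[i] for i in order]


@dataclass
class SubjectData:
    params: SubjectParams
    traces: list[GazeTrace]
    events: list[TrialEvent]
    truths: list[TruthRecord]


@dataclass
class CohortDataset:
    """A simulated cohort: per-subject traces, trial events and truth."""

    config: CohortConfig
    subjects: list[SubjectData]

    def truth_table(self) -> pd.DataFrame:
        rows = [vars(t) for s in self.subjects for t in s.truths]
        return pd.DataFrame(rows)

    def event_table(self) -> pd.DataFrame:
        rows = [vars(e) for s in self.subjects for e in s.events]
        return pd.DataFrame(rows)

    def latency_table(self) -> pd.DataFrame:
        """True latencies in the shape of the detector's output table."""
        df = self.truth_table()
        df = df.rename(columns={"true_latency_ms": "latency_ms"})
        df["valid"] = ~df["degenerate"]
        df["reason"] = np.where(df["valid"], "", "degenerate")
        return df[["subject_id", "group", "task", "side", "trial_index",
                   "latency_ms", "valid", "reason"]]

    def behavior_table(self) -> pd.DataFrame:
        ev = self.event_table()
        groups = {s.params.subject_id: s.params.group for s in self.subjects}
        ev["group"] = ev["subject_id"].map(groups)
        return ev


def simulate_cohort(config: CohortConfig | None = None, *,
                    include_traces: bool = True) -> CohortDataset:
    """Simulate a full cohort under ``config``.

    Per subject, latent task means are drawn from the group-level
    distributions, the block schedule is balanced and shuffled, and every
    trial is synthesised.  With ``include_traces=False`` the gaze traces
    are skipped (events and ground truth only), which is orders of
    magnitude faster and sufficient for statistics that consume latencies
    directly.  Identical config and seed give identical datasets.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    prefix = {"patient": "P", "control": "C", "relative": "R"}
    subjects: list[SubjectData] = []
    active_groups = []
    for group, size in config.group_sizes.items():
        if size == 0:
            warnings.warn(f"group {group!r} has size 0 and is omitted", stacklevel=2)
            continue
        active_groups.append((group, size))
    seeds = root.spawn(sum(n for _, n in active_groups))
    k = 0
    for group, size in active_groups:
        for i in range(size):
            rng = np.random.default_rng(seeds[k]); k += 1
            sid = f"{prefix.get(group, group[:1].upper())}{i + 1:02d}"
            params = _draw_subject(rng, sid, group, config)
            traces: list[GazeTrace] = []
            events: list[TrialEvent] = []
            truths: list[TruthRecord] = []
            idx = 0
            for block in range(config.n_blocks):
                for task, side in _block_schedule(rng, config.trials_per_block):
                    if include_traces:
                        trace, event, truth = simulate_trial(
                            params, task, side,
                            geometry=config.geometry,
                            main_sequence=config.main_sequence,
                            timing=config.timing,
                            noise_sd_deg=config.noise_sd_deg,
                            sampling_rate=config.sampling_rate,
                            latency_floor_ms=config.latency_floor_ms,
                            latency_family=config.latency_family,
                            exgauss_tau_ms=config.exgauss_tau_ms,
                            rng=rng, trial_index=idx, block=block,
                        )
                        traces.append(trace)
                    else:
                        trace, event, truth = _simulate_trial_fast(
                            params, task, side, config, rng, idx, block)
                    events.append(event)
                    truths.append(truth)
                    idx += 1
            subjects.append(SubjectData(params, traces, events, truths))
    return CohortDataset(config=config, subjects=subjects)


def _simulate_trial_fast(params, task, side, cfg, rng, idx, block):
    """Trial events and truth without synthesising the trace.

    Draws the same quantities as ``simulate_trial`` in the same order from
    the subject's stream, minus the per-sample position noise.
    """
    latency, degenerate = _draw_latency(
        rng, params.latency_mean_ms[task], params.within_sd_ms,
        cfg.latency_floor_ms, cfg.latency_family, cfg.exgauss_tau_ms)
    t2 = cfg.timing.second_target_onset_ms
    amp = cfg.geometry.target_eccentricity_deg
    correct = bool(rng.random() < params.accuracy[task])
    match = bool(rng.random() < 0.5)
    rt, _ = _draw_truncated(rng, params.rt_mean_ms[task], params.rt_within_sd_ms, 300.0)
    event = TrialEvent(
        subject_id=params.subject_id, trial_index=idx, block=block,
        task=task, side=side,
        first_target_onset_ms=cfg.timing.fixation_duration_ms,
        second_target_onset_ms=t2,
        response_yes=match if correct else not match,
        correct=correct, response_time_ms=rt)
    truth = TruthRecord(
        subject_id=params.subject_id, group=params.group, trial_index=idx,
        task=task, side=side, true_latency_ms=latency,
        true_saccade_onset_ms=t2 + latency,
        true_amplitude_deg=amp if side == "right" else -amp,
        degenerate=degenerate)
    return None, event, truth


def simulate_latency_table(config: CohortConfig | None = None) -> pd.DataFrame:
    """Latency table straight from the latency model (no trace synthesis).

    Equivalent to running the detector on a simulated cohort up to the
    detector's ~1-sample quantisation; used for statistics-level replication
    studies where synthesising millions of samples would add nothing.
    """
    return simulate_cohort(config, include_traces=False).latency_table()
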