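"""Gaze-signal preprocessing: visual-angle transform, artifact masking,
smoothing and velocity estimation.

The pipeline that feeds the saccade detector is, in order:

1. transform raw screen offsets to visual angles (``to_visual_angle``),
2. mask physiologically implausible velocity samples, i.e. anything faster
   than ``ARTIFACT_CEILING_DEG_S`` = 750 deg/s (``artifact_filter``) — human
   saccadic peak velocities saturate well below that, so faster samples are
   tracker artifacts such as blinks or reflection losses,
3. smooth eye position with a 20 ms centered moving average (``smooth``),
4. differentiate the smoothed horizontal position into a speed signal
   (``velocity``).

Masking is computed on the *raw* velocity, before smoothing, so that a
blink spike cannot leak into its neighbours through the averaging window.
``preprocess_trace`` composes the four steps and logs the order so the
processing chain can be audited.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Sampling rate of the video-oculography system (Hz).
DEFAULT_SAMPLING_RATE_HZ = 200.0
#: Velocity ceiling above which samples are treated as artifacts (deg/s).
ARTIFACT_CEILING_DEG_S = 750.0
#: Moving-average window for position smoothing (ms).
SMOOTHING_WINDOW_MS = 20.0
#: Extra samples masked on each side of an artifact sample.
ARTIFACT_GUARD_SAMPLES = 2


@dataclass
class GazeTrace:
    """Uniformly sampled horizontal/vertical eye position in degrees.

    Parameters
    ----------
    time_ms : ndarray
        Sample times in milliseconds on a strictly increasing uniform grid
        with spacing ``1000 / sampling_rate``.
    x_deg, y_deg : ndarray
        Horizontal and vertical gaze position in degrees of visual angle.
        Positive x is rightward.
    sampling_rate : float
        Sampling rate in Hz.
    """

    time_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    subject_id: str = ""
    trial_index: int = -1

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        if not (len(self.time_ms) == len(self.x_deg) == len(self.y_deg)):
            raise ValueError("time, x and y must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.time_ms) >= 2:
            dt = np.diff(self.time_ms)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            expected = 1000.0 / self.sampling_rate
            if not np.allclose(dt, expected, rtol=1e-6, atol=1e-6):
                raise ValueError(
                    "sample times must be uniform with spacing "
                    f"{expected:.6g} ms (1000/sampling_rate)"
                )

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate


@dataclass
class VelocityTrace:
    """Eye speed (deg/s) with an artifact mask.

    ``speed`` is non-negative; ``velocity`` keeps the sign (positive =
    rightward).  ``mask`` flags artifact samples that the detector must not
    use.  ``position`` carries the (smoothed) horizontal position so that
    saccade amplitudes can be read off event boundaries.
    """

    time_ms: np.ndarray
    speed: np.ndarray
    velocity: np.ndarray
    mask: np.ndarray
    position: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    subject_id: str = ""
    trial_index: int = -1

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.time_ms)


def to_visual_angle(offset_cm, viewing_distance_cm: float):
    """Convert an on-screen offset (cm) to a visual angle (degrees).

    angle = degrees(arctan(offset / viewing_distance)); odd in the offset,
    so left/right symmetry is preserved.
    """
    if viewing_distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    return np.degrees(np.arctan(np.asarray(offset_cm, dtype=float) / viewing_distance_cm))


def _moving_average(values: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average over ``n`` samples with shrinking edge windows.

    For even ``n`` the window takes one extra sample on the future side
    (centroid half a sample early, which offsets the half-sample lag of the
    backward-extended onset convention downstream).  Each
    output is a plain mean of in-range samples, so the output never exceeds
    the input's range.
    """
    m = len(values)
    left = (n - 1) // 2
    right = n - left - 1
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(m)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, m - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def smooth(trace: GazeTrace, window_ms: float = SMOOTHING_WINDOW_MS) -> GazeTrace:
    """Smooth eye position with a centered moving average.

    A 20 ms window at 200 Hz spans 4 samples.  Windows shrink near the trace
    edges instead of trimming samples, so no data around target onset is
    lost.  A window shorter than one sample period returns the trace
    unchanged with a warning.
    """
    n = int(round(window_ms / trace.dt_ms))
    if n <= 1:
        if window_ms < trace.dt_ms:
            warnings.warn(
                "smoothing window shorter than one sample period; returning "
                "the trace unchanged",
                stacklevel=2,
            )
        return replace(trace, x_deg=trace.x_deg.copy(), y_deg=trace.y_deg.copy())
    return replace(
        trace,
        x_deg=_moving_average(trace.x_deg, n),
        y_deg=_moving_average(trace.y_deg, n),
    )


def smoothing_span_samples(window_ms: float, sampling_rate: float) -> int:
    """Number of samples covered by a smoothing window at a sampling rate."""
    return int(round(window_ms * sampling_rate / 1000.0))


def velocity(trace: GazeTrace) -> VelocityTrace:
    """Horizontal eye velocity (deg/s) from central differences.

    Interior samples use the symmetric two-sample difference; the endpoints
    fall back to one-sided differences.  Only the horizontal channel is
    differentiated: the targets sit on the horizontal meridian and latency
    is defined on horizontal gaze shifts.
    """
    if len(trace) < 3:
        raise ValueError("velocity needs at least 3 samples")
    dt_s = trace.dt_ms / 1000.0
    x = trace.x_deg
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt_s)
    v[0] = (x[1] - x[0]) / dt_s
    v[-1] = (x[-1] - x[-2]) / dt_s
    return VelocityTrace(
        time_ms=trace.time_ms,
        speed=np.abs(v),
        velocity=v,
        mask=np.zeros(len(x), dtype=bool),
        position=x,
        sampling_rate=trace.sampling_rate,
        subject_id=trace.subject_id,
        trial_index=trace.trial_index,
    )


def artifact_filter(
    vel: VelocityTrace,
    ceiling_deg_s: float = ARTIFACT_CEILING_DEG_S,
    guard_samples: int = ARTIFACT_GUARD_SAMPLES,
) -> VelocityTrace:
    """Mask velocity samples above a physiological-plausibility ceiling.

    Samples faster than ``ceiling_deg_s`` (default 750 deg/s, beyond human
    saccadic peak velocities) are flagged as artifacts, together with
    ``guard_samples`` neighbours on each side.  The mask propagates to
    saccade detection, which drops events overlapping masked samples.
    """
    if ceiling_deg_s <= 0:
        raise ValueError("ceiling must be positive")
    hot = vel.speed > ceiling_deg_s
    mask = hot.copy()
    for shift in range(1, guard_samples + 1):
        mask[:-shift] |= hot[shift:]
        mask[shift:] |= hot[:-shift]
    return replace(vel, mask=vel.mask | mask)


def preprocess_trace(
    trace: GazeTrace,
    *,
    ceiling_deg_s: float = ARTIFACT_CEILING_DEG_S,
    window_ms: float = SMOOTHING_WINDOW_MS,
    guard_samples: int = ARTIFACT_GUARD_SAMPLES,
) -> VelocityTrace:
    """Run the fixed preprocessing chain on a trace already in degrees.

    Order: artifact masking on raw velocity -> position smoothing ->
    velocity of the smoothed positions, carrying the artifact mask forward.
    """
    logger.debug(
        "preprocess %s/%d: artifact mask (> %g deg/s, guard %d) -> smooth "
        "(%g ms) -> velocity",
        trace.subject_id, trace.trial_index, ceiling_deg_s, guard_samples, window_ms,
    )
    raw_vel = velocity(trace)
    masked = artifact_filter(raw_vel, ceiling_deg_s, guard_samples)
    vel = velocity(smooth(trace, window_ms))
    vel.mask = masked.mask
    return vel
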