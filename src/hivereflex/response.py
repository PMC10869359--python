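"""Pulse-aligned window extraction and the per-pulse response metrics.

Three scalars summarize the colony's reaction to each beep:

* ``pulse_magnitude`` — RMS of the raw signal over the pulse span, i.e. how
  much vibration actually reached the honeycomb;
* ``positive_response`` — mean rectified-and-smoothed envelope over the 4 s
  after the pulse minus the mean over the 1 s before it (positive when the
  bees buzz louder: the collective buzzing response);
* ``negative_response`` — mean pre-pulse envelope minus the mean envelope
  over the first 0.25 s after the pulse (positive when the signal drops:
  the brief immobilization/freezing response).

Both response metrics operate on the rectified signal smoothed with a
4.5 ms moving average; the signed signal itself has mean ~0 and carries no
envelope information.  The pulse span itself is excluded from both the pre
and post windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stimulus import StimulusSchedule

__all__ = [
    "AccelTrace",
    "PulseWindow",
    "ResponseMetrics",
    "extract_windows",
    "envelope",
    "pulse_magnitude",
    "positive_response",
    "negative_response",
    "compute_metrics",
]

logger = logging.getLogger(__name__)

#: Default moving-average smoothing window for envelopes, s.
SMOOTH_WINDOW = 0.0045
#: Span of the early post-pulse window used by negative_response, s.
EARLY_WINDOW = 0.25


@dataclass(frozen=True)
class AccelTrace:
    """A uniformly sampled single-channel acceleration time series."""

    samples: np.ndarray
    sample_rate: float
    start_epoch: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("AccelTrace requires a single-channel 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AccelTrace samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def end_epoch(self) -> float:
        return self.start_epoch + self.duration

    def times(self) -> np.ndarray:
        return self.start_epoch + np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class PulseWindow:
    """Raw signal segments around one pulse.

    ``pre`` covers the second before pulse onset, ``pulse`` the stimulus
    span, ``post`` the four seconds after the pulse end.  The segments are
    contiguous slices of the parent trace, so concatenating them reproduces
    the original samples over that span exactly.
    """

    pre: np.ndarray
    pulse: np.ndarray
    post: np.ndarray
    pulse_epoch: float
    sample_rate: float


@dataclass(frozen=True)
class ResponseMetrics:
    pulse_epoch: float
    pulse_magnitude: float
    positive_response: float
    negative_response: float


def extract_windows(
    trace: AccelTrace,
    schedule: "StimulusSchedule | Sequence[float]",
    pre: float = 1.0,
    post: float = 4.0,
    pulse_duration: float = 0.1,
) -> list[PulseWindow]:
    """Cut sample-exact pulse-aligned windows out of a trace.

    Window index 0 of ``pre`` is exactly ``pre`` seconds before pulse
    onset.  Pulses whose windows would run off either end of the trace are
    skipped with a logged warning.
    """
    if pre <= 0 or post <= 0 or pulse_duration <= 0:
        raise ValueError("pre, post and pulse_duration must be positive")
    times = schedule.times if isinstance(schedule, StimulusSchedule) else np.asarray(schedule, float)
    fs = trace.sample_rate
    n_pre = int(round(pre * fs))
    n_pulse = int(round(pulse_duration * fs))
    n_post = int(round(post * fs))
    x = trace.samples
    windows: list[PulseWindow] = []
    for t in np.atleast_1d(times):
        onset = int(round((t - trace.start_epoch) * fs))
        lo = onset - n_pre
        hi = onset + n_pulse + n_post
        if lo < 0 or hi > x.size:
            logger.warning(
                "pulse at epoch %.3f skipped: window [%d, %d) outside trace of %d samples",
                t, lo, hi, x.size,
            )
            continue
        windows.append(
            PulseWindow(
                pre=x[lo:onset],
                pulse=x[onset : onset + n_pulse],
                post=x[onset + n_pulse : hi],
                pulse_epoch=float(t),
                sample_rate=fs,
            )
        )
    if not windows:
        logger.warning("no pulses of the schedule fall inside the trace")
    return windows


def envelope(segment: np.ndarray, sample_rate: float, window: float = SMOOTH_WINDOW) -> np.ndarray:
    """Rectified, moving-average-smoothed amplitude envelope.

    The absolute value of the signal is averaged over a centred window of
    ``window`` seconds; at the edges the window shrinks symmetrically down
    to a single sample, so there is no zero-padding bias and the output has
    the same length as the input.  Homogeneous of degree 1:
    ``envelope(a*x) == a*envelope(x)`` for ``a >= 0``.
    """
    x = np.abs(np.asarray(segment, dtype=float))
    n_win = int(round(window * sample_rate))
    if n_win < 2:
        raise ValueError(
            f"smoothing window {window} s is shorter than two sample periods "
            f"at {sample_rate} Hz"
        )
    half = n_win // 2
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def pulse_magnitude(window: PulseWindow) -> float:
    """RMS of the raw signal over the pulse segment."""
    if window.pulse.size == 0:
        raise ValueError("empty pulse segment")
    return float(np.sqrt(np.mean(window.pulse**2)))


def positive_response(window: PulseWindow, smooth: float = SMOOTH_WINDOW) -> float:
    """Buzzing response: mean post-pulse (4 s) minus pre-pulse (1 s) envelope."""
    post_env = envelope(window.post, window.sample_rate, smooth)
    pre_env = envelope(window.pre, window.sample_rate, smooth)
    return float(post_env.mean() - pre_env.mean())


def negative_response(
    window: PulseWindow,
    smooth: float = SMOOTH_WINDOW,
    early: float = EARLY_WINDOW,
) -> float:
    """Immobilization response: pre-pulse envelope minus the first 0.25 s post."""
    n_early = int(round(early * window.sample_rate))
    if n_early < 1 or n_early > window.post.size:
        raise ValueError("early window outside the post segment")
    post_env = envelope(window.post[:n_early], window.sample_rate, smooth)
    pre_env = envelope(window.pre, window.sample_rate, smooth)
    return float(pre_env.mean() - post_env.mean())


def compute_metrics(
    windows: Iterable[PulseWindow],
    smooth: float = SMOOTH_WINDOW,
    early: float = EARLY_WINDOW,
) -> pd.DataFrame:
    """Per-pulse metrics table with columns
    ``pulse_epoch, pulse_magnitude, positive_response, negative_response``."""
    rows = [
        {
            "pulse_epoch": w.pulse_epoch,
            "pulse_magnitude": pulse_magnitude(w),
            "positive_response": positive_response(w, smooth),
            "negative_response": negative_response(w, smooth, early),
        }
        for w in windows
    ]
    return pd.DataFrame(rows, columns=["pulse_epoch", "pulse_magnitude", "positive_response", "negative_response"])
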