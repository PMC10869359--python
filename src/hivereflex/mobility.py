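"""Bee mobility from grey-scale video by frame differencing.

The relative mobility of the bees on a comb is the per-frame mean of the
absolute grey-level difference between consecutive frames: it is zero
when nothing moves and, without absolute calibration, scales with how
much the bees move.  A vibrational pulse freezes the bees; the mobility
trace shows a trough immediately at the end of the pulse and recovers
exponentially (time constant ~1 s at the optimal 500 Hz drive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MobilityTrace",
    "RecoveryFit",
    "frame_mobility",
    "trough_depth",
    "fit_recovery",
    "frequency_effectiveness",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MobilityTrace:
    """Mean absolute frame-difference per consecutive frame pair.

    ``values[k]`` compares frames k and k+1 and is timestamped at the
    later frame: ``t_k = start_time + (k + 1)/frame_rate``.
    """

    values: np.ndarray
    frame_rate: float = 50.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if np.any(values < 0):
            raise ValueError("mobility values must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def times(self) -> np.ndarray:
        return self.start_time + (np.arange(self.values.size) + 1) / self.frame_rate


@dataclass(frozen=True)
class RecoveryFit:
    """Least-squares fit of M(t) = M0 - D*exp(-(t - pulse_end)/tau)."""

    baseline: float
    depth: float
    tau: float
    residual: float
    flagged: bool = False


def frame_mobility(
    stack: np.ndarray,
    frame_rate: float = 50.0,
    start_time: float = 0.0,
) -> MobilityTrace:
    """Mobility trace of a (n_frames, H, W) grey-scale stack.

    value_k = mean over pixels of \\|frame_{k+1} - frame_k\\|; zero iff the
    two frames are identical.  Adding a constant grey level to every frame
    leaves the trace unchanged.
    """
    frames = np.asarray(stack)
    if frames.ndim != 3:
        raise ValueError("stack must be 3-D (n_frames, height, width)")
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    diffs = np.abs(np.diff(frames.astype(np.float64), axis=0))
    return MobilityTrace(diffs.mean(axis=(1, 2)), frame_rate, start_time)


def trough_depth(
    mob: MobilityTrace,
    pulse_end: float,
    baseline_window: float = 1.0,
    pulse_onset: float | None = None,
) -> float:
    """Immobilization depth: baseline mobility minus the mobility at the
    first frame after the pulse end (where the freeze is deepest).

    Baseline is the mean over ``baseline_window`` seconds before
    ``pulse_onset`` (default: the pulse end itself).
    """
    if pulse_onset is None:
        pulse_onset = pulse_end
    t = mob.times()
    if not (t[0] <= pulse_end <= t[-1]):
        raise ValueError("pulse_end outside the mobility trace")
    base_mask = (t >= pulse_onset - baseline_window) & (t < pulse_onset)
    if not base_mask.any():
        raise ValueError("no baseline frames before the pulse")
    post = np.flatnonzero(t >= pulse_end)
    if post.size == 0:
        raise ValueError("no frames after the pulse end")
    return float(mob.values[base_mask].mean() - mob.values[post[0]])


def fit_recovery(
    mob: MobilityTrace,
    pulse_end: float,
    max_lag: float = 8.0,
    baseline_window: float = 1.0,
    pulse_onset: float | None = None,
) -> RecoveryFit:
    """Fit the exponential recovery M(t) = M0 - D*exp(-(t-pulse_end)/tau)
    to the post-pulse mobility values with t in (pulse_end, pulse_end+max_lag].

    Deterministic: initial guesses are M0 = pre-pulse baseline mean,
    D = trough estimate, tau = 0.5 s, with tau bounded to [0.02, 30] s.
    Non-convergence or an unidentifiable depth yields a flagged fit with
    infinite residual.
    """
    if pulse_onset is None:
        pulse_onset = pulse_end
    t = mob.times()
    mask = (t >= pulse_end) & (t <= pulse_end + max_lag)
    if mask.sum() < 10:
        raise ValueError("need at least 10 frames after pulse_end to fit")
    tt = t[mask] - pulse_end
    yy = mob.values[mask]

    base_mask = (t >= pulse_onset - baseline_window) & (t < pulse_onset)
    m0_init = float(yy[-max(yy.size // 10, 1):].mean()) if not base_mask.any() else float(
        mob.values[base_mask].mean()
    )
    d_init = max(m0_init - float(yy[0]), 1e-12)

    def model(x, m0, d, tau):
        return m0 - d * np.exp(-x / tau)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                tt,
                yy,
                p0=[m0_init, d_init, 0.5],
                bounds=([0.0, 0.0, 0.02], [np.inf, np.inf, 30.0]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError):
        return RecoveryFit(m0_init, d_init, np.nan, np.inf, flagged=True)
    m0, d, tau = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((model(tt, *popt) - yy) ** 2)))
    # D ~ 0 leaves tau unconstrained: flag rather than report an arbitrary tau
    scale = max(abs(m0), float(np.std(yy)), 1e-300)
    flagged = d < 1e-6 * scale
    return RecoveryFit(m0, d, tau, resid if not flagged else np.inf, flagged=flagged)


def frequency_effectiveness(
    mob: MobilityTrace,
    sweep_onsets: "list[tuple[float, float]] | np.ndarray",
    pulse_duration: float = 0.1,
    baseline_window: float = 1.0,
    recovery_tau_hint: float = 1.0,
    global_baseline: bool = True,
) -> dict[float, float]:
    """Immobilization depth per sweep pulse, keyed by carrier frequency.

    ``sweep_onsets`` is a sequence of (frequency_hz, onset_s) pairs in the
    mobility trace's time base.  Depth is the baseline mobility minus the
    mobility value at the first frame after each pulse's end.  Because
    sweep pulses are spaced shorter than the recovery time constant, each
    pulse's immediate pre-window still rides on the previous recovery; by
    default the baseline is therefore measured once, in the
    ``baseline_window`` seconds before the *first* pulse, and a warning is
    logged about the overlap.  Set ``global_baseline=False`` to use a
    per-pulse pre-window instead (appropriate for well-separated pulses).
    """
    pairs = [(float(f), float(o)) for f, o in sweep_onsets]
    onsets = np.array([o for _, o in pairs])
    if onsets.size > 1:
        spacing = float(np.min(np.diff(np.sort(onsets))))
        if spacing < 2.0 * recovery_tau_hint:
            logger.warning(
                "inter-pulse spacing %.2f s < 2x recovery tau %.2f s: "
                "recovery windows overlap", spacing, recovery_tau_hint,
            )
    t = mob.times()
    curve: dict[float, float] = {}
    if global_baseline:
        first = onsets.min()
        window = min(baseline_window, max(first - t[0], 0.02))
        base_mask = (t >= first - window) & (t < first)
        if not base_mask.any():
            raise ValueError("no baseline frames before the first sweep pulse")
        base = float(mob.values[base_mask].mean())
        for f, onset in pairs:
            post = np.flatnonzero(t >= onset + pulse_duration)
            if post.size == 0:
                logger.warning("pulse at %.2f s beyond trace end: skipped", onset)
                continue
            curve[f] = base - float(mob.values[post[0]])
        return curve
    for f, onset in pairs:
        window = min(baseline_window, max(onset - t[0], 0.1))
        try:
            curve[f] = trough_depth(
                mob, onset + pulse_duration,
                baseline_window=window, pulse_onset=onset,
            )
        except ValueError:
            logger.warning("pulse at %.2f s too close to trace edges: skipped", onset)
    return curve
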