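"""Synthesis of the artificial "beep" stimulus and its firing schedule.

The stimulus used throughout the assay is a short monochromatic tone burst:
a pure sinusoid shaped by a Gaussian amplitude envelope with a 30 ms full
width at half maximum, centred in a 0.1 s window, with the carrier at
340 Hz by default.  Stimuli are fired roughly hourly, at times jittered
around a nominal grid by Gaussian offsets (SD 15 min) so the colony cannot
habituate to a periodic knock.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSpec",
    "StimulusSchedule",
    "SweepPulse",
    "make_beep",
    "make_schedule",
    "make_sweep",
    "GAUSSIAN_FWHM_TO_SIGMA",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma.
GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one beep pulse.

    Attributes
    ----------
    center_freq:
        Carrier frequency in Hz.
    envelope_fwhm:
        Full width at half maximum of the Gaussian amplitude envelope, s.
    total_duration:
        Total support of the sampled waveform, s.  The envelope is centred
        in this window and its tails are truncated at the window edges, so
        a 0.1 s pulse and a 30 ms FWHM hold simultaneously.
    amplitude:
        Peak absolute value of the waveform (dimensionless drive units).
    sample_rate:
        Sampling rate in Hz.  Must satisfy Nyquist for the carrier.
    """

    center_freq: float = 340.0
    envelope_fwhm: float = 0.030
    total_duration: float = 0.100
    amplitude: float = 1.0
    sample_rate: float = 8000.0

    def __post_init__(self) -> None:
        if not self.center_freq > 0:
            raise ValueError(f"center_freq must be positive, got {self.center_freq}")
        if not self.envelope_fwhm > 0:
            raise ValueError(f"envelope_fwhm must be positive, got {self.envelope_fwhm}")
        if self.total_duration < self.envelope_fwhm:
            raise ValueError(
                "total_duration must be at least envelope_fwhm "
                f"({self.total_duration} < {self.envelope_fwhm})"
            )
        if not self.sample_rate > 2.0 * self.center_freq:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz violates Nyquist for a "
                f"{self.center_freq} Hz carrier (needs > {2 * self.center_freq} Hz)"
            )
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sample_rate))

    def replace(self, **changes) -> "StimulusSpec":
        return dataclasses.replace(self, **changes)


def make_beep(spec: StimulusSpec) -> np.ndarray:
    """Synthesize one beep pulse.

    Returns ``spec.n_samples`` samples of a sinusoid of frequency
    ``spec.center_freq`` multiplied by a Gaussian envelope of FWHM
    ``spec.envelope_fwhm`` centred mid-window.  The carrier phase is fixed
    to ``cos(2*pi*f*(t - t_c))`` (crest at the envelope centre), which
    makes the waveform exactly even-symmetric about its centre sample and
    puts the peak absolute value — rescaled to ``spec.amplitude`` — at the
    centre itself.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate
    # centre on an exact sample so the peak sits at a well-defined index
    t_c = (n // 2) / spec.sample_rate
    sigma = spec.envelope_fwhm * GAUSSIAN_FWHM_TO_SIGMA
    env = np.exp(-0.5 * ((t - t_c) / sigma) ** 2)
    wave = env * np.cos(2.0 * np.pi * spec.center_freq * (t - t_c))
    peak = np.abs(wave).max()
    if spec.amplitude == 0.0 or peak == 0.0:
        return np.zeros(n)
    return wave * (spec.amplitude / peak)


@dataclass(frozen=True)
class StimulusSchedule:
    """Randomized firing times of the stimulus.

    ``times`` are absolute epoch seconds (UTC); ``nominal`` the underlying
    periodic grid.  Offsets ``times - nominal`` are the Gaussian jitter.
    """

    times: np.ndarray
    nominal: np.ndarray
    mean_interval: float = 3600.0
    jitter_sd: float = 900.0
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        nominal = np.asarray(self.nominal, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "nominal", nominal)
        if times.shape != nominal.shape:
            raise ValueError("times and nominal must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("schedule times must be strictly increasing")

    @property
    def offsets(self) -> np.ndarray:
        return self.times - self.nominal

    def __len__(self) -> int:
        return int(self.times.size)


def make_schedule(
    start: float,
    end: float,
    mean_interval: float = 3600.0,
    jitter_sd: float = 900.0,
    seed: int | None = None,
    max_redraws: int = 100,
) -> StimulusSchedule:
    """Draw a randomized stimulation schedule on ``[start, end]``.

    Nominal firing times sit on a periodic grid ``start + k*mean_interval``
    (k >= 1); each actual time adds an independent Gaussian offset of
    standard deviation ``jitter_sd``.  A draw that would break strict
    monotonicity is re-drawn up to ``max_redraws`` times, after which the
    jitter is deemed too large for the interval and the call fails.
    """
    if not end > start:
        raise ValueError("end must be greater than start")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if mean_interval <= 0:
        raise ValueError("mean_interval must be positive")
    n = int(np.floor((end - start) / mean_interval))
    nominal = start + mean_interval * np.arange(1, n + 1)
    rng = np.random.default_rng(seed)
    if jitter_sd == 0.0:
        return StimulusSchedule(nominal.copy(), nominal, mean_interval, jitter_sd, seed)
    times = np.empty(n)
    prev = -np.inf
    for k in range(n):
        for attempt in range(max_redraws + 1):
            t = nominal[k] + rng.normal(0.0, jitter_sd)
            if t > prev:
                break
        else:
            raise ValueError(
                f"jitter_sd={jitter_sd} too large relative to "
                f"mean_interval={mean_interval}: could not keep times "
                f"strictly increasing after {max_redraws} re-draws"
            )
        times[k] = t
        prev = t
    return StimulusSchedule(times, nominal, mean_interval, jitter_sd, seed)


@dataclass(frozen=True)
class SweepPulse:
    """One pulse of a frequency sweep: (carrier frequency, waveform, onset)."""

    freq: float
    waveform: np.ndarray
    onset: float


def make_sweep(
    freq_start: float,
    freq_end: float,
    step: float,
    inter_pulse: float,
    spec: StimulusSpec,
) -> list[SweepPulse]:
    """Build a succession of beeps on an arithmetic frequency grid.

    One pulse per frequency in ``freq_start, freq_start+step, ..., freq_end``
    with onsets spaced ``inter_pulse`` seconds apart.  A 0 Hz entry yields a
    null (all-zero) pulse; this is how the real drive chain behaves when the
    carrier is absent.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if freq_end < freq_start:
        raise ValueError("freq_end must be >= freq_start")
    if inter_pulse <= 0:
        raise ValueError("inter_pulse must be positive")
    n = int(np.floor((freq_end - freq_start) / step + 0.5)) + 1
    freqs = freq_start + step * np.arange(n)
    pulses = []
    for k, f in enumerate(freqs):
        if f <= 0:
            wave = np.zeros(spec.n_samples)
        else:
            wave = make_beep(spec.replace(center_freq=float(f)))
        pulses.append(SweepPulse(float(f), wave, k * inter_pulse))
    return pulses
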