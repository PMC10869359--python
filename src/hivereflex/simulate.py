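"""Ground-truth colony vibro-response simulator.

Generates accelerometer traces, video frame stacks and per-pulse ground
truth with the statistical structure the analysis stages assume, so the
whole pipeline is testable without a hive:

* broadband colony baseline noise (band-passed Gaussian, 50–2000 Hz);
* the driven pulse artifact, scaled by a (possibly frequency-dependent)
  transfer gain;
* a short-lived post-pulse envelope drop (default 20%) recovering
  exponentially (tau 1 s) — the freezing/immobilization response;
* a long-lived additive buzz enhancement whose envelope rises to a peak
  near 1 s after the pulse and then decays exponentially;
* sporadic individual "whooping" chirps, typically ~200 ms after the
  pulse and confined to the 2 s that follow it;
* diurnal (24 h) and seasonal multiplicative modulation of baseline and
  buzz levels.

The trace model is a single band-passed unit-variance carrier noise
process amplitude-modulated by ``baseline * immobilization_factor +
buzz_envelope``: immobilization is multiplicative on the colony envelope
(moving bees scale the whole signal) while the buzz adds to it linearly in
the envelope domain, keeping the downstream response metrics exactly
linear in the configured amplitudes.  Whoops and the pulse artifact are
independent additive waveforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .response import AccelTrace
from .stimulus import StimulusSchedule, StimulusSpec, SweepPulse, make_beep, make_schedule

__all__ = [
    "GainCurve",
    "ColonySimConfig",
    "PulseTruth",
    "GroundTruthLog",
    "FrameSimResult",
    "simulate_trace",
    "simulate_pulse_extracts",
    "simulate_season",
    "simulate_frames",
    "simulate_sweep_frames",
]


@dataclass(frozen=True)
class GainCurve:
    """Frequency-dependent stimulus-to-honeycomb transfer gain.

    A Gaussian bump peaked at ``peak_freq`` (default 500 Hz, where the
    immobilization effectiveness of the real drive chain is maximal) on
    top of a constant ``floor`` (the measured transfer stays well above
    zero across the 50-2000 Hz band).
    """

    peak_freq: float = 500.0
    width: float = 300.0
    peak_gain: float = 1.0
    floor: float = 0.15

    def __call__(self, freq: float | np.ndarray) -> float | np.ndarray:
        f = np.asarray(freq, dtype=float)
        g = self.floor + (self.peak_gain - self.floor) * np.exp(
            -0.5 * ((f - self.peak_freq) / self.width) ** 2
        )
        return float(g) if np.isscalar(freq) else g


@dataclass(frozen=True)
class ColonySimConfig:
    """Simulator parameters.  Amplitudes are in the same arbitrary
    acceleration units as the baseline; times in seconds."""

    baseline_rms: float = 1.0
    baseline_band: tuple[float, float] = (50.0, 2000.0)
    # the drive artifact dwarfs the colony signal (it clips the display in
    # real recordings), hence a large default transfer gain
    pulse_gain: "float | GainCurve" = 20.0
    immob_depth: float = 0.20
    immob_recovery_tau: float = 1.0
    # the video assay drives the shaker directly on the frame rod, far
    # stronger coupling than the hive-wall knock: near-total freezing
    video_immob_depth: float = 0.90
    buzz_amp: float = 0.5
    buzz_peak_time: float = 1.0
    buzz_decay_tau: float = 1.0
    buzz_long_frac: float = 0.6
    buzz_long_tau: float = 4.0
    buzz_amp_shape: float = 2.0
    whoop_rate: float = 0.15
    whoop_amp: float = 4.0
    whoop_latency_mean: float = 0.200
    whoop_latency_shape: float = 16.0
    whoop_duration: float = 0.080
    whoop_band: tuple[float, float] = (300.0, 600.0)
    diurnal_profile: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.immob_depth <= 1.0:
            raise ValueError("immob_depth must lie in [0, 1]")
        for name in ("immob_recovery_tau", "buzz_decay_tau", "buzz_peak_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.whoop_latency_mean <= 0 or self.whoop_latency_mean > 2.0:
            raise ValueError("whoop_latency_mean must lie in (0, 2] s")
        if self.diurnal_profile is not None and len(self.diurnal_profile) != 24:
            raise ValueError("diurnal_profile must have 24 hourly factors")

    def gain_at(self, freq: float) -> float:
        if callable(self.pulse_gain):
            return float(self.pulse_gain(freq))
        return float(self.pulse_gain)

    def diurnal_factor(self, epoch: "float | np.ndarray") -> "float | np.ndarray":
        """Multiplicative 24 h modulation, linearly interpolated between the
        hourly profile points (periodic).  1.0 when no profile is set."""
        if self.diurnal_profile is None:
            return 1.0 if np.isscalar(epoch) else np.ones(np.shape(epoch))
        hours = (np.asarray(epoch, dtype=float) % 86400.0) / 3600.0
        grid = np.arange(25.0)
        prof = np.asarray(self.diurnal_profile + (self.diurnal_profile[0],))
        out = np.interp(hours, grid, prof)
        return float(out) if np.isscalar(epoch) else out

    def replace(self, **changes) -> "ColonySimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class PulseTruth:
    """Ground truth for one simulated pulse."""

    pulse_epoch: float
    pulse_end: float
    immob_depth: float
    immob_recovery_tau: float
    buzz_amp: float  # short-lived component amplitude
    buzz_amp_long: float
    buzz_decay_tau: float
    whoop_onsets: np.ndarray  # s after pulse end
    whoop_amps: np.ndarray


@dataclass
class GroundTruthLog:
    """One :class:`PulseTruth` record per scheduled pulse."""

    records: list[PulseTruth] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pulse_epoch": [r.pulse_epoch for r in self.records],
                "immob_depth": [r.immob_depth for r in self.records],
                "immob_recovery_tau": [r.immob_recovery_tau for r in self.records],
                "buzz_amp": [r.buzz_amp for r in self.records],
                "buzz_amp_long": [r.buzz_amp_long for r in self.records],
                "buzz_decay_tau": [r.buzz_decay_tau for r in self.records],
                "n_whoops": [r.whoop_onsets.size for r in self.records],
                "whoop_onsets": [";".join(f"{t:.6f}" for t in r.whoop_onsets) for r in self.records],
            }
        )


def _bandpass_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``.

    Normalized by the filter's analytic white-noise gain so the output
    variance is 1 in expectation (not per realization)."""
    low, high = band
    nyq = fs / 2.0
    high = min(high, 0.99 * nyq)
    sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    w, h = sps.sosfreqz(sos, worN=4096)
    # zero-phase filtering applies |H|^2; white-noise std gain is the RMS of |H|^2
    gain = np.sqrt(np.mean(np.abs(h) ** 4))
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / gain


def _buzz_shape(lag: np.ndarray, peak_time: float, decay_tau: float) -> np.ndarray:
    """Unit-peak buzz envelope template: quadratic rise to the peak, then
    exponential decay.  The slow onset reflects the collective response
    building up and keeps the first ~0.25 s (the immobilization window)
    nearly buzz-free, as in the real recordings where the drop is visible
    despite the buzz."""
    s = np.zeros_like(lag)
    rising = (lag >= 0) & (lag < peak_time)
    s[rising] = (lag[rising] / peak_time) ** 2
    decaying = lag >= peak_time
    s[decaying] = np.exp(-(lag[decaying] - peak_time) / decay_tau)
    return s


def buzz_templates(
    lag: np.ndarray, config: "ColonySimConfig"
) -> tuple[np.ndarray, np.ndarray]:
    """The two unit-peak buzz envelope templates.

    The collective buzzing response comprises two independent
    contributions: a short-lived one peaking at ``buzz_peak_time`` and
    decaying with ``buzz_decay_tau``, and a long-lived one building up
    over twice that time and decaying with ``buzz_long_tau``.  Their
    independent per-event amplitudes are what make the buzz occupy the
    first *two* principal-component ranks downstream.
    """
    short = _buzz_shape(lag, config.buzz_peak_time, config.buzz_decay_tau)
    long_ = _buzz_shape(lag, 2.0 * config.buzz_peak_time, config.buzz_long_tau)
    return short, long_


def _whoop_wave(fs: float, duration: float, band: tuple[float, float], amp: float) -> np.ndarray:
    """A whooping chirp: short upward frequency sweep under a Gaussian
    envelope, peak absolute amplitude ``amp``."""
    n = max(int(round(duration * fs)), 4)
    t = np.arange(n) / fs
    carrier = sps.chirp(t, f0=band[0], f1=band[1], t1=duration, method="linear")
    sigma = duration / 4.0
    env = np.exp(-0.5 * ((t - duration / 2.0) / sigma) ** 2)
    w = env * carrier
    return w * (amp / np.abs(w).max())


def _draw_whoops(cfg: ColonySimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson whoop count; latencies ~ Gamma(shape, mean/shape) truncated
    to (0, 2] s; amplitudes jittered uniformly +-30% about whoop_amp."""
    n = rng.poisson(cfg.whoop_rate)
    onsets = np.empty(n)
    scale = cfg.whoop_latency_mean / cfg.whoop_latency_shape
    for i in range(n):
        for _ in range(1000):
            lat = rng.gamma(cfg.whoop_latency_shape, scale)
            if 0.0 < lat <= 2.0:
                onsets[i] = lat
                break
        else:  # pragma: no cover - essentially impossible at sane configs
            onsets[i] = cfg.whoop_latency_mean
    amps = cfg.whoop_amp * rng.uniform(0.7, 1.3, size=n)
    order = np.argsort(onsets)
    return onsets[order], amps[order]


def simulate_trace(
    config: ColonySimConfig,
    schedule: StimulusSchedule,
    spec: StimulusSpec,
    duration: float,
    start_epoch: float = 0.0,
    rng: np.random.Generator | None = None,
    buzz_scale: float = 1.0,
) -> tuple[AccelTrace, GroundTruthLog]:
    """Simulate a continuous accelerometer trace covering ``schedule``.

    ``buzz_scale`` is an extra multiplier on the buzz amplitude (used by
    :func:`simulate_season` for seasonal modulation).  Returns the trace
    and one ground-truth record per pulse.
    """
    fs = spec.sample_rate
    n = int(round(duration * fs))
    times = np.atleast_1d(schedule.times)
    if times.size and (times.min() < start_epoch or times.max() + spec.total_duration > start_epoch + duration):
        raise ValueError("schedule extends outside the simulated trace duration")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    carrier = _bandpass_noise(rng, n, config.baseline_band, fs)
    t_epoch = start_epoch + np.arange(n) / fs
    diurnal = config.diurnal_factor(t_epoch)
    base_env = config.baseline_rms * np.ones(n) * diurnal
    factor = np.ones(n)
    buzz_env = np.zeros(n)
    extra = np.zeros(n)
    truth = GroundTruthLog()

    beep = make_beep(spec) * config.gain_at(spec.center_freq)

    for t_pulse in times:
        onset_i = int(round((t_pulse - start_epoch) * fs))
        end_i = onset_i + spec.n_samples
        t_end = t_pulse + spec.total_duration
        # pulse artifact
        hi = min(end_i, n)
        extra[onset_i:hi] += beep[: hi - onset_i]
        # immobilization: multiplicative envelope loss recovering exponentially
        span = min(n, end_i + int(round(30.0 * config.immob_recovery_tau * fs)))
        lag = (np.arange(end_i, span) - end_i) / fs
        factor[end_i:span] *= 1.0 - config.immob_depth * np.exp(-lag / config.immob_recovery_tau)
        # buzz: additive envelope enhancement built from two independently
        # scaled templates (short- and long-lived contributions)
        if config.buzz_amp > 0:
            k = config.buzz_amp_shape
            amp = config.buzz_amp * buzz_scale * rng.gamma(k, 1.0 / k)
            amp_long = config.buzz_amp * config.buzz_long_frac * buzz_scale * rng.gamma(k, 1.0 / k)
        else:
            amp = amp_long = 0.0
        bspan = min(
            n,
            end_i + int(round((2 * config.buzz_peak_time + 30.0 * max(config.buzz_decay_tau, config.buzz_long_tau)) * fs)),
        )
        blag = (np.arange(end_i, bspan) - end_i) / fs
        short, long_ = buzz_templates(blag, config)
        buzz_env[end_i:bspan] += (amp * short + amp_long * long_) * config.diurnal_factor(t_end)
        # whoops
        onsets, amps = _draw_whoops(config, rng)
        for lat, wamp in zip(onsets, amps):
            w = _whoop_wave(fs, config.whoop_duration, config.whoop_band, wamp)
            wi = end_i + int(round(lat * fs))
            whi = min(wi + w.size, n)
            if wi < n:
                extra[wi:whi] += w[: whi - wi]
        truth.records.append(
            PulseTruth(
                pulse_epoch=float(t_pulse),
                pulse_end=float(t_end),
                immob_depth=config.immob_depth,
                immob_recovery_tau=config.immob_recovery_tau,
                buzz_amp=float(amp),
                buzz_amp_long=float(amp_long),
                buzz_decay_tau=config.buzz_decay_tau,
                whoop_onsets=onsets,
                whoop_amps=amps,
            )
        )

    samples = carrier * (base_env * factor + buzz_env) + extra
    return AccelTrace(samples, fs, start_epoch), truth


def simulate_pulse_extracts(
    config: ColonySimConfig,
    n_events: int,
    spec: StimulusSpec | None = None,
    pre: float = 1.0,
    post: float = 4.0,
    pad: float = 0.2,
    start_epoch: float = 0.0,
    event_spacing: float = 3600.0,
    rng: np.random.Generator | None = None,
    buzz_scales: np.ndarray | None = None,
) -> tuple[list[AccelTrace], StimulusSchedule, GroundTruthLog]:
    """Simulate ``n_events`` independent single-pulse recording extracts.

    Each extract is a short trace with its pulse exactly ``pre`` seconds
    after the extract start (the deposited-data convention), pulses spaced
    ``event_spacing`` apart in epoch time.  This is the desk-scale stand-in
    for a long field recording cut into pulse-aligned pieces.
    """
    if spec is None:
        spec = StimulusSpec()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    epochs = start_epoch + event_spacing * np.arange(1, n_events + 1)
    # a lead-in pad is simulated and discarded so the band-pass filter's edge
    # transient cannot bias the pre-pulse envelope at the extract start
    duration = pad + pre + spec.total_duration + post + pad
    n_lead = int(round(pad * spec.sample_rate))
    traces: list[AccelTrace] = []
    truth = GroundTruthLog()
    for k, t_pulse in enumerate(epochs):
        sched = StimulusSchedule(
            np.array([t_pulse]), np.array([t_pulse]),
            mean_interval=event_spacing, jitter_sd=0.0,
        )
        scale = 1.0 if buzz_scales is None else float(buzz_scales[k])
        trace, tr = simulate_trace(
            config, sched, spec, duration, start_epoch=t_pulse - pre - pad,
            rng=rng, buzz_scale=scale,
        )
        traces.append(AccelTrace(trace.samples[n_lead:], spec.sample_rate, t_pulse - pre))
        truth.records.extend(tr.records)
    schedule = StimulusSchedule(epochs, epochs, mean_interval=event_spacing, jitter_sd=0.0)
    return traces, schedule, truth


def simulate_season(
    config: ColonySimConfig,
    days: int,
    spec: StimulusSpec | None = None,
    pulses_per_day: int = 24,
    start_epoch: float = 0.0,
    jitter_sd: float = 900.0,
    seasonal_buzz: np.ndarray | None = None,
    pre: float = 1.0,
    post: float = 4.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[AccelTrace], StimulusSchedule, GroundTruthLog]:
    """Simulate a multi-day campaign of per-pulse recording extracts.

    Pulses fire on a jittered grid of ``pulses_per_day`` per day;
    ``seasonal_buzz`` (length ``days``) multiplies the buzz amplitude per
    day, on top of the config's diurnal profile.  Deterministic given the
    config seed.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if spec is None:
        spec = StimulusSpec()
    if seasonal_buzz is not None and len(seasonal_buzz) != days:
        raise ValueError("seasonal_buzz must have one factor per day")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    interval = 86400.0 / pulses_per_day
    sched_seed = int(rng.integers(2**31))
    schedule = make_schedule(
        start_epoch, start_epoch + days * 86400.0, mean_interval=interval,
        jitter_sd=min(jitter_sd, interval / 4.0), seed=sched_seed,
    )
    pad = 0.2
    duration = pad + pre + spec.total_duration + post + pad
    n_lead = int(round(pad * spec.sample_rate))
    traces: list[AccelTrace] = []
    truth = GroundTruthLog()
    for t_pulse in schedule.times:
        day = int(np.clip((t_pulse - start_epoch) // 86400.0, 0, days - 1))
        scale = 1.0 if seasonal_buzz is None else float(seasonal_buzz[day])
        sched = StimulusSchedule(np.array([t_pulse]), np.array([t_pulse]),
                                 mean_interval=interval, jitter_sd=0.0)
        trace, tr = simulate_trace(
            config, sched, spec, duration, start_epoch=t_pulse - pre - pad,
            rng=rng, buzz_scale=scale,
        )
        traces.append(AccelTrace(trace.samples[n_lead:], spec.sample_rate, t_pulse - pre))
        truth.records.extend(tr.records)
    return traces, schedule, truth


#: Mean of |x| for a zero-mean unit-variance Gaussian: converts an
#: amplitude-envelope (std) scale to the rectified-envelope scale.
RECTIFIED_MEAN = float(np.sqrt(2.0 / np.pi))


def true_buzz_matrix(
    truth: GroundTruthLog,
    config: ColonySimConfig,
    n_cols: int,
    sample_rate: float,
    include_immob: bool = False,
) -> np.ndarray:
    """Ground-truth collective envelope response, events x samples, on the
    rectified-envelope scale of :func:`hivereflex.response.envelope`.

    Row i is the planted buzz envelope of pulse i (both templates); with
    ``include_immob`` the deterministic immobilization transient
    (-baseline*depth*exp(-t/tau)) is added, giving the full collective
    (non-whoop) response the rank-1-2 reconstruction estimates.
    """
    lag = np.arange(n_cols) / sample_rate
    short, long_ = buzz_templates(lag, config)
    rows = np.empty((len(truth.records), n_cols))
    for i, rec in enumerate(truth.records):
        rows[i] = rec.buzz_amp * short + rec.buzz_amp_long * long_
        if include_immob:
            rows[i] -= config.baseline_rms * rec.immob_depth * np.exp(
                -lag / rec.immob_recovery_tau
            )
    return RECTIFIED_MEAN * rows


def true_whoop_matrix(
    truth: GroundTruthLog,
    config: ColonySimConfig,
    n_cols: int,
    sample_rate: float,
) -> np.ndarray:
    """Ground-truth whoop envelope contributions, events x samples, on the
    rectified-envelope scale (Gaussian chirp envelopes at the planted
    onsets and amplitudes)."""
    t = np.arange(n_cols) / sample_rate
    dur = config.whoop_duration
    rows = np.zeros((len(truth.records), n_cols))
    for i, rec in enumerate(truth.records):
        for lat, amp in zip(rec.whoop_onsets, rec.whoop_amps):
            rows[i] += amp * np.exp(-0.5 * ((t - lat - dur / 2) / (dur / 4)) ** 2)
    return RECTIFIED_MEAN * rows


@dataclass
class FrameSimResult:
    """Synthetic video stack plus its analytic expectations."""

    frames: np.ndarray  # (n_frames, H, W) float32, 0..255 grey levels
    frame_rate: float
    expected_mobility: np.ndarray  # per frame pair, relative units (baseline 1)
    step_factor: np.ndarray  # ground-truth per-step multiplier
    depth: "float | np.ndarray"
    tau: float
    pulse_times: np.ndarray
    pulse_duration: float


def _step_factor(
    t: np.ndarray,
    pulse_times: np.ndarray,
    pulse_duration: float,
    depth: np.ndarray,
    tau: float,
) -> np.ndarray:
    """Per-bee step-size multiplier: each pulse scales steps by
    (1 - depth*exp(-(t - t_end)/tau)) from its end onward."""
    f = np.ones_like(t)
    for d, tp in zip(depth, pulse_times):
        t_end = tp + pulse_duration
        lag = t - t_end
        m = lag >= 0
        f[m] *= 1.0 - d * np.exp(-lag[m] / tau)
    return np.clip(f, 0.0, None)


def simulate_frames(
    config: ColonySimConfig,
    pulse_times: "np.ndarray | list[float]",
    n_frames: int,
    frame_rate: float = 50.0,
    n_bees: int = 150,
    frame_size: tuple[int, int] = (96, 128),
    step_px: float = 0.6,
    blob_sigma: float = 2.0,
    brightness: float = 150.0,
    pulse_duration: float = 0.1,
    depth: "float | np.ndarray | None" = None,
    tau: float | None = None,
    rng: np.random.Generator | None = None,
) -> FrameSimResult:
    """Render ``n_bees`` random-walking Gaussian blobs at ``frame_rate``.

    After each pulse the per-bee step size is multiplied by
    ``1 - depth*exp(-(t - t_end)/tau)``; ``depth`` may be per-pulse (for
    frequency sweeps) and defaults to the config's deep video-assay
    immobilization.  Returns the stack together with the analytic
    expected mobility curve (relative units, baseline 1), whose value for
    frame pair k is the step factor at the time of the later frame.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pulse_times = np.asarray(pulse_times, dtype=float)
    if depth is None:
        depth = config.video_immob_depth
    depth_arr = np.broadcast_to(np.asarray(depth, dtype=float), pulse_times.shape).copy()
    if tau is None:
        tau = config.immob_recovery_tau

    H, W = frame_size
    margin = int(np.ceil(3 * blob_sigma)) + 1
    patch_half = int(np.ceil(3 * blob_sigma))
    p = 2 * patch_half + 1
    oy, ox = np.mgrid[-patch_half : patch_half + 1, -patch_half : patch_half + 1]

    pos = np.column_stack(
        [
            rng.uniform(margin, H - 1 - margin, n_bees),
            rng.uniform(margin, W - 1 - margin, n_bees),
        ]
    )
    # step factor at the time of the *later* frame of each step
    t_frames = np.arange(n_frames) / frame_rate
    fac = _step_factor(t_frames, pulse_times, pulse_duration, depth_arr, tau)

    frames = np.zeros((n_frames, H, W), dtype=np.float32)

    def render(k: int) -> None:
        iy = np.round(pos[:, 0]).astype(int)
        ix = np.round(pos[:, 1]).astype(int)
        fy = pos[:, 0] - iy
        fx = pos[:, 1] - ix
        vals = brightness * np.exp(
            -((oy[None] - fy[:, None, None]) ** 2 + (ox[None] - fx[:, None, None]) ** 2)
            / (2 * blob_sigma**2)
        )
        flat = ((iy[:, None, None] + oy[None]) * W + (ix[:, None, None] + ox[None])).ravel()
        np.add.at(frames[k].reshape(-1), flat, vals.ravel())

    render(0)
    for k in range(1, n_frames):
        step = rng.normal(0.0, step_px * fac[k], size=(n_bees, 2))
        pos += step
        # reflect off the walls (keeping the blob patch inside the frame)
        pos[:, 0] = np.clip(np.abs(pos[:, 0] - margin) + margin, margin, None)
        pos[:, 0] = H - 1 - margin - np.abs(H - 1 - margin - pos[:, 0])
        pos[:, 1] = np.clip(np.abs(pos[:, 1] - margin) + margin, margin, None)
        pos[:, 1] = W - 1 - margin - np.abs(W - 1 - margin - pos[:, 1])
        render(k)

    np.clip(frames, 0.0, 255.0, out=frames)
    expected = fac[1:].copy()
    return FrameSimResult(
        frames=frames,
        frame_rate=frame_rate,
        expected_mobility=expected,
        step_factor=fac,
        depth=depth_arr if depth_arr.size > 1 else float(depth_arr[0]) if depth_arr.size else 0.0,
        tau=float(tau),
        pulse_times=pulse_times,
        pulse_duration=pulse_duration,
    )


def simulate_sweep_frames(
    config: ColonySimConfig,
    sweep: list[SweepPulse],
    lead_in: float = 1.2,
    tail: float = 2.2,
    depth_at_peak: float = 0.9,
    frame_rate: float = 50.0,
    n_bees: int = 600,
    rng: np.random.Generator | None = None,
    **frame_kwargs,
) -> FrameSimResult:
    """Render the video counterpart of a frequency sweep experiment.

    The per-pulse immobilization depth follows the configured transfer
    gain curve, scaled so the depth at the curve's peak is
    ``depth_at_peak``; a 0 Hz (null) pulse immobilizes nothing.
    """
    freqs = np.array([p.freq for p in sweep])
    onsets = lead_in + np.array([p.onset for p in sweep])
    gains = np.array([config.gain_at(f) if f > 0 else 0.0 for f in freqs])
    peak = gains.max()
    depths = depth_at_peak * gains / peak if peak > 0 else np.zeros_like(gains)
    total = onsets[-1] + tail
    n_frames = int(round(total * frame_rate))
    return simulate_frames(
        config,
        onsets,
        n_frames,
        frame_rate=frame_rate,
        n_bees=n_bees,
        depth=depths,
        rng=rng,
        **frame_kwargs,
    )
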