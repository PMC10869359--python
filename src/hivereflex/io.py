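"""Readers, writers and run configuration.

Traces follow the deposited-data convention: one single-channel audio
file per recording, named by the Unix epoch of its first sample
(``1630227600.wav``).  WAV (float32 or 16-bit PCM) is read and written
through :mod:`scipy.io.wavfile`; ``.flac`` paths are recognized but
rejected with a diagnostic asking for conversion, since no FLAC codec is
bundled.  Schedules and metrics travel as CSV, configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .response import AccelTrace
from .simulate import ColonySimConfig, GainCurve
from .stimulus import StimulusSchedule, StimulusSpec

__all__ = [
    "read_trace",
    "write_trace",
    "read_schedule",
    "write_schedule",
    "read_metrics",
    "write_metrics",
    "AnalysisParams",
    "RunConfig",
]

METRICS_COLUMNS = ["pulse_epoch", "pulse_magnitude", "positive_response", "negative_response"]
SCHEDULE_COLUMNS = ["epoch_s", "nominal_epoch_s", "offset_s"]


def _epoch_from_name(path: Path) -> float:
    stem = path.stem
    try:
        return float(stem)
    except ValueError:
        raise ValueError(
            f"cannot parse a Unix epoch from file name {path.name!r}; "
            "trace files must be named <unix_epoch>.wav"
        ) from None


def read_trace(path: "str | Path") -> AccelTrace:
    """Read a single-channel trace; the start epoch comes from the file name."""
    path = Path(path)
    if path.suffix.lower() == ".flac":
        raise ValueError(
            f"{path.name}: FLAC decoding is not bundled; convert to WAV first "
            "(e.g. `ffmpeg -i in.flac out.wav`)"
        )
    epoch = _epoch_from_name(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path.name}: expected a single channel, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AccelTrace(data, float(rate), epoch)


def write_trace(trace: AccelTrace, path: "str | Path") -> Path:
    """Write a trace as float32 WAV.  If ``path`` is a directory the file
    is named ``<unix_epoch>.wav`` after the trace's start epoch."""
    path = Path(path)
    if path.is_dir() or path.suffix == "":
        path.mkdir(parents=True, exist_ok=True)
        e = trace.start_epoch
        stem = str(int(round(e))) if abs(e - round(e)) < 1e-6 else f"{e:.3f}"
        path = path / f"{stem}.wav"
    if path.suffix.lower() == ".flac":
        raise ValueError("FLAC encoding is not bundled; write WAV instead")
    wavfile.write(path, int(round(trace.sample_rate)), trace.samples.astype(np.float32))
    return path


def write_schedule(schedule: StimulusSchedule, path: "str | Path") -> None:
    pd.DataFrame(
        {
            "epoch_s": schedule.times,
            "nominal_epoch_s": schedule.nominal,
            "offset_s": schedule.offsets,
        }
    ).to_csv(path, index=False)


def read_schedule(path: "str | Path") -> StimulusSchedule:
    df = pd.read_csv(path)
    missing = [c for c in SCHEDULE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"schedule CSV missing columns {missing}")
    return StimulusSchedule(
        df["epoch_s"].to_numpy(float), df["nominal_epoch_s"].to_numpy(float)
    )


def write_metrics(metrics: pd.DataFrame, path: "str | Path") -> None:
    missing = [c for c in METRICS_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics frame missing columns {missing}")
    metrics[METRICS_COLUMNS].to_csv(path, index=False)


def read_metrics(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics CSV missing columns {missing}")
    return df


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable analysis parameters with their field defaults."""

    pre: float = 1.0
    post: float = 4.0
    smooth_window: float = 0.0045
    early_window: float = 0.25
    buzz_ranks: tuple[int, int] = (1, 2)
    whoop_ranks: tuple[int, int] = (3, 15)
    threshold_sd: float = 5.0
    morning: tuple[float, float] = (0.0, 12.0)
    tz_offset: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs: stimulus, simulator and analysis
    parameters plus the master seed.  Round-trips losslessly through YAML;
    unknown keys are warned about, never silently dropped."""

    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    sim: ColonySimConfig = field(default_factory=ColonySimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "stimulus": dataclasses.asdict(self.stimulus),
            "sim": dataclasses.asdict(self.sim),
            "analysis": dataclasses.asdict(self.analysis),
            "seed": self.seed,
        }
        gain = self.sim.pulse_gain
        if isinstance(gain, GainCurve):
            d["sim"]["pulse_gain"] = dataclasses.asdict(gain)
        for sect in ("analysis", "sim", "stimulus"):
            for k, v in d[sect].items():
                if isinstance(v, tuple):
                    d[sect][k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {"stimulus": StimulusSpec, "sim": ColonySimConfig, "analysis": AnalysisParams}
        kwargs: dict = {"seed": int(data.pop("seed", 0))}
        for name, klass in sections.items():
            raw = dict(data.pop(name, {}))
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = sorted(set(raw) - known)
            if unknown:
                warnings.warn(f"unknown {name} config keys ignored: {unknown}", stacklevel=2)
            vals = {k: v for k, v in raw.items() if k in known}
            for k, v in vals.items():
                if isinstance(v, list):
                    vals[k] = tuple(v)
            if name == "sim" and isinstance(vals.get("pulse_gain"), (dict, tuple)):
                vals["pulse_gain"] = GainCurve(**dict(vals["pulse_gain"]))
            kwargs[name] = klass(**vals)
        if data:
            warnings.warn(f"unknown config sections ignored: {sorted(data)}", stacklevel=2)
        return cls(**kwargs)

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
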