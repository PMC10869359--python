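# hive-reflex

Stimulation–response analysis for honeybee colonies probed with short
artificial vibrational pulses.

A colony is "knocked" through the hive wall with a gentle beep — a 0.1 s
monochromatic tone burst, carrier 340 Hz, shaped by a Gaussian envelope of
30 ms full width at half maximum — fired at randomized, roughly hourly
times (60 min ± 15 min SD jitter, to prevent habituation).  An
accelerometer embedded in the central comb records the colony's reflex:

* a **negative response** — the bees freeze, and the vibrational envelope
  drops ~20% immediately after the pulse, recovering exponentially
  (time constant ≈ 1 s in video at the optimal 500 Hz drive);
* a **positive response** — a collective *buzzing* enhancement that peaks
  around 1 s after the pulse and decays over seconds; and
* sporadic **whooping signals** from individual bees, typically ~200 ms
  after the pulse and confined to the following 2 s.

This package implements the full desk-scale pipeline: stimulus and
schedule synthesis, a ground-truth colony simulator (accelerometer traces
*and* 50 FPS video frame stacks), pulse-aligned response metrics,
PCA rank-based separation of buzz and whoops, frame-difference mobility
quantification with exponential-recovery fitting, and seasonal/diurnal
reporting with robust outlier flagging of anomalous (e.g. queenless)
colonies.

## The metrics

For each pulse, with `E(t)` the rectified signal smoothed by a 4.5 ms
moving average:

| metric | definition |
| --- | --- |
| pulse magnitude | RMS of the raw signal over the 0.1 s pulse span |
| positive response | mean E over the 4 s post-pulse − mean E over the 1 s pre-pulse |
| negative response | mean E over the 1 s pre-pulse − mean E over the 0.25 s post-pulse |

Event-aligned post-pulse envelopes (one row per pulse, pre-pulse mean
subtracted) are decomposed by PCA.  The collective buzz, comprising
independent short- and long-lived contributions, occupies ranks 1–2;
reconstruction from ranks 3–15 isolates the individual whooping signals,
which a robust 5-SD threshold detector then extracts.

Video mobility is the per-frame mean of |frame<sub>k+1</sub> −
frame<sub>k</sub>|; pulse-induced freezing appears as a trough recovering
as `M(t) = M0 − D·exp(−(t − t_end)/τ)`.

## Worked example

```python
import hivereflex as hr

cfg = hr.ColonySimConfig(seed=42)                 # pilot-default colony
traces, schedule, truth = hr.simulate_pulse_extracts(cfg, n_events=6)
windows = [hr.extract_windows(t, [e])[0] for t, e in zip(traces, schedule.times)]
print(hr.compute_metrics(windows).round(3).to_string(index=False))
print(f"{hr.metabolic_duty_cycle(5, 3600):.2f}%")
```

prints

```
 pulse_epoch  pulse_magnitude  positive_response  negative_response
      3600.0            6.794              0.144              0.140
      7200.0            6.745              0.047              0.128
     10800.0            6.909              0.363              0.133
     14400.0            6.701              0.280              0.134
     18000.0            6.688              0.020              0.138
     21600.0            6.731              0.489              0.110
0.14%
```

Pulse magnitudes are steady (the drive is constant), the positive
response varies pulse to pulse (per-event buzz amplitudes are random),
and the negative response sits near 0.13 envelope units — a ~16% drop of
the ~0.80 baseline envelope, the windowed-mean reading of the 20%
instantaneous freeze.  The final line is the metabolic cost of the assay:
a 5 s response to an hourly stimulus occupies 0.14% of the colony's time.

A command-line interface mirrors the library:

```sh
hive-reflex beep --freq 340 --fwhm-ms 30 --duration-ms 100 --rate 8000 -o beep.wav
hive-reflex schedule --start 0 --end 864000 --mean-min 60 --sd-min 15 --seed 42 -o schedule.csv
hive-reflex simulate trace --n-events 20 -o recs/
hive-reflex analyze --trace-dir recs/ --schedule recs/schedule.csv --out metrics.csv
hive-reflex report grid --metrics metrics.csv --out report/
```

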