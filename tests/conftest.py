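import numpy as np
import pytest

import hivereflex as hr


@pytest.fixture(scope="session")
def default_spec():
    return hr.StimulusSpec()


@pytest.fixture(scope="session")
def pca_pipeline():
    """200 simulated pulse events at default settings, with the fitted PC
    model and ground truth.  Shared: the PCA separation checks all read
    from the same campaign, as they would from one field dataset."""
    cfg = hr.ColonySimConfig(seed=11)
    traces, sched, truth = hr.simulate_pulse_extracts(cfg, 200)
    windows = [hr.extract_windows(t, [e])[0] for t, e in zip(traces, sched.times)]
    matrix = hr.build_matrix(windows)
    model = hr.fit_pca(matrix)
    return {
        "config": cfg,
        "windows": windows,
        "matrix": matrix,
        "model": model,
        "truth": truth,
        "schedule": sched,
    }


@pytest.fixture(scope="session")
def sweep_experiment():
    """A full 0-2000 Hz video sweep at the default transfer-gain curve."""
    cfg = hr.ColonySimConfig(seed=8, pulse_gain=hr.GainCurve())
    sweep = hr.make_sweep(0, 2000, 50, 2.2, hr.StimulusSpec())
    res = hr.simulate_sweep_frames(cfg, sweep, rng=np.random.default_rng(8))
    mob = hr.frame_mobility(res.frames)
    curve = hr.frequency_effectiveness(mob, [(p.freq, 1.2 + p.onset) for p in sweep])
    return {"config": cfg, "sweep": sweep, "mobility": mob, "curve": curve}


@pytest.fixture(scope="session")
def null_extracts():
    """200 pulse extracts with every response effect zeroed."""
    cfg = hr.ColonySimConfig(
        immob_depth=0.0, buzz_amp=0.0, whoop_rate=0.0, seed=1
    )
    traces, sched, _ = hr.simulate_pulse_extracts(cfg, 200)
    windows = [hr.extract_windows(t, [e])[0] for t, e in zip(traces, sched.times)]
    return windows
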