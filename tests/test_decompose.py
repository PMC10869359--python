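"""PCA rank separation of the collective buzz from individual whoops."""

import numpy as np
import pytest

import hivereflex as hr
from hivereflex.decompose import ResponseMatrix, build_matrix, detect_whoops, fit_pca, rank_energy, reconstruct, sort_events
from hivereflex.simulate import true_buzz_matrix, true_whoop_matrix


def toy_model(scores_rows, epochs=None):
    X = np.asarray(scores_rows, dtype=float)
    epochs = np.arange(X.shape[0]) if epochs is None else np.asarray(epochs)
    return fit_pca(ResponseMatrix(X, epochs, 100.0))


class TestBuildMatrix:
    def test_one_row_per_window_and_pre_mean_subtraction(self, pca_pipeline):
        windows = pca_pipeline["windows"]
        m = build_matrix(windows[:10])
        assert m.data.shape[0] == 10

    def test_identical_windows_give_identical_rows(self, pca_pipeline):
        w = pca_pipeline["windows"][0]
        m = build_matrix([w, w, w])
        assert np.array_equal(m.data[0], m.data[1])
        assert np.array_equal(m.data[0], m.data[2])

    def test_ragged_windows_rejected(self, pca_pipeline):
        w = pca_pipeline["windows"][0]
        short = hr.PulseWindow(w.pre, w.pulse, w.post[:-100], w.pulse_epoch, w.sample_rate)
        with pytest.raises(ValueError, match="ragged"):
            build_matrix([w, short])

    def test_fewer_than_two_windows_rejected(self, pca_pipeline):
        with pytest.raises(ValueError):
            build_matrix(pca_pipeline["windows"][:1])

    def test_null_effect_rows_centred_on_zero(self, null_extracts):
        m = build_matrix(null_extracts)
        row_means = m.data.mean(axis=1)
        assert abs(row_means.mean()) <= 3 * row_means.std(ddof=1) / np.sqrt(row_means.size)


class TestPCModel:
    def test_components_orthonormal(self, pca_pipeline):
        c = pca_pipeline["model"].components
        gram = c @ c.T
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8

    def test_explained_variance_non_increasing(self, pca_pipeline):
        ev = pca_pipeline["model"].explained_variance
        assert np.all(np.diff(ev) <= 1e-12)

    def test_full_rank_reconstruction_is_complete(self, pca_pipeline):
        model, matrix = pca_pipeline["model"], pca_pipeline["matrix"]
        full = reconstruct(model, range(1, model.n_components + 1))
        rel = np.abs(full - matrix.data).max() / np.abs(matrix.data).max()
        assert rel < 1e-6

    def test_energy_conservation_across_ranks(self, pca_pipeline):
        model, matrix = pca_pipeline["model"], pca_pipeline["matrix"]
        centred = matrix.data - matrix.data.mean(axis=0)
        total = np.sum(centred**2)
        per_rank = np.sum(model.scores**2)
        assert abs(per_rank - total) / total < 1e-6

    def test_single_event_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(ResponseMatrix(np.ones((1, 10)), np.array([0.0]), 10.0))


class TestSortEvents:
    def test_output_is_permutation_in_score_order(self, pca_pipeline):
        model = pca_pipeline["model"]
        order = sort_events(model)
        assert sorted(order) == list(range(model.scores.shape[0]))
        pc1 = model.scores[order, 0]
        assert np.all(np.diff(pc1) <= 1e-12)

    def test_ties_broken_by_epoch(self):
        model = toy_model(
            [[1.0, 0.0], [1.0, 0.0], [2.0, 1.0], [0.0, 2.0]],
            epochs=[40.0, 10.0, 5.0, 1.0],
        )
        tied = np.flatnonzero(np.isclose(model.scores[:, 0], model.scores[:, 0].max()))
        order = sort_events(model)
        if tied.size > 1:  # equal top scores: earlier epoch first
            first_two = order[:2]
            assert model.epochs[first_two[0]] <= model.epochs[first_two[1]]

    def test_planted_strongest_event_sorts_first(self, pca_pipeline):
        model, truth = pca_pipeline["model"], pca_pipeline["truth"]
        order = sort_events(model)
        strength = np.array([r.buzz_amp + r.buzz_amp_long for r in truth.records])
        # the leading event should be among the genuinely loudest
        assert strength[order[0]] >= np.percentile(strength, 90)


class TestReconstruct:
    def test_empty_rank_set_gives_mean_rows(self, pca_pipeline):
        model = pca_pipeline["model"]
        rec = reconstruct(model, [])
        assert np.allclose(rec, model.mean[None, :])

    def test_out_of_range_rank_rejected(self, pca_pipeline):
        with pytest.raises(ValueError, match="ranks"):
            reconstruct(pca_pipeline["model"], [0])
        with pytest.raises(ValueError, match="ranks"):
            reconstruct(pca_pipeline["model"], [10**6])


class TestSeparation:
    def test_rank12_reconstruction_tracks_collective_response(self, pca_pipeline):
        model, matrix = pca_pipeline["model"], pca_pipeline["matrix"]
        truth, cfg = pca_pipeline["truth"], pca_pipeline["config"]
        target = true_buzz_matrix(truth, cfg, matrix.data.shape[1], matrix.sample_rate, include_immob=True)
        r12 = reconstruct(model, [1, 2])
        r = np.corrcoef(r12.ravel(), target.ravel())[0, 1]
        assert r > 0.95

    def test_whoop_energy_confined_to_ranks_three_plus(self, pca_pipeline):
        model, matrix = pca_pipeline["model"], pca_pipeline["matrix"]
        truth, cfg = pca_pipeline["truth"], pca_pipeline["config"]
        W = true_whoop_matrix(truth, cfg, matrix.data.shape[1], matrix.sample_rate)
        e12 = rank_energy(model, W, [1, 2])
        e315 = rank_energy(model, W, range(3, 16))
        assert e12 < 0.10 * e315

    def test_detected_whoops_match_planted_onsets(self, pca_pipeline):
        model, matrix = pca_pipeline["model"], pca_pipeline["matrix"]
        truth = pca_pipeline["truth"]
        events = detect_whoops(reconstruct(model, range(3, 16)), matrix.sample_rate, 5.0)
        assert events, "no whoops detected at default settings"
        by_row = {}
        for i, rec in enumerate(truth.records):
            if rec.whoop_onsets.size:
                by_row[i] = rec.whoop_onsets
        errs = []
        for e in events:
            cand = by_row.get(e.event_index)
            assert cand is not None, "detection in a whoop-free event"
            errs.append(abs(e.onset - cand[np.argmin(np.abs(cand - e.onset))]))
        assert np.median(errs) * 1000 <= 10.0
        onsets = np.array([e.onset for e in events])
        assert np.mean(onsets <= 2.0) >= 0.95
        assert abs(np.median(onsets) * 1000 - 200.0) <= 20.0

    def test_null_simulation_false_positive_rate_below_one_percent(self):
        cfg = hr.ColonySimConfig(whoop_rate=0.0, seed=21)
        traces, sched, _ = hr.simulate_pulse_extracts(cfg, 200)
        windows = [hr.extract_windows(t, [e])[0] for t, e in zip(traces, sched.times)]
        matrix = build_matrix(windows)
        model = fit_pca(matrix)
        events = detect_whoops(reconstruct(model, range(3, 16)), matrix.sample_rate, 5.0)
        affected = len({e.event_index for e in events})
        assert affected / 200 < 0.01
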