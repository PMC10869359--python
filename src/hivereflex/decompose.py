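"""PCA rank-based separation of the collective buzz from individual whoops.

The post-pulse envelope segments of all retained pulses form an
events x samples response matrix (each row has its own pre-pulse envelope
mean subtracted).  Principal component analysis of this matrix
concentrates the slowly varying, collective buzzing response in the first
two rank-ordered components, while the short, sparse whooping signals of
individual bees are confined to components of rank three and above.
Reconstructing the matrix from ranks 1-2 therefore yields a denoised buzz
estimate, and the rank 3-15 reconstruction isolates the whoops, on which
a simple robust threshold detector operates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .response import SMOOTH_WINDOW, PulseWindow, envelope

__all__ = [
    "ResponseMatrix",
    "PCModel",
    "WhoopEvent",
    "build_matrix",
    "fit_pca",
    "sort_events",
    "reconstruct",
    "detect_whoops",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """Event-aligned envelope segments: rows are pulses, columns envelope
    samples over the post-pulse window, after per-event pre-pulse mean
    subtraction."""

    data: np.ndarray
    epochs: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        epochs = np.asarray(self.epochs, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "epochs", epochs)
        if data.ndim != 2:
            raise ValueError("ResponseMatrix data must be 2-D (events x samples)")
        if epochs.size != data.shape[0]:
            raise ValueError("one epoch per event row required")

    @property
    def n_events(self) -> int:
        return int(self.data.shape[0])


@dataclass(frozen=True)
class PCModel:
    """Fitted principal components of a response matrix.

    ``components`` are orthonormal rows ordered by decreasing explained
    variance; ``scores`` the per-event coordinates; each component's sign
    is fixed so its inner product with the matrix column mean is
    non-negative, making "decreasing first PC score" reproducible.
    """

    mean: np.ndarray
    components: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    epochs: np.ndarray
    sample_rate: float

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])


@dataclass(frozen=True)
class WhoopEvent:
    """A detected whooping excursion in one event row."""

    event_index: int
    onset: float  # s after pulse end
    peak: float
    duration: float


def build_matrix(
    windows: Sequence[PulseWindow],
    smooth: float = SMOOTH_WINDOW,
    hop: int | None = None,
) -> ResponseMatrix:
    """Stack smoothed post-pulse envelopes, minus each event's scalar
    pre-pulse envelope mean, into a rectangular events x samples matrix.

    The raw signal is heavily oversampled relative to its smoothed
    envelope, so rows are sampled every ``hop`` raw samples; the default
    hop is the smoothing window itself (4.5 ms), i.e. the envelope's own
    resolution.  Pass ``hop=1`` to keep the full raw rate.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    lengths = {w.post.size for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"ragged windows: post lengths {sorted(lengths)}")
    rates = {w.sample_rate for w in windows}
    if len(rates) != 1:
        raise ValueError("windows must share one sample rate")
    fs = rates.pop()
    if hop is None:
        hop = max(int(round(smooth * fs)), 1)
    n_cols = (lengths.pop() + hop - 1) // hop
    rows = np.empty((len(windows), n_cols))
    for i, w in enumerate(windows):
        pre_mean = envelope(w.pre, fs, smooth).mean()
        rows[i] = envelope(w.post, fs, smooth)[::hop] - pre_mean
    epochs = np.array([w.pulse_epoch for w in windows])
    return ResponseMatrix(rows, epochs, fs / hop)


def fit_pca(matrix: ResponseMatrix, n_components: int | None = None) -> PCModel:
    """Standard PCA on the event rows (full SVD), sign-fixed against the
    column mean.  ``n_components`` defaults to the full rank
    ``min(n_events, n_samples)`` so the basis is complete."""
    X = matrix.data
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least two events")
    k = min(n, p) if n_components is None else min(n_components, n, p)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    col_mean = pca.mean_
    flip = np.sign(components @ col_mean)
    flip[flip == 0] = 1.0
    components *= flip[:, None]
    scores = scores * flip[None, :]
    return PCModel(
        mean=col_mean,
        components=components,
        scores=scores,
        explained_variance=pca.explained_variance_.copy(),
        epochs=matrix.epochs,
        sample_rate=matrix.sample_rate,
    )


def sort_events(model: PCModel) -> np.ndarray:
    """Event ordering by decreasing first-PC score; ties broken by event
    epoch, earlier first.  Returns a permutation of row indices."""
    pc1 = model.scores[:, 0]
    return np.lexsort((model.epochs, -pc1))


def _rank_indices(model: PCModel, ranks: Iterable[int]) -> np.ndarray:
    ranks = np.asarray(sorted(set(int(r) for r in ranks)), dtype=int)
    if ranks.size and (ranks.min() < 1 or ranks.max() > model.n_components):
        raise ValueError(
            f"ranks must lie in 1..{model.n_components}, got {ranks.tolist()}"
        )
    return ranks - 1


def reconstruct(model: PCModel, ranks: Iterable[int]) -> np.ndarray:
    """Rebuild the matrix from a subset of 1-based component ranks:
    mean + sum over ranks of score_r * component_r."""
    idx = _rank_indices(model, ranks)
    out = np.tile(model.mean, (model.scores.shape[0], 1))
    if idx.size:
        out += model.scores[:, idx] @ model.components[idx]
    return out


def rank_energy(model: PCModel, rows: np.ndarray, ranks: Iterable[int]) -> float:
    """Energy of ``rows`` (events x samples) projected on the given
    component ranks: sum of squared inner products with each component."""
    idx = _rank_indices(model, ranks)
    if idx.size == 0:
        return 0.0
    proj = rows @ model.components[idx].T
    return float(np.sum(proj**2))


def detect_whoops(
    whoop_matrix: np.ndarray,
    sample_rate: float,
    threshold_sd: float = 5.0,
    merge_gap: float = 0.020,
    min_duration: float = 0.010,
    onset_sd: float = 1.0,
) -> list[WhoopEvent]:
    """Threshold detector for whoop excursions in a rank >=3 reconstruction.

    The across-event column mean (shared buzz/drop template) is removed
    first, and each column is whitened by its robust (MAD-based) standard
    deviation across events: colony envelope noise scales with the local
    envelope, so the whitening keeps loud-buzz regions from triggering on
    their own fluctuations.  Per row, whitened samples exceeding
    ``threshold_sd`` row noise SDs above the row median are grouped into
    excursions; excursions closer than ``merge_gap`` are merged and those
    shorter than ``min_duration`` dropped.  Each excursion's onset is then
    walked back to where the whitened row last crossed ``onset_sd`` SDs,
    so the reported onset (s after pulse end, column 0) tracks the start
    of the whoop rather than the instant it cleared the high threshold.
    """
    X = np.asarray(whoop_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("whoop_matrix must be 2-D")
    raw = X - X.mean(axis=0)
    col_med = np.median(raw, axis=0)
    col_sd = 1.4826 * np.median(np.abs(raw - col_med), axis=0)
    floor = np.median(col_sd)
    if floor == 0.0:
        return []
    dev = raw / np.maximum(col_sd, 0.1 * floor)
    gap = int(round(merge_gap * sample_rate))
    min_len = max(int(round(min_duration * sample_rate)), 1)
    events: list[WhoopEvent] = []
    for i, row in enumerate(dev):
        med = np.median(row)
        sd = 1.4826 * np.median(np.abs(row - med))
        if sd == 0.0:
            continue
        above = row > med + threshold_sd * sd
        if not above.any():
            continue
        low = row > med + onset_sd * sd
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            lo, hi = idx[s], idx[e]
            if hi - lo + 1 < min_len:
                continue
            onset_i = lo
            while onset_i > 0 and low[onset_i - 1]:
                onset_i -= 1
            events.append(
                WhoopEvent(
                    event_index=i,
                    onset=onset_i / sample_rate,
                    peak=float(raw[i, lo : hi + 1].max()),
                    duration=(hi - lo + 1) / sample_rate,
                )
            )
    return events
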