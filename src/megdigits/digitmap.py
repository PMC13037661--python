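"""Vertex-wise windowed decoding, finger labelling, and group digit maps.

A digit map assigns cortical vertices, per 50-ms window, to the finger
whose movement they best discriminate.  Individual maps label each vertex
with the class of highest class-conditional accuracy; group maps first
mask vertices whose mean four-class accuracy is significantly above the
25% chance level (one-sided permutation test with Benjamini-Hochberg
correction across vertices) and then vote among the participants' labels
inside the mask.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import DigitMap, N_TASKS, SourceEpochs
from .decode import cv_ovr_linear
from .stats import vertex_permutation_bh

__all__ = [
    "vertexwise_decode",
    "label_individual",
    "group_digit_map",
    "finger_counts",
]

logger = logging.getLogger(__name__)


def vertexwise_decode(
    source_epochs: SourceEpochs,
    window: float = 0.050,
    span: tuple[float, float] = (-1.0, 2.0),
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    windows: np.ndarray | None = None,
    vertices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Four-class decoding at each (window, vertex).

    Features for one CV run are the vertex's ``window``-second source
    segment.  ``windows``/``vertices`` restrict the computation (indices
    into the tiling / the vertex axis); unrestricted runs over hundreds
    of vertices are expensive.

    Returns
    -------
    accuracy : (n_windows, n_vertices) mean four-class accuracy.
    per_class : (n_windows, n_vertices, n_tasks) class-conditional recall.
    window_starts : (n_windows,) start times in seconds of the windows
        actually computed.
    """
    sfreq = source_epochs.sfreq
    spw = int(round(window * sfreq))
    n_win_total = int(round((span[1] - span[0]) / window))
    start0 = int(round((span[0] - source_epochs.t0) * sfreq))
    win_sel = np.arange(n_win_total) if windows is None else np.asarray(windows, int)
    vert_sel = (
        np.arange(source_epochs.n_channels)
        if vertices is None
        else np.asarray(vertices, int)
    )
    acc = np.empty((win_sel.size, vert_sel.size))
    per_class = np.empty((win_sel.size, vert_sel.size, N_TASKS))
    for wi, w in enumerate(win_sel):
        s0 = start0 + int(w) * spw
        for vi, v in enumerate(vert_sel):
            X = source_epochs.data[:, v, s0 : s0 + spw]
            res = cv_ovr_linear(X, source_epochs.labels, folds=folds, seed=seed, C=C)
            acc[wi, vi] = res.overall_accuracy
            per_class[wi, vi] = res.per_class_accuracy
    window_starts = span[0] + win_sel * window
    return acc, per_class, window_starts


def label_individual(per_class_accuracy: np.ndarray) -> np.ndarray:
    """Label each (window, vertex) with the class of highest accuracy.

    Ties (including the all-equal case) are left unassigned (-1): an
    arbitrary tie-break would inject spurious votes into the group map.
    """
    pc = np.asarray(per_class_accuracy, float)
    best = np.nanmax(pc, axis=-1, keepdims=True)
    is_best = pc == best
    tie = is_best.sum(axis=-1) != 1
    labels = np.argmax(pc, axis=-1)
    labels = np.where(tie, -1, labels)
    return labels.astype(int)


def group_digit_map(
    individual_labels: np.ndarray,
    group_accuracies: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 5000,
    chance: float = 0.25,
    seed: int = 0,
    window_starts: np.ndarray | None = None,
) -> DigitMap:
    """Voting-based group digit map.

    Parameters
    ----------
    individual_labels : (n_subjects, n_windows, n_vertices) int
        Per-subject finger labels (-1 = unassigned).
    group_accuracies : (n_subjects, n_windows, n_vertices)
        Per-subject mean four-class accuracies; their across-subject mean
        is tested against ``chance`` by a one-sided sign-flip permutation
        test with BH correction across vertices within each window.
    """
    labels = np.asarray(individual_labels, int)
    accs = np.asarray(group_accuracies, float)
    if labels.shape != accs.shape:
        raise ValueError("label and accuracy arrays must share a shape")
    if labels.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    n_subj, n_win, n_vert = labels.shape

    sig_mask, _ = vertex_permutation_bh(
        accs, chance=chance, n_perm=n_perm, alpha=alpha, one_sided=True, seed=seed
    )

    group = np.full((n_win, n_vert), -1, dtype=int)
    n_ties = 0
    for w in range(n_win):
        for v in np.flatnonzero(sig_mask[w]):
            votes = labels[:, w, v]
            votes = votes[votes >= 0]
            if votes.size == 0:
                continue
            counts = np.bincount(votes, minlength=N_TASKS)
            top = counts.max()
            winners = np.flatnonzero(counts == top)
            if winners.size == 1:
                group[w, v] = winners[0]
            else:
                n_ties += 1  # tied vote: unassigned
    if n_ties:
        logger.info("group_digit_map: %d tied votes left unassigned", n_ties)

    counts = np.stack(
        [np.sum((group == k) & sig_mask, axis=1) for k in range(N_TASKS)], axis=1
    )
    dm = DigitMap(
        labels=group,
        accuracy=accs.mean(axis=0),
        per_class_accuracy=None,
        significant=sig_mask,
        counts=counts,
        threshold=0.0,
        window_starts=window_starts,
    )
    dm.threshold = finger_counts(dm)[1]
    return dm


def finger_counts(digitmap: DigitMap) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-window finger vertex counts with the activation threshold.

    The threshold is 25% of one quarter of the maximum total assigned
    vertex count over windows; fingers whose count exceeds it in a window
    are flagged as active there.

    Returns ``(counts (n_windows, n_tasks), threshold, active flags)``.
    """
    counts = digitmap.counts
    totals = counts.sum(axis=1)
    max_total = totals.max() if counts.size else 0
    threshold = 0.25 * max_total / 4.0
    active = counts > threshold
    return counts, float(threshold), active
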