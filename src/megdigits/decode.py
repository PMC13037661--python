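"""Cross-validated one-versus-rest linear decoding and the feature pipelines.

All pipelines share one harness: stratified 5-fold cross-validation, with
standardization fitted on the training fold only, and a linear
one-versus-rest max-margin classifier (SVM, C = 1 by default).  Feature
extraction steps that look at more than one trial (PCA loadings,
activation-map extrema) are re-fitted inside each training fold, so the
test fold never leaks into the fitted parameters.

Pipelines
---------
* point-wise: all-vertex amplitudes at a single time sample;
* window-wise: the per-trial activation-index map of a single 50-ms window;
* PCA-based: retained ROI component time courses over the task period;
* A-epoch-based: time courses at the 8 extrema vertices of the full-epoch
  activation map (max + min per task);
* A-window-based: per 50-ms window, the 8 extrema-vertex segments,
  concatenated over windows (same dimensionality as A-epoch-based);
* virtual-channel single-window vs window-combined decoding;
* optional power features (Morlet power instead of time courses).
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as scisig
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .containers import (
    ActivationMap,
    DecodingResult,
    Epochs,
    N_TASKS,
    SourceEpochs,
    VirtualChannelSet,
)
from .source import extrema_vertices

__all__ = [
    "cv_ovr_linear",
    "pointwise_decode",
    "windowwise_decode",
    "decode_pca",
    "decode_a_epoch",
    "decode_a_window",
    "build_virtual_channels",
    "single_vs_combined",
    "power_features",
    "decode_power",
    "pca_feature_builder",
    "a_epoch_feature_builder",
    "a_window_feature_builder",
]


# ---------------------------------------------------------------------------
# CV harness
# ---------------------------------------------------------------------------

def _check_labels(y: np.ndarray, folds: int) -> np.ndarray:
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < folds):
        lacking = classes[counts < folds]
        raise ValueError(
            f"classes {lacking.tolist()} have fewer than {folds} trials; "
            "every class must appear in every fold"
        )
    return y


def cv_ovr_linear(
    features: np.ndarray | None,
    labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    feature_builder=None,
) -> DecodingResult:
    """Stratified k-fold one-versus-rest linear SVM decoding.

    Either pass a fixed feature matrix ``(n_trials, n_features)``, or a
    ``feature_builder(train_idx, test_idx) -> (X_train, X_test)`` callable
    for fold-dependent feature extraction (leakage-free by construction).
    """
    y = _check_labels(labels, folds)
    if feature_builder is None:
        X = np.asarray(features, float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("features must be (n_trials, n_features)")
        if np.all(X.std(axis=0) == 0):
            warnings.warn("all features have zero variance; decoding is degenerate")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    fold_acc = np.empty(folds)
    for f, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        if feature_builder is not None:
            X_tr, X_te = feature_builder(tr, te)
        else:
            X_tr, X_te = X[tr], X[te]
        scaler = StandardScaler().fit(X_tr)
        clf = LinearSVC(C=C, dual="auto", max_iter=5000, tol=1e-3).fit(scaler.transform(X_tr), y[tr])
        pred = clf.predict(scaler.transform(X_te))
        fold_acc[f] = np.mean(pred == y[te])
        for t, p in zip(y[te], pred):
            confusion[np.searchsorted(classes, t), np.searchsorted(classes, p)] += 1
    return DecodingResult(fold_accuracies=fold_acc, confusion=confusion)


def _series_result(results: list[DecodingResult], times: np.ndarray) -> DecodingResult:
    series = np.array([r.mean_accuracy for r in results])
    series_folds = np.stack([r.fold_accuracies for r in results], axis=1)
    confusion = np.sum([r.confusion for r in results], axis=0)
    return DecodingResult(
        fold_accuracies=series_folds.mean(axis=1),
        confusion=confusion,
        series=series,
        series_folds=series_folds,
        series_times=np.asarray(times),
    )


# ---------------------------------------------------------------------------
# time-resolved pipelines
# ---------------------------------------------------------------------------

def pointwise_decode(
    source_epochs: SourceEpochs,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    decim: int = 1,
    span: tuple[float, float] | None = None,
) -> DecodingResult:
    """One CV run per time sample; features are all vertex amplitudes there.

    ``decim`` subsamples the time axis; ``span`` restricts it.  The series
    holds the mean accuracy per retained sample.
    """
    mask = np.ones(source_epochs.n_samples, bool)
    if span is not None:
        mask = source_epochs.time_mask(span)
    idx = np.flatnonzero(mask)[::decim]
    results = [
        cv_ovr_linear(source_epochs.data[:, :, s], source_epochs.labels,
                      folds=folds, seed=seed, C=C)
        for s in idx
    ]
    return _series_result(results, source_epochs.times[idx])


def windowwise_decode(
    awin: ActivationMap,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> DecodingResult:
    """One CV run per 50-ms window; features are per-trial vertex A values.

    Vertices with NaN activation in a window are dropped listwise for
    that window (with a warning).
    """
    if not awin.windowed:
        raise ValueError("need a windowed activation map")
    tv = awin.trial_values  # (trials, V, n_win)
    results = []
    for w in range(tv.shape[2]):
        X = tv[:, :, w]
        bad = np.any(np.isnan(X), axis=0)
        if bad.any():
            warnings.warn(f"window {w}: dropping {bad.sum()} NaN vertices")
            X = X[:, ~bad]
        results.append(cv_ovr_linear(X, awin.labels, folds=folds, seed=seed, C=C))
    return _series_result(results, awin.window_starts)


# ---------------------------------------------------------------------------
# spatial-feature pipelines (fold-wise feature builders)
# ---------------------------------------------------------------------------

def pca_feature_builder(
    source_epochs: SourceEpochs,
    var_frac: float = 0.70,
    task_window: tuple[float, float] = (-1.0, 2.0),
    decim: int = 1,
):
    """Builder: ROI PCA loadings fitted on the training trials only.

    Features are the retained components' time courses over the task
    period, concatenated.  ``decim`` subsamples the feature time grid --
    band-limited source series are heavily oversampled at 300 Hz (the
    low-frequency virtual-channel pipeline similarly works on a 30 Hz
    grid).
    """
    from .source import roi_pca

    tidx = np.flatnonzero(source_epochs.time_mask(task_window))[::decim]

    def build(train_idx, test_idx):
        sub = source_epochs.copy(
            data=source_epochs.data[train_idx],
            labels=source_epochs.labels[train_idx],
        )
        comps, _, _ = roi_pca(sub, var_frac=var_frac)
        def proj(idx):
            sc = np.einsum("kv,tvs->tks", comps, source_epochs.data[idx][:, :, tidx])
            return sc.reshape(len(idx), -1)
        return proj(train_idx), proj(test_idx)

    return build


def _task_mean_map(trial_values: np.ndarray, labels: np.ndarray, idx) -> np.ndarray:
    sel_v = trial_values[idx]
    sel_y = labels[idx]
    return np.stack(
        [np.nanmean(sel_v[sel_y == k], axis=0) for k in range(N_TASKS)]
    )


def a_epoch_feature_builder(
    source_epochs: SourceEpochs,
    amap: ActivationMap,
    task_window: tuple[float, float] = (-1.0, 2.0),
    decim: int = 1,
):
    """Builder: A-epoch extrema vertices selected on the training fold.

    The task-averaged map is recomputed from training trials, its 8
    extrema (max + min per task, duplicates retained) picked, and the
    source time courses at those vertices over the task period used as
    features.
    """
    if amap.windowed:
        raise ValueError("need the full-epoch activation map")
    tidx = np.flatnonzero(source_epochs.time_mask(task_window))[::decim]

    def build(train_idx, test_idx):
        mean_map = _task_mean_map(amap.trial_values, amap.labels, train_idx)
        ext = extrema_vertices(mean_map).ravel()  # 8 vertices
        def feats(idx):
            seg = source_epochs.data[idx][:, ext, :][:, :, tidx]
            return seg.reshape(len(idx), -1)
        return feats(train_idx), feats(test_idx)

    return build


def a_window_feature_builder(
    source_epochs: SourceEpochs,
    awin: ActivationMap,
    decim: int = 1,
):
    """Builder: per-window extrema vertices from training-fold A-window maps.

    For each window the 8 extrema vertices are found on the training
    trials' task-averaged map and that window's source segment at those
    vertices extracted; segments are concatenated over windows in
    temporal order.  The dimensionality equals the A-epoch features
    (8 vertices x all task-period samples).
    """
    if not awin.windowed:
        raise ValueError("need a windowed activation map")
    sfreq = source_epochs.sfreq
    spw = int(round(awin.window_length * sfreq))
    starts = np.round(
        (awin.window_starts - source_epochs.t0) * sfreq
    ).astype(int)

    def build(train_idx, test_idx):
        mean_map = _task_mean_map(awin.trial_values, awin.labels, train_idx)
        ext = extrema_vertices(mean_map)  # (n_win, n_tasks, 2)
        def feats(idx):
            parts = []
            for w, s0 in enumerate(starts):
                verts = ext[w].ravel()
                seg = source_epochs.data[idx][:, verts, s0 : s0 + spw : decim]
                parts.append(seg.reshape(len(idx), -1))
            return np.concatenate(parts, axis=1)
        return feats(train_idx), feats(test_idx)

    return build


def decode_pca(source_epochs, folds=5, seed=0, C=1.0, var_frac=0.70,
               task_window=(-1.0, 2.0), decim=1) -> DecodingResult:
    """PCA-based classification (whole-ROI temporal features)."""
    return cv_ovr_linear(
        None, source_epochs.labels, folds=folds, seed=seed, C=C,
        feature_builder=pca_feature_builder(
            source_epochs, var_frac, task_window, decim
        ),
    )


def decode_a_epoch(source_epochs, amap, folds=5, seed=0, C=1.0,
                   task_window=(-1.0, 2.0), decim=1) -> DecodingResult:
    """A-epoch-based classification (8 extrema-vertex time courses)."""
    return cv_ovr_linear(
        None, source_epochs.labels, folds=folds, seed=seed, C=C,
        feature_builder=a_epoch_feature_builder(
            source_epochs, amap, task_window, decim
        ),
    )


def decode_a_window(source_epochs, awin, folds=5, seed=0, C=1.0, decim=1) -> DecodingResult:
    """A-window-based classification (time-resolved extrema segments)."""
    return cv_ovr_linear(
        None, source_epochs.labels, folds=folds, seed=seed, C=C,
        feature_builder=a_window_feature_builder(source_epochs, awin, decim),
    )


# ---------------------------------------------------------------------------
# virtual channels
# ---------------------------------------------------------------------------

def _spans_to_window_indices(spans, window_starts) -> np.ndarray:
    starts = np.asarray(window_starts)
    keep = np.zeros(starts.size, bool)
    for lo, hi in spans:
        keep |= (starts >= lo - 1e-9) & (starts <= hi + 1e-9)
    return np.flatnonzero(keep)


def build_virtual_channels(
    windowwise_result: DecodingResult,
    pointwise_result: DecodingResult,
    windowed_extrema: np.ndarray,
    window_starts: np.ndarray,
    window_length: float,
) -> VirtualChannelSet:
    """Select virtual channels from significantly decodable windows.

    ``windowwise_result.significant_spans`` and
    ``pointwise_result.significant_spans`` must have been filled by the
    cluster-permutation machinery (accuracy vs the 25% chance level).
    Each significant window contributes 8 channels: the max- and min-A
    vertices of each task in that window.  An empty selection is returned
    flagged (``.empty``) when no window survives.
    """
    for res, name in ((windowwise_result, "window-wise"), (pointwise_result, "point-wise")):
        if res.significant_spans is None:
            raise ValueError(
                f"{name} result carries no significance spans; run the cluster "
                "permutation test first"
            )
    win_idx = _spans_to_window_indices(
        windowwise_result.significant_spans, window_starts
    )
    entries = []
    for w in win_idx:
        for task in range(windowed_extrema.shape[1]):
            entries.append((int(w), task, "max", int(windowed_extrema[w, task, 0])))
            entries.append((int(w), task, "min", int(windowed_extrema[w, task, 1])))
    if not entries:
        warnings.warn("no significantly decodable window: empty virtual-channel set")
    return VirtualChannelSet(
        entries=entries,
        decodable_windows=win_idx,
        decodable_timespans=list(pointwise_result.significant_spans),
        window_starts=np.asarray(window_starts),
        window_length=window_length,
    )


def _resample_epochs(epochs: Epochs, sfreq_out: float) -> Epochs:
    frac = Fraction(sfreq_out / epochs.sfreq).limit_denominator(1000)
    data = scisig.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    return epochs.copy(data=data, sfreq=sfreq_out)


def single_vs_combined(
    source_epochs: SourceEpochs,
    vcs: VirtualChannelSet,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    resample_sfreq: float | None = 30.0,
) -> tuple[dict, DecodingResult | None]:
    """Single-window vs window-combined virtual-channel classification.

    Each decodable window contributes its 8 virtual channels over its own
    time segment, intersected with the decodable point-wise timespans
    (falling back to the window's span when the intersection is empty on
    the resampled grid).  The single-window scheme classifies from one
    window's features; the combined scheme concatenates the features of
    all decodable windows in temporal order.  Low-frequency
    virtual-channel series are downsampled to ``resample_sfreq`` (30 Hz
    by default) before segment extraction to limit dimensionality.  Both
    schemes share identical CV folds.  Returns
    ``({window_idx: DecodingResult}, combined_result)``; empty input
    yields ``({}, None)``.
    """
    if vcs.empty:
        warnings.warn("empty virtual-channel set: nothing to decode")
        return {}, None
    ep = source_epochs
    if resample_sfreq is not None and resample_sfreq < ep.sfreq:
        ep = _resample_epochs(ep, resample_sfreq)
    decodable = np.zeros(ep.n_samples, bool)
    for lo, hi in vcs.decodable_timespans:
        decodable |= ep.time_mask((lo, hi + 1.0 / ep.sfreq))
    if not decodable.any():
        warnings.warn("decodable point-wise spans select no samples")
        return {}, None

    singles = {}
    feature_blocks = []
    for w in vcs.decodable_windows:
        verts = vcs.vertices_for_window(int(w))
        t_lo = float(vcs.window_starts[int(w)])
        wmask = ep.time_mask((t_lo, t_lo + vcs.window_length))
        seg = wmask & decodable
        if not seg.any():
            seg = wmask
        X = ep.data[:, verts, :][:, :, seg].reshape(ep.n_trials, -1)
        feature_blocks.append(X)
        singles[int(w)] = cv_ovr_linear(X, ep.labels, folds=folds, seed=seed, C=C)
    Xc = np.concatenate(feature_blocks, axis=1)
    combined = cv_ovr_linear(Xc, ep.labels, folds=folds, seed=seed, C=C)
    return singles, combined


# ---------------------------------------------------------------------------
# power-feature variant
# ---------------------------------------------------------------------------

def power_features(
    signals: np.ndarray,
    sfreq: float,
    freqs,
    n_cycles: float = 4.0,
    decim: int = 5,
) -> np.ndarray:
    """Morlet power of ``(trials, k, samples)`` signals as flat features.

    Power is averaged over the frequency grid and decimated in time.
    """
    from mne.time_frequency import tfr_array_morlet

    x = np.asarray(signals, float)
    p = tfr_array_morlet(
        x, sfreq=sfreq, freqs=np.atleast_1d(freqs), n_cycles=n_cycles, output="power"
    )
    p = p.mean(axis=2)[:, :, ::decim]  # average over freqs, decimate time
    return p.reshape(x.shape[0], -1)


def decode_power(
    source_epochs: SourceEpochs,
    amap: ActivationMap,
    freqs,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    task_window: tuple[float, float] = (-1.0, 2.0),
    n_cycles: float = 4.0,
    decim: int = 5,
) -> DecodingResult:
    """A-epoch extrema pipeline with TFR-power features instead of time series."""
    if amap.windowed:
        raise ValueError("need the full-epoch activation map")
    tmask = source_epochs.time_mask(task_window)

    def build(train_idx, test_idx):
        mean_map = _task_mean_map(amap.trial_values, amap.labels, train_idx)
        ext = extrema_vertices(mean_map).ravel()
        def feats(idx):
            seg = source_epochs.data[idx][:, ext, :]
            f = power_features(seg, source_epochs.sfreq, freqs, n_cycles, decim)
            # restrict to the task period on the decimated grid
            full = f.reshape(len(idx), len(ext), -1)
            grid = np.arange(source_epochs.n_samples)[::decim]
            return full[:, :, tmask[grid]].reshape(len(idx), -1)
        return feats(train_idx), feats(test_idx)

    return cv_ovr_linear(
        None, source_epochs.labels, folds=folds, seed=seed, C=C, feature_builder=build
    )
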