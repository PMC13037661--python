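"""LCMV beamforming, activation-index maps, extrema vertices, and ROI PCA.

The spatial filter for a vertex with effective leadfield l (channels
vector) is the linearly constrained minimum-variance solution

    w = C^-1 l / (l^T C^-1 l),

which minimizes output variance subject to unit gain w @ l = 1.  The
source orientation at each vertex is chosen as the direction of maximal
reconstructed variance: the vector beamformer output covariance (3 x 3)
is eigendecomposed and the dominant eigenvector taken.

The activation index contrasts task against baseline power per vertex
and trial i:

    A(i) = (w Cs(i) w^T - w Cb(i) w^T) / (w Cs(i) w^T + w Cb(i) w^T),

with Cs(i) and Cb(i) the channel covariances of the task and baseline
windows of trial i.  A lies in (-1, 1) whenever both quadratic forms are
positive, vanishes when they are equal, and flips sign when the windows
are swapped.  Per-trial values are averaged across trials of each task.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import (
    ActivationMap,
    BeamformerFit,
    Epochs,
    N_TASKS,
    SourceEpochs,
    SourceModel,
)

__all__ = [
    "data_covariance",
    "fit_lcmv",
    "reconstruct",
    "activation_index",
    "activation_index_from_cov",
    "a_window_maps",
    "extrema_vertices",
    "roi_pca",
]


def data_covariance(epochs: Epochs, ddof: int = 1) -> np.ndarray:
    """Channel covariance pooled over all trials and samples.

    The per-channel mean over the pooled samples is removed; the result
    is symmetrized to guard against round-off.
    """
    x = epochs.data
    if not np.all(np.isfinite(x)):
        raise ValueError("epochs contain non-finite values")
    n_total = x.shape[0] * x.shape[2]
    if n_total < x.shape[1] + 1:
        raise ValueError("need at least n_channels + 1 pooled samples")
    flat = np.swapaxes(x, 0, 1).reshape(x.shape[1], -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    cov = flat @ flat.T / (n_total - ddof)
    return 0.5 * (cov + cov.T)


def _regularized_inverse(cov: np.ndarray, reg: float) -> np.ndarray:
    c = np.asarray(cov, float)
    if reg < 0:
        raise ValueError("reg must be nonnegative")
    if reg > 0:
        c = c + reg * np.mean(np.diag(c)) * np.eye(c.shape[0])
    # detect effective singularity before inverting
    w = np.linalg.eigvalsh(c)
    if w[0] <= 0 or w[0] / w[-1] < 1e-14:
        raise np.linalg.LinAlgError(
            "covariance is singular; use reg > 0 (Tikhonov loading)"
        )
    return np.linalg.inv(c)


def fit_lcmv(
    source_model: SourceModel,
    covariance: np.ndarray,
    reg: float = 0.05,
) -> BeamformerFit:
    """Fit unit-gain LCMV filters with max-variance orientation per vertex.

    For each vertex the free-orientation (3-column) leadfield is combined
    with the regularized inverse covariance to form the vector beamformer;
    the 3 x 3 reconstructed covariance is eigendecomposed and the filter
    re-derived along the dominant eigenvector, rescaled to exact unit
    gain.  The sphere forward model is blind to radial sources, so the
    orientation search runs in the leadfield's numerical column space.
    """
    cov = 0.5 * (np.asarray(covariance, float) + np.asarray(covariance, float).T)
    cinv = _regularized_inverse(cov, reg)
    if source_model.leadfield_free is not None:
        lf = source_model.leadfield_free  # (C, V, 3)
    else:
        lf = source_model.leadfield[:, :, None]  # fixed orientation only
    V = source_model.n_vertices
    C = cov.shape[0]
    weights = np.empty((V, C))
    orientation = np.empty((V, 3))
    for v in range(V):
        Lv = lf[:, v, :]  # (C, n_ori)
        # restrict the search to the numerically non-silent orientation subspace
        _, s_svd, vt_svd = np.linalg.svd(Lv, full_matrices=False)
        r = int(np.sum(s_svd > 1e-8 * s_svd[0]))
        Vr = vt_svd[:r].T  # (n_ori, r) orientation basis
        Lr = Lv @ Vr  # (C, r)
        M = Lr.T @ cinv @ Lr  # (r, r)
        W3 = np.linalg.solve(M, Lr.T @ cinv)  # (r, C) vector beamformer
        S = W3 @ cov @ W3.T
        _, evecs = np.linalg.eigh(0.5 * (S + S.T))
        u_r = evecs[:, -1]  # direction of maximal reconstructed variance
        l_eff = Lr @ u_r
        ori3 = Vr @ u_r  # back to head coordinates
        if ori3.shape[0] != 3:  # fixed-orientation leadfield fallback
            ori3 = np.pad(ori3, (0, 3 - ori3.shape[0]))
        nrm = np.linalg.norm(ori3)
        ori3 = ori3 / nrm if nrm > 0 else ori3
        # fix the sign convention: largest-|component| positive
        j = int(np.argmax(np.abs(ori3)))
        if ori3[j] < 0:
            ori3 = -ori3
            l_eff = -l_eff
        ci_l = cinv @ l_eff
        denom = float(l_eff @ ci_l)
        if denom <= 0:
            raise np.linalg.LinAlgError(
                f"vertex {v}: degenerate leadfield/covariance combination"
            )
        weights[v] = ci_l / denom
        orientation[v] = ori3
    return BeamformerFit(
        weights=weights, orientation=orientation, reg=reg, data_cov=cov
    )


def reconstruct(epochs: Epochs, fit: BeamformerFit) -> SourceEpochs:
    """Project sensor epochs to source space: one time course per vertex."""
    if epochs.n_channels != fit.weights.shape[1]:
        raise ValueError(
            f"channel mismatch: epochs have {epochs.n_channels}, "
            f"filters expect {fit.weights.shape[1]}"
        )
    data = np.einsum("vc,tcs->tvs", fit.weights, epochs.data)
    return epochs.copy(data=data, space="source", channel_names=None)


def activation_index_from_cov(
    w: np.ndarray, cov_task: np.ndarray, cov_baseline: np.ndarray
) -> float:
    """A = (w Cs w^T - w Cb w^T) / (w Cs w^T + w Cb w^T) for one vertex."""
    w = np.asarray(w, float)
    ps = float(w @ np.asarray(cov_task, float) @ w)
    pb = float(w @ np.asarray(cov_baseline, float) @ w)
    denom = ps + pb
    if denom == 0:
        return np.nan
    return (ps - pb) / denom


def _window_power(
    source_data: np.ndarray, mask: np.ndarray, demean: bool
) -> np.ndarray:
    """Per-trial, per-vertex power of the samples selected by ``mask``.

    Equal to the quadratic form w C w^T with C the (biased, 1/n) window
    covariance of the sensor channels: projecting first and taking the
    (1/n) variance of the projected time course is algebraically the same
    quantity.
    """
    seg = source_data[:, :, mask]
    if demean:
        seg = seg - seg.mean(axis=2, keepdims=True)
    return np.mean(seg**2, axis=2)


def _trial_average(trial_values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    tasks = np.arange(N_TASKS)
    out = np.stack(
        [np.nanmean(trial_values[labels == k], axis=0) for k in tasks]
    )
    return out


def activation_index(
    fit: BeamformerFit,
    epochs: Epochs,
    task_window: tuple[float, float] = (-1.0, 2.0),
    baseline_window: tuple[float, float] = (-2.0, -1.5),
    demean: bool = True,
) -> ActivationMap:
    """Full-epoch activation-index map (A-epoch), per trial then averaged.

    ``demean=True`` uses mean-removed window covariances; ``False`` uses
    raw second-moment matrices.  Vertices where both quadratic forms are
    zero get NaN with a warning.
    """
    for name, win in (("task", task_window), ("baseline", baseline_window)):
        m = epochs.time_mask(win)
        if not m.any():
            raise ValueError(f"{name} window {win} lies outside the epoch")
    src = reconstruct(epochs, fit)
    ms = epochs.time_mask(task_window)
    mb = epochs.time_mask(baseline_window)
    ps = _window_power(src.data, ms, demean)
    pb = _window_power(src.data, mb, demean)
    denom = ps + pb
    zero = denom == 0
    if zero.any():
        warnings.warn(f"activation_index: {zero.sum()} undefined (0/0) entries -> NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        a_trial = np.where(zero, np.nan, (ps - pb) / denom)
    return ActivationMap(
        values=_trial_average(a_trial, epochs.labels),
        trial_values=a_trial,
        labels=epochs.labels.copy(),
        task_window=task_window,
        baseline_window=baseline_window,
    )


def a_window_maps(
    fit: BeamformerFit,
    epochs: Epochs,
    window: float = 0.050,
    span: tuple[float, float] = (-1.0, 2.0),
    baseline_window: tuple[float, float] = (-2.0, -1.5),
    demean: bool = True,
) -> ActivationMap:
    """Windowed activation-index maps: nonoverlapping ``window``-second tiles.

    Each tile's covariance is contrasted against the fixed baseline
    window.  With the defaults (50 ms over [-1, 2) at 300 Hz) this yields
    exactly 60 windows of 15 samples.
    """
    spw_f = window * epochs.sfreq
    spw = int(round(spw_f))
    if abs(spw_f - spw) > 1e-9 or spw < 1:
        raise ValueError(
            f"window of {window} s is not an integer number of samples at "
            f"{epochs.sfreq} Hz"
        )
    span_samples = (span[1] - span[0]) * epochs.sfreq
    n_win = int(round(span_samples / spw))
    if abs(span_samples - n_win * spw) > 1e-6:
        raise ValueError("span is not divisible by the window length on the sample grid")

    src = reconstruct(epochs, fit)
    mb = epochs.time_mask(baseline_window)
    pb = _window_power(src.data, mb, demean)  # (trials, V)

    start = int(round((span[0] - epochs.t0) * epochs.sfreq))
    if start < 0 or start + n_win * spw > epochs.n_samples:
        raise ValueError("span lies outside the epoch")
    seg = src.data[:, :, start : start + n_win * spw]
    seg = seg.reshape(seg.shape[0], seg.shape[1], n_win, spw)
    if demean:
        seg = seg - seg.mean(axis=3, keepdims=True)
    ps = np.mean(seg**2, axis=3)  # (trials, V, n_win)

    denom = ps + pb[:, :, None]
    zero = denom == 0
    if zero.any():
        warnings.warn(f"a_window_maps: {zero.sum()} undefined (0/0) entries -> NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        a_trial = np.where(zero, np.nan, (ps - pb[:, :, None]) / denom)
    win_starts = span[0] + np.arange(n_win) * window
    return ActivationMap(
        values=_trial_average(a_trial, epochs.labels),
        trial_values=a_trial,
        labels=epochs.labels.copy(),
        task_window=span,
        baseline_window=baseline_window,
        window_length=window,
        window_starts=win_starts,
    )


def extrema_vertices(amap_values: np.ndarray | ActivationMap) -> np.ndarray:
    """Per-task argmax/argmin vertices of a trial-averaged activation map.

    For an epoch map ``(n_tasks, V)`` returns ``(n_tasks, 2)`` with
    columns (max_vertex, min_vertex) -- eight vertices for four tasks.
    For a windowed map ``(n_tasks, V, n_windows)`` returns
    ``(n_windows, n_tasks, 2)``.  NaNs are excluded; exact ties break to
    the lowest vertex index; duplicates across tasks are retained.
    """
    vals = amap_values.values if isinstance(amap_values, ActivationMap) else np.asarray(amap_values)
    if vals.ndim == 2:
        if np.all(np.isnan(vals)):
            raise ValueError("activation map is all-NaN")
        out = np.empty((vals.shape[0], 2), dtype=int)
        for k in range(vals.shape[0]):
            out[k, 0] = int(np.nanargmax(vals[k]))
            out[k, 1] = int(np.nanargmin(vals[k]))
        return out
    if vals.ndim == 3:
        n_tasks, V, n_win = vals.shape
        if np.all(np.isnan(vals)):
            raise ValueError("activation map is all-NaN")
        out = np.empty((n_win, n_tasks, 2), dtype=int)
        for w in range(n_win):
            for k in range(n_tasks):
                col = vals[k, :, w]
                out[w, k, 0] = int(np.nanargmax(col))
                out[w, k, 1] = int(np.nanargmin(col))
        return out
    raise ValueError("expected a (tasks, V) or (tasks, V, windows) map")


def roi_pca(
    source_epochs: SourceEpochs, var_frac: float = 0.70
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial PCA over the vertex dimension of reconstructed signals.

    Computed on trial-concatenated, time-demeaned data.  Retains the
    smallest leading component set whose cumulative explained variance
    exceeds ``var_frac``.

    Returns
    -------
    components : (n_comp, V) spatial loadings.
    scores : (n_trials, n_comp, n_samples) component time courses.
    explained : (n_comp,) explained-variance ratios of the retained set.
    """
    if not 0 < var_frac <= 1:
        raise ValueError("var_frac must lie in (0, 1]")
    x = source_epochs.data
    if x.shape[1] < 2:
        raise ValueError("need at least 2 vertices")
    flat = np.swapaxes(x, 0, 1).reshape(x.shape[1], -1)  # (V, trials*samples)
    flat = flat - flat.mean(axis=1, keepdims=True)
    # SVD of the vertex x time matrix; eigenvectors of the spatial covariance
    u, s, _ = np.linalg.svd(flat, full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    csum = np.cumsum(ratio)
    n_comp = int(np.searchsorted(csum, var_frac, side="right")) + 1
    n_comp = min(n_comp, len(s))
    comps = u[:, :n_comp].T  # (n_comp, V)
    scores = np.einsum("kv,tvs->tks", comps, x)
    return comps, scores, ratio[:n_comp]
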