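"""EMG envelope extraction, movement-onset/offset detection, and decoding.

The movement-initiation threshold for each trial is T = mu + k*sigma,
where mu and sigma are the mean and standard deviation of the trial's
processed envelope and k defaults to 2.  The first sample strictly above
T marks movement onset; the last sample of the final above-threshold run
marks movement offset.  Reaction time is cue-to-onset, movement time is
onset-to-offset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .containers import DecodingResult, EMGEpochs, MovementTiming

__all__ = [
    "emg_envelope",
    "detect_onset_offset",
    "detect_timings",
    "timings_to_frame",
    "emg_decode",
]


def emg_envelope(
    raw: EMGEpochs,
    l_freq: float = 20.0,
    h_freq: float = 450.0,
    smooth_freq: float = 50.0,
    order: int = 4,
) -> EMGEpochs:
    """Band-pass, full-wave rectify, and low-pass smooth raw EMG.

    All filters are zero-phase (Butterworth of the given order applied
    forward-backward), so the envelope carries no group delay -- a
    requirement for onset timing.
    """
    nyq = raw.sfreq / 2.0
    if h_freq >= nyq:
        raise ValueError(
            f"band edge {h_freq} Hz must be below Nyquist {nyq} Hz"
        )
    if not 0 < l_freq < h_freq:
        raise ValueError("need 0 < l_freq < h_freq")
    sos_bp = signal.butter(order, [l_freq, h_freq], btype="bandpass", fs=raw.sfreq, output="sos")
    sos_lp = signal.butter(order, smooth_freq, btype="lowpass", fs=raw.sfreq, output="sos")
    x = signal.sosfiltfilt(sos_bp, raw.data, axis=-1)
    env = signal.sosfiltfilt(sos_lp, np.abs(x), axis=-1)
    return EMGEpochs(
        data=env, sfreq=raw.sfreq, cue_sample=raw.cue_sample, labels=raw.labels.copy()
    )


def detect_onset_offset(
    envelope_trial: np.ndarray,
    sfreq: float,
    cue_sample: int,
    k: float = 2.0,
    ddof: int = 1,
    baseline_window: tuple[int, int] | None = None,
    offset_rule: str = "last_above",
) -> MovementTiming:
    """Threshold-crossing movement timing for one envelope trace.

    T = mu + k*sigma is computed over the whole epoch by default (the
    epoch includes the burst); pass ``baseline_window`` (sample indices)
    to compute mu/sigma over a pre-cue segment instead.  Comparison with
    T is strict: samples exactly at T do not trigger onset.  If no sample
    exceeds T the trial is flagged invalid rather than raising.

    ``offset_rule``:

    * ``"last_above"`` (default): the last sample of the final
      above-threshold run, i.e. the sample immediately preceding the
      final drop below threshold;
    * ``"last_drop"``: the first sample of that final drop.
    """
    env = np.asarray(envelope_trial, float).ravel()
    if not np.all(np.isfinite(env)):
        raise ValueError("envelope contains non-finite values")
    if k < 0:
        raise ValueError("k must be nonnegative")
    if baseline_window is not None:
        lo, hi = baseline_window
        seg = env[lo:hi]
    else:
        seg = env
    mu = float(np.mean(seg))
    sigma = float(np.std(seg, ddof=ddof)) if seg.size > ddof else 0.0
    threshold = mu + k * sigma

    above = env > threshold
    if not np.any(above):
        return MovementTiming(
            onset_sample=None,
            offset_sample=None,
            reaction_time=None,
            movement_time=None,
            threshold=threshold,
            mu=mu,
            sigma=sigma,
            k=k,
            valid=False,
        )
    onset = int(np.argmax(above))
    last_above = int(len(env) - 1 - np.argmax(above[::-1]))
    if offset_rule == "last_above":
        offset = last_above
    elif offset_rule == "last_drop":
        offset = min(last_above + 1, len(env) - 1)
    else:
        raise ValueError(f"unknown offset_rule {offset_rule!r}")
    return MovementTiming(
        onset_sample=onset,
        offset_sample=offset,
        reaction_time=(onset - cue_sample) / sfreq,
        movement_time=(offset - onset) / sfreq,
        threshold=threshold,
        mu=mu,
        sigma=sigma,
        k=k,
        valid=True,
    )


def detect_timings(
    envelopes: EMGEpochs,
    k: float = 2.0,
    channel: int | str = "mean",
    **kwargs,
) -> list[MovementTiming]:
    """Per-trial movement timings.

    ``channel="mean"`` averages the envelope over EMG channels before
    thresholding; an integer picks a single channel.
    """
    out = []
    for i in range(envelopes.n_trials):
        if channel == "mean":
            env = envelopes.data[i].mean(axis=0)
        else:
            env = envelopes.data[i, int(channel)]
        out.append(
            detect_onset_offset(
                env, envelopes.sfreq, envelopes.cue_sample, k=k, **kwargs
            )
        )
    return out


def timings_to_frame(
    timings: list[MovementTiming], labels: np.ndarray, sfreq: float, cue_sample: int
) -> pd.DataFrame:
    """Tabulate timings for TSV export (trial, label, onset_s, offset_s, rt, mt)."""
    rows = []
    for i, tm in enumerate(timings):
        rows.append(
            {
                "trial": i,
                "label": int(labels[i]),
                "onset_s": (
                    np.nan
                    if tm.onset_sample is None
                    else (tm.onset_sample - cue_sample) / sfreq
                ),
                "offset_s": (
                    np.nan
                    if tm.offset_sample is None
                    else (tm.offset_sample - cue_sample) / sfreq
                ),
                "rt_s": np.nan if tm.reaction_time is None else tm.reaction_time,
                "mt_s": np.nan if tm.movement_time is None else tm.movement_time,
                "valid": tm.valid,
            }
        )
    return pd.DataFrame(rows)


def emg_decode(
    envelopes: EMGEpochs,
    timings: list[MovementTiming],
    window: tuple[float, float] = (-1.0, 2.0),
    folds: int = 5,
    seed: int = 0,
    decim: int = 1,
) -> DecodingResult:
    """Four-class decoding from onset-aligned EMG envelopes.

    Each trial's envelope is segmented from ``window[0]`` to ``window[1]``
    seconds around its detected movement onset and fed (all channels
    concatenated) to the linear one-versus-rest harness.  Trials flagged
    invalid, or whose window exceeds the epoch, are dropped with a warning.
    """
    from .decode import cv_ovr_linear

    n_lo = int(round(window[0] * envelopes.sfreq))
    n_hi = int(round(window[1] * envelopes.sfreq))
    feats, keep = [], []
    for i, tm in enumerate(timings):
        if not tm.valid or tm.onset_sample is None:
            continue
        lo = tm.onset_sample + n_lo
        hi = tm.onset_sample + n_hi
        if lo < 0 or hi > envelopes.n_samples:
            continue
        seg = envelopes.data[i, :, lo:hi:decim]
        feats.append(seg.ravel())
        keep.append(i)
    n_dropped = envelopes.n_trials - len(keep)
    if n_dropped:
        warnings.warn(f"emg_decode: dropped {n_dropped} invalid/out-of-range trials")
    X = np.asarray(feats)
    y = envelopes.labels[np.asarray(keep, dtype=int)]
    return cv_ovr_linear(X, y, folds=folds, seed=seed)
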