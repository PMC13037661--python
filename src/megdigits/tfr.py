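"""Morlet time-frequency responses, evoked/induced split, baseline t-maps.

Total power is the trial-average of single-trial Morlet power (4 cycles
by default).  The evoked response is the power of the trial-averaged
signal (phase-locked components survive the average); the induced
response is total minus evoked, exact by construction, and may be
pointwise negative where phase-locked power dominates a bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

__all__ = ["TFR", "morlet_tfr", "evoked_induced", "baseline_tmap"]


@dataclass
class TFR:
    """Time-frequency power with its grid and edge-validity mask."""

    power: np.ndarray  # (trials_or_1, n_freqs, n_samples)
    freqs: np.ndarray
    times: np.ndarray
    n_cycles: float
    kind: str  # total | evoked | induced
    valid: np.ndarray | None = None  # (n_freqs, n_samples) bool, False near edges

    @property
    def averaged(self) -> np.ndarray:
        return self.power.mean(axis=0)


def _as_trials_samples(data: np.ndarray) -> np.ndarray:
    x = np.asarray(data, float)
    if x.ndim == 3:
        if x.shape[1] != 1:
            raise ValueError(
                "pass single-channel data (trials, samples) or (trials, 1, samples); "
                "average or select a channel/vertex first"
            )
        x = x[:, 0, :]
    if x.ndim != 2:
        raise ValueError("expected (trials, samples) data")
    return x


def _check_freqs(freqs, sfreq, n_cycles, n_samples) -> np.ndarray:
    freqs = np.atleast_1d(np.asarray(freqs, float))
    if np.any(freqs >= sfreq / 2):
        raise ValueError("frequencies must be below Nyquist")
    epoch_len = n_samples / sfreq
    if np.any(freqs < n_cycles / epoch_len):
        raise ValueError(
            f"lowest frequency unresolvable: need f >= n_cycles/epoch_length "
            f"= {n_cycles / epoch_len:.3f} Hz"
        )
    return freqs


def _edge_mask(freqs, times, n_cycles) -> np.ndarray:
    """True where a sample is at least one wavelet half-width from both edges."""
    half = (n_cycles / freqs) / 2.0  # seconds, per frequency
    t0, t1 = times[0], times[-1]
    return (times[None, :] >= t0 + half[:, None]) & (
        times[None, :] <= t1 - half[:, None]
    )


def _power(x: np.ndarray, sfreq: float, freqs: np.ndarray, n_cycles: float) -> np.ndarray:
    """Single-trial Morlet power, shape (trials, n_freqs, n_samples)."""
    out = tfr_array_morlet(
        x[:, None, :], sfreq=sfreq, freqs=freqs, n_cycles=n_cycles, output="power"
    )
    return out[:, 0]


def morlet_tfr(
    signal_epochs,
    freqs,
    n_cycles: float = 4.0,
    sfreq: float | None = None,
    times: np.ndarray | None = None,
    keep_trials: bool = False,
):
    """Total TFR: per-trial Morlet power, averaged over trials.

    ``signal_epochs`` may be an :class:`~megdigits.containers.Epochs`
    restricted to one channel/vertex, or a raw ``(trials, samples)``
    array together with ``sfreq`` (and optionally ``times``).
    """
    if hasattr(signal_epochs, "sfreq"):
        x = _as_trials_samples(signal_epochs.data)
        sfreq = signal_epochs.sfreq
        times = signal_epochs.times
    else:
        x = _as_trials_samples(signal_epochs)
        if sfreq is None:
            raise ValueError("sfreq required for array input")
        if times is None:
            times = np.arange(x.shape[1]) / sfreq
    freqs = _check_freqs(freqs, sfreq, n_cycles, x.shape[1])
    p = _power(x, sfreq, freqs, n_cycles)
    if not keep_trials:
        p = p.mean(axis=0, keepdims=True)
    return TFR(
        power=p,
        freqs=freqs,
        times=np.asarray(times),
        n_cycles=n_cycles,
        kind="total",
        valid=_edge_mask(freqs, np.asarray(times), n_cycles),
    )


def evoked_induced(
    signal_epochs, freqs, n_cycles: float = 4.0, sfreq: float | None = None,
    times: np.ndarray | None = None,
) -> tuple[TFR, TFR]:
    """Split the total TFR into evoked and induced parts.

    evoked = power of the trial-averaged signal (phase-locked);
    induced = total - evoked (non-phase-locked), exact by construction.
    A single trial yields evoked = total and induced = 0 with a warning.
    """
    if hasattr(signal_epochs, "sfreq"):
        x = _as_trials_samples(signal_epochs.data)
        sfreq = signal_epochs.sfreq
        times = signal_epochs.times
    else:
        x = _as_trials_samples(signal_epochs)
        if sfreq is None:
            raise ValueError("sfreq required for array input")
        if times is None:
            times = np.arange(x.shape[1]) / sfreq
    times = np.asarray(times)
    freqs = _check_freqs(freqs, sfreq, n_cycles, x.shape[1])
    if x.shape[0] < 2:
        warnings.warn("single trial: evoked equals total, induced is zero")
    total = _power(x, sfreq, freqs, n_cycles).mean(axis=0, keepdims=True)
    evoked = _power(x.mean(axis=0, keepdims=True), sfreq, freqs, n_cycles)
    induced = total - evoked
    mask = _edge_mask(freqs, times, n_cycles)
    ev = TFR(evoked, freqs, times, n_cycles, "evoked", mask)
    ind = TFR(induced, freqs, times, n_cycles, "induced", mask)
    return ev, ind


def baseline_tmap(
    tfr_per_trial: TFR | np.ndarray,
    baseline_window: tuple[float, float],
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Paired t-statistic map of per-trial power vs per-trial baseline mean.

    For each (frequency, time) cell: one-sample t across trials of
    power(trial, f, t) - mean_{t' in baseline}(power(trial, f, t')).
    Zero-variance cells yield NaN with a warning.  Significance masking
    belongs to the cluster-permutation machinery in :mod:`megdigits.stats`.
    """
    if isinstance(tfr_per_trial, TFR):
        p = tfr_per_trial.power
        times = tfr_per_trial.times
    else:
        p = np.asarray(tfr_per_trial, float)
        if times is None:
            raise ValueError("times required for array input")
    if p.shape[0] < 2:
        raise ValueError("need per-trial power (>= 2 trials)")
    lo, hi = baseline_window
    eps = 0.5 * (times[1] - times[0])
    bmask = (times >= lo - eps) & (times < hi - eps)
    if not bmask.any():
        raise ValueError("baseline window lies outside the epoch")
    base = p[:, :, bmask].mean(axis=2)  # (trials, F)
    d = p - base[:, :, None]
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"baseline_tmap: {zero.sum()} zero-variance cells -> NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, np.nan, mean / (sd / np.sqrt(n)))
    return t
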