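"""Band-pass filtering, six-band decomposition, onset alignment and resampling.

The canonical band partition is delta (0.5-4 Hz), theta (4-8), alpha
(8-13), beta (13-30), gamma (30-60) and high-gamma (60-90).  All filters
are zero-phase 4th-order Butterworth applied forward-backward.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import SensorEpochs

__all__ = ["BandSpec", "BANDS", "bandpass", "make_bands", "align_and_resample"]


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi})")


BANDS = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 60.0),
    BandSpec("high_gamma", 60.0, 90.0),
)


def bandpass(
    epochs: SensorEpochs,
    lo: float,
    hi: float,
    order: int = 4,
    name: str | None = None,
) -> SensorEpochs:
    """Zero-phase Butterworth band-pass; trial order and labels preserved."""
    nyq = epochs.sfreq / 2.0
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band [{lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {nyq} Hz")
    if lo > 0:
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=epochs.sfreq, output="sos")
    else:
        sos = signal.butter(order, hi, btype="lowpass", fs=epochs.sfreq, output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy(data=data, band=name if name is not None else f"{lo:g}-{hi:g}Hz")


def make_bands(
    epochs: SensorEpochs, bands: tuple[BandSpec, ...] = BANDS
) -> dict[str, SensorEpochs]:
    """Decompose epochs into one band-passed copy per BandSpec."""
    return {b.name: bandpass(epochs, b.lo, b.hi, name=b.name) for b in bands}


def align_and_resample(
    epochs: SensorEpochs,
    onsets: np.ndarray,
    tmin: float = -2.0,
    tmax: float = 2.0,
    sfreq_out: float = 300.0,
) -> SensorEpochs:
    """Re-reference each trial's time axis to its movement onset and resample.

    ``onsets`` gives, per trial, the movement-onset time in seconds on the
    *current* time axis of ``epochs``.  The output grid is half-open
    ``[tmin, tmax)`` at ``sfreq_out`` with sample 0 of the new axis at the
    onset; resampling uses polyphase filtering (anti-aliased).

    Raises if any trial's requested window falls outside the recorded
    span, listing the offending trials.
    """
    onsets = np.asarray(onsets, float)
    if onsets.shape != (epochs.n_trials,):
        raise ValueError("need one onset per trial")

    frac = Fraction(sfreq_out / epochs.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if up / down * epochs.sfreq != sfreq_out:
        raise ValueError(
            f"cannot resample {epochs.sfreq} -> {sfreq_out} Hz with a small rational factor"
        )
    if up == down:
        res = epochs.data
    else:
        res = signal.resample_poly(epochs.data, up, down, axis=-1)
    n_res = res.shape[-1]
    n_out = int(round((tmax - tmin) * sfreq_out))

    starts = np.round((onsets + tmin - epochs.t0) * sfreq_out).astype(int)
    bad = [
        i
        for i, s in enumerate(starts)
        if s < 0 or s + n_out > n_res
    ]
    if bad:
        raise ValueError(
            f"requested window [{tmin}, {tmax}) exceeds available data for trials {bad}"
        )
    out = np.empty((epochs.n_trials, epochs.n_channels, n_out))
    for i, s in enumerate(starts):
        out[i] = res[i, :, s : s + n_out]
    return epochs.copy(data=out, sfreq=sfreq_out, t0=tmin)
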