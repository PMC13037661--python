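"""In-memory containers shared by all pipeline stages.

Conventions
-----------
* Epoched data are ``(n_trials, n_channels_or_vertices, n_samples)`` arrays.
* The epoch time grid is half-open ``[tmin, tmax)``: sample ``j`` sits at
  ``t0 + j / sfreq`` and ``tmax`` itself is never a sample.  This makes
  non-overlapping 50-ms window tilings exact (60 windows over ``[-1, 2)``
  at 300 Hz, 15 samples each, no shared boundary sample).
* ``t0`` is the time of the first sample relative to movement onset
  (EMG-defined 0 ms), in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

TASK_NAMES = ("thumb", "index", "middle", "little")
N_TASKS = 4


def _as_array(x, dtype=None) -> np.ndarray:
    a = np.asarray(x)
    if dtype is not None:
        a = a.astype(dtype, copy=False)
    return a


@dataclass
class Epochs:
    """Epoched multichannel time series with task labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Sensor field values, source amplitudes, or EMG voltages.
    sfreq : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds relative to movement onset.
    labels : ndarray of int, shape (n_trials,)
        Task class per trial (0..3 for the four fingers).
    band : str
        Frequency-band tag: ``broadband``, ``delta``, ``theta``, ``alpha``,
        ``beta``, ``gamma`` or ``high_gamma``.
    space : str
        ``"sensor"``, ``"source"`` or ``"emg"``.
    """

    data: np.ndarray
    sfreq: float
    t0: float
    labels: np.ndarray
    band: str = "broadband"
    space: str = "sensor"
    channel_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.data = _as_array(self.data)
        self.labels = _as_array(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples), got ndim={self.data.ndim}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"trial count {self.data.shape[0]}"
            )
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Half-open time grid ``t0 + j/sfreq``."""
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for the half-open interval ``[lo, hi)``."""
        lo, hi = window
        t = self.times
        # guard against float fuzz on the grid boundaries
        eps = 0.5 / self.sfreq
        return (t >= lo - eps) & (t < hi - eps)

    def copy(self, **changes) -> "Epochs":
        out = dataclasses.replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "labels" not in changes:
            out.labels = self.labels.copy()
        return out


# Aliases that document intent at call sites.
SensorEpochs = Epochs
SourceEpochs = Epochs


@dataclass
class EMGEpochs:
    """Epoched EMG traces aligned to the visual cue.

    ``cue_sample`` indexes the cue onset within each trial; reaction time
    is measured from this sample to the detected movement onset.
    """

    data: np.ndarray
    sfreq: float
    cue_sample: int
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.data = _as_array(self.data)
        self.labels = _as_array(self.labels, dtype=np.int64)
        if self.data.ndim == 2:  # single-channel convenience
            self.data = self.data[:, None, :]
        if self.data.ndim != 3:
            raise ValueError("EMG data must be (trials, channels, samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if not 0 <= self.cue_sample < self.data.shape[2]:
            raise ValueError("cue_sample must lie within the epoch")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class SourceModel:
    """ROI source space plus forward model.

    ``leadfield`` holds the gain for each vertex's *fixed* orientation
    (used when simulating); ``leadfield_free`` holds the three Cartesian
    orientation columns per vertex (used by the beamformer's orientation
    search).
    """

    vertex_positions: np.ndarray  # (V, 3), metres, head frame
    vertex_orientations: np.ndarray  # (V, 3), unit vectors
    leadfield: np.ndarray  # (C, V)
    leadfield_free: np.ndarray | None = None  # (C, V, 3)
    roi_labels: np.ndarray | None = None
    sensor_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertex_positions = _as_array(self.vertex_positions, float)
        self.vertex_orientations = _as_array(self.vertex_orientations, float)
        self.leadfield = _as_array(self.leadfield, float)
        V = self.vertex_positions.shape[0]
        if V < 2:
            raise ValueError("need at least 2 vertices")
        norms = np.linalg.norm(self.vertex_orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("vertex orientations must have unit norm")
        if self.leadfield.shape[1] != V:
            raise ValueError("leadfield column count must equal vertex count")
        col_norms = np.linalg.norm(self.leadfield, axis=0)
        if np.any(col_norms == 0):
            raise ValueError("leadfield has an all-zero column")

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]

    @property
    def n_channels(self) -> int:
        return self.leadfield.shape[0]

    def neighborhood(self, vertex: int, frac: float = 0.05) -> np.ndarray:
        """Indices of the closest ``frac`` of vertices to ``vertex``
        (by Euclidean distance, the vertex itself included)."""
        d = np.linalg.norm(
            self.vertex_positions - self.vertex_positions[vertex], axis=1
        )
        k = max(1, int(np.ceil(frac * self.n_vertices)))
        return np.argsort(d)[:k]


@dataclass
class GroundTruth:
    """Generating parameters recorded by the simulator for recovery tests."""

    task_labels: np.ndarray
    active_vertex_sets: dict = field(default_factory=dict)  # (task, band) -> indices
    emg_onsets: np.ndarray | None = None  # sample indices per trial
    emg_offsets: np.ndarray | None = None
    band_envelopes: dict = field(default_factory=dict)  # band -> (times, envelope)

    def __post_init__(self) -> None:
        if self.emg_onsets is not None and self.emg_offsets is not None:
            if np.any(np.asarray(self.emg_onsets) >= np.asarray(self.emg_offsets)):
                raise ValueError("every EMG onset must precede its offset")


@dataclass
class BeamformerFit:
    """Per-vertex LCMV spatial filters.

    ``weights[v]`` is the row vector w applied to sensor data; it satisfies
    the unit-gain constraint w @ l_eff = 1 where ``l_eff`` is the leadfield
    along the chosen orientation.
    """

    weights: np.ndarray  # (V, C)
    orientation: np.ndarray  # (V, 3)
    reg: float
    data_cov: np.ndarray  # (C, C)

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


@dataclass
class ActivationMap:
    """Task-vs-baseline activation index A per vertex.

    ``values`` is the trial-averaged map: ``(n_tasks, n_vertices)`` for the
    full-epoch map or ``(n_tasks, n_vertices, n_windows)`` for 50-ms window
    maps.  ``trial_values`` keeps the per-trial indices used for decoding
    (``(n_trials, n_vertices[, n_windows])``).
    """

    values: np.ndarray
    trial_values: np.ndarray
    labels: np.ndarray
    task_window: tuple[float, float]
    baseline_window: tuple[float, float]
    window_length: float | None = None  # seconds; None for the epoch map
    window_starts: np.ndarray | None = None  # seconds, one per window

    @property
    def windowed(self) -> bool:
        return self.window_length is not None

    @property
    def n_windows(self) -> int:
        return 1 if not self.windowed else self.values.shape[2]


@dataclass
class MovementTiming:
    """EMG threshold-crossing result for one trial (threshold T = mu + k*sigma)."""

    onset_sample: int | None
    offset_sample: int | None
    reaction_time: float | None
    movement_time: float | None
    threshold: float
    mu: float
    sigma: float
    k: float
    valid: bool

    def __post_init__(self) -> None:
        expected = self.mu + self.k * self.sigma
        if not np.isclose(self.threshold, expected, rtol=1e-12, atol=0.0):
            raise ValueError("threshold must equal mu + k*sigma")
        if self.valid and self.onset_sample is not None and self.offset_sample is not None:
            if self.onset_sample > self.offset_sample:
                raise ValueError("onset must not follow offset")


@dataclass
class DecodingResult:
    """Cross-validated classification outcome.

    ``confusion`` aggregates counts over folds with rows = true class and
    columns = predicted class; ``per_class_accuracy`` is the class-conditional
    recall (diagonal / row sum).
    """

    fold_accuracies: np.ndarray
    confusion: np.ndarray
    series: np.ndarray | None = None  # mean accuracy per time point / window
    series_folds: np.ndarray | None = None  # (folds, n_points)
    series_times: np.ndarray | None = None  # seconds
    significant_spans: list | None = None  # [(t_lo, t_hi), ...] from stats
    meta: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def per_class_accuracy(self) -> np.ndarray:
        row = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.confusion) / row, np.nan)

    @property
    def overall_accuracy(self) -> float:
        """trace / total of the aggregated confusion matrix."""
        return float(np.trace(self.confusion) / self.confusion.sum())

    def summary(self) -> str:
        lines = [
            "Decoding result",
            "---------------",
            f"mean accuracy : {self.mean_accuracy:.4f} (sd {self.sd:.4f}, "
            f"{len(self.fold_accuracies)} folds)",
            f"chance level  : {1.0 / self.confusion.shape[0]:.4f}",
        ]
        for i, acc in enumerate(self.per_class_accuracy):
            name = TASK_NAMES[i] if i < len(TASK_NAMES) else str(i)
            lines.append(f"  recall[{name:>6s}] : {acc:.4f}")
        if self.series is not None:
            lines.append(f"series        : {self.series.size} points, "
                         f"peak {np.nanmax(self.series):.4f}")
        return "\n".join(lines)


@dataclass
class VirtualChannelSet:
    """Beamformer virtual channels chosen from decodable 50-ms windows.

    One entry per (window, task, polarity): the vertex whose activation
    index was extremal for that task in that window.
    """

    entries: list  # of (window_idx, task, polarity, vertex)
    decodable_windows: np.ndarray  # window indices
    decodable_timespans: list  # [(t_lo, t_hi), ...] from point-wise decoding
    window_starts: np.ndarray | None = None
    window_length: float | None = None

    @property
    def empty(self) -> bool:
        return len(self.entries) == 0

    def vertices_for_window(self, window_idx: int) -> np.ndarray:
        return np.array(
            [e[3] for e in self.entries if e[0] == window_idx], dtype=int
        )


@dataclass
class DigitMap:
    """Group-level per-window vertex labelling of finger preference."""

    labels: np.ndarray  # (n_windows, V), task id or -1 for unassigned
    accuracy: np.ndarray  # (n_windows, V) mean four-class accuracy
    per_class_accuracy: np.ndarray | None  # (n_windows, V, n_tasks)
    significant: np.ndarray  # (n_windows, V) bool
    counts: np.ndarray  # (n_windows, n_tasks)
    threshold: float
    window_starts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any((self.labels >= 0) & ~self.significant):
            raise ValueError("labels may only be assigned at significant vertices")
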