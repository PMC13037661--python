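"""Forward-model simulation of finger-movement MEG and EMG.

The generator produces sensor-space epochs with the statistical structure
the downstream analysis assumes, plus full ground truth, so that every
stage (beamforming, activation-index mapping, decoding, digit maps) can be
tested by parameter recovery without access to human recordings.

What is emulated
----------------
* Four task classes (thumb / index / middle / little extension).
* Phase-locked low-frequency (delta, theta) source bumps peaking near
  movement onset, on small task-specific vertex clusters -- the spatial
  substrate of finger decodability.
* alpha / beta oscillations with random phase per trial whose envelope
  dips before/during movement (ERD) and rebounds after movement offset
  (ERS), on a task-shared vertex set.
* Weak high-gamma bursts at onset.
* 1/f background activity at every vertex, plus spatially white sensor
  noise scaled to a configurable SNR.
* EMG: baseline noise plus an envelope-modulated burst with recorded true
  onset/offset; per-task amplitude and duration distributions make the
  four classes learnable.

The forward model is the homogeneous single-sphere magnetic dipole field
(Sarvas closed form) sampled by radial magnetometers on an outer sensor
shell; radial dipoles are magnetically silent in this model, so simulated
orientations are constrained to the local tangential plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    EMGEpochs,
    GroundTruth,
    N_TASKS,
    SensorEpochs,
    SourceModel,
)

__all__ = [
    "SimulationConfig",
    "EMGConfig",
    "make_source_model",
    "simulate_meg",
    "simulate_emg",
    "sphere_dipole_field",
]

_MU0_4PI = 1e-7  # magnetic constant / 4 pi, SI


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def sphere_dipole_field(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_pos: np.ndarray,
) -> np.ndarray:
    """Magnetic field of a current dipole in a homogeneous conducting sphere.

    Sarvas closed form, sphere centred at the origin.  Returns the full
    field vector at each sensor; volume currents are accounted for, and a
    radially oriented dipole yields an identically zero external field.

    Parameters
    ----------
    dipole_pos : (3,) position of the dipole in metres.
    dipole_moment : (3,) dipole moment vector.
    sensor_pos : (n_sensors, 3) sensor positions (outside the sphere).

    Returns
    -------
    (n_sensors, 3) field vectors.
    """
    r0 = np.asarray(dipole_pos, float)
    q = np.asarray(dipole_moment, float)
    r = np.atleast_2d(np.asarray(sensor_pos, float))
    a_vec = r - r0[None, :]
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    ar = np.einsum("ij,ij->i", a_vec, r)
    f = a * (rn * a + rn**2 - r @ r0)
    grad_f = (
        (a**2 / rn + ar / a + 2 * a + 2 * rn)[:, None] * r
        - (a + 2 * rn + ar / a)[:, None] * r0[None, :]
    )
    q_x_r0 = np.cross(q, r0)
    b = _MU0_4PI / f[:, None] ** 2 * (
        f[:, None] * q_x_r0[None, :] - (r @ q_x_r0)[:, None] * grad_f
    )
    return b


def _fibonacci_cap(n: int, direction: np.ndarray, cap_angle: float) -> np.ndarray:
    """Quasi-uniform unit vectors on a spherical cap around ``direction``."""
    i = np.arange(n) + 0.5
    # uniform in solid angle on the cap
    cos_t = 1.0 - i / n * (1.0 - np.cos(cap_angle))
    theta = np.arccos(np.clip(cos_t, -1, 1))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n)
    pts = np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )
    # rotate +z onto `direction`
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(z @ d)
    if np.linalg.norm(v) < 1e-12:
        return pts if c > 0 else -pts
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return pts @ rot.T


def make_source_model(
    n_vertices: int = 200,
    n_channels: int = 64,
    seed: int = 0,
    *,
    forward: str = "sphere",
    cortex_radius: float = 0.07,
    sensor_radius: float = 0.105,
    roi_angle: float = 0.5,
    sensor_angle: float = 1.0,
    orientation_jitter: float = 0.3,
) -> SourceModel:
    """Build a spherical-cap ROI patch with its lead field.

    Vertices sit on a cap of angular radius ``roi_angle`` (radians) at
    cortical depth inside the head sphere -- a stand-in for the contralateral
    primary sensorimotor patch.  Sensors are radial magnetometers on a wider
    cap of an outer shell.  Orientations are drawn tangentially (the sphere
    model is blind to radial dipoles, so radial draws are rejected and
    redrawn).  ``forward="random"`` replaces the dipole physics with a
    smooth random gain matrix, useful for fast unit tests.
    """
    if n_vertices < 2:
        raise ValueError("need n_vertices >= 2")
    if n_channels < 8:
        raise ValueError("need n_channels >= 8")
    rng = np.random.default_rng(seed)

    roi_dir = np.array([-0.4, 0.15, 0.9])
    roi_dir /= np.linalg.norm(roi_dir)
    vert_dirs = _fibonacci_cap(n_vertices, roi_dir, roi_angle)
    positions = cortex_radius * vert_dirs

    sensor_dirs = _fibonacci_cap(n_channels, roi_dir, sensor_angle)
    sensors = sensor_radius * sensor_dirs

    # Tangential orientations, spatially coherent: pyramidal-cell dipoles in a
    # small patch are locally aligned, so neighbouring vertices must not cancel.
    # Each vertex projects a common direction (plus jitter) onto its tangent
    # plane; draws that land near-radial (silent in the sphere model) are
    # rejected and redrawn.
    base_dir = rng.standard_normal(3)
    base_dir /= np.linalg.norm(base_dir)
    orientations = np.empty((n_vertices, 3))
    for v in range(n_vertices):
        while True:
            raw = base_dir + orientation_jitter * rng.standard_normal(3)
            tang = raw - (raw @ vert_dirs[v]) * vert_dirs[v]
            norm = np.linalg.norm(tang)
            if norm > 1e-6:
                orientations[v] = tang / norm
                break

    if forward == "sphere":
        lf_free = np.empty((n_channels, n_vertices, 3))
        for v in range(n_vertices):
            for k in range(3):
                e = np.zeros(3)
                e[k] = 1.0
                b = sphere_dipole_field(positions[v], e, sensors)
                lf_free[:, v, k] = np.einsum("ij,ij->i", b, sensor_dirs)
        leadfield = np.einsum("cvk,vk->cv", lf_free, orientations)
    elif forward == "random":
        # smooth random gains: white matrix blurred along vertices
        raw = rng.standard_normal((n_channels, n_vertices, 3))
        d = np.linalg.norm(
            positions[:, None, :] - positions[None, :, :], axis=2
        )
        kern = np.exp(-(d / (0.3 * cortex_radius * roi_angle + 1e-12)) ** 2)
        kern /= kern.sum(axis=1, keepdims=True)
        lf_free = np.einsum("cwk,vw->cvk", raw, kern)
        leadfield = np.einsum("cvk,vk->cv", lf_free, orientations)
        bad = np.linalg.norm(leadfield, axis=0) < 1e-12
        leadfield[:, bad] += rng.standard_normal((n_channels, bad.sum()))
    else:
        raise ValueError(f"unknown forward model {forward!r}")

    return SourceModel(
        vertex_positions=positions,
        vertex_orientations=orientations,
        leadfield=leadfield,
        leadfield_free=lf_free,
        sensor_positions=sensors,
    )


# ---------------------------------------------------------------------------
# MEG simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the sensor-epoch generator.

    Defaults follow the emulated experiment: 100 valid trials per task,
    epochs from -2 s to +2 s around movement onset at 300 Hz, movement
    time around 0.25 s.  Amplitudes are in source units relative to the
    delta component; ``snr`` is the ratio of projected-signal power to
    sensor-noise power (``np.inf`` disables sensor noise).
    ``cluster_separation`` controls how far apart the four finger clusters
    are placed on the patch -- per-finger cortical separation is not a
    quantity the emulated experiment pins down, so it is a knob.
    """

    n_trials_per_task: int = 100
    sfreq: float = 300.0
    tmin: float = -2.0
    tmax: float = 2.0
    snr: float = 1.0
    amplitudes: dict = field(
        default_factory=lambda: {
            "delta": 1.0,
            "theta": 0.7,
            "alpha": 0.8,
            "beta": 0.6,
            "high_gamma": 0.12,
            "background": 0.12,
        }
    )
    cluster_size: int = 5
    cluster_separation: float = 0.012  # metres between adjacent finger clusters
    latency_jitter: float = 0.05  # max |latency shift| of the evoked bump, s
    amp_jitter: float = 0.2  # fractional amplitude jitter per trial
    erd_depth: float = 0.6
    ers_gain: float = 0.5
    movement_duration: float = 0.25  # s; sets the ERS latency
    task_vertices: dict | None = None  # task id -> vertex indices (override)

    # oscillation centre frequencies per component, Hz
    f_delta: float = 2.5
    f_theta: float = 6.0
    f_alpha: float = 10.0
    f_beta: float = 20.0
    f_high_gamma: float = 75.0


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def _one_over_f_noise(rng, n_series: int, n_samples: int, sfreq: float) -> np.ndarray:
    """Rows of 1/f-power noise with unit variance."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    shape[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shape[None, :], n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True) + 1e-300
    return out


def _task_clusters(model: SourceModel, cfg: SimulationConfig, rng) -> dict:
    """Choose four disjoint vertex clusters, one per task."""
    if cfg.task_vertices is not None:
        out = {}
        for task, idx in cfg.task_vertices.items():
            if not 0 <= int(task) < N_TASKS:
                raise ValueError(f"unknown task id {task!r}")
            out[int(task)] = np.asarray(idx, dtype=int)
        if len(out) != N_TASKS:
            raise ValueError("task_vertices must cover all four tasks")
        return out
    pos = model.vertex_positions
    center = pos.mean(axis=0)
    # two orthogonal directions in the patch plane
    u, s, vt = np.linalg.svd(pos - center, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    half = cfg.cluster_separation / 2.0
    offsets = [(-half, -half), (half, -half), (-half, half), (half, half)]
    clusters: dict = {}
    taken: set = set()
    for task, (a, b) in enumerate(offsets):
        target = center + a * e1 + b * e2
        order = np.argsort(np.linalg.norm(pos - target, axis=1))
        chosen = [v for v in order if v not in taken][: cfg.cluster_size]
        taken.update(chosen)
        clusters[task] = np.array(chosen, dtype=int)
    return clusters


def simulate_meg(
    source_model: SourceModel,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[SensorEpochs, GroundTruth]:
    """Generate broadband sensor epochs plus ground truth.

    Source structure per trial (task ``k``):

    * delta and theta: Gaussian-windowed oscillatory bumps with fixed
      polarity (phase-locked), peak latency jittered by at most
      ``latency_jitter`` around 0 s, on task ``k``'s vertex cluster;
    * alpha and beta: random-phase oscillations on a task-shared central
      vertex set with an ERD dip spanning preparation/execution and an
      ERS rebound after movement offset;
    * high-gamma: brief random-phase burst at onset on the shared set;
    * 1/f background on every vertex.

    The sensor data are the lead-field projection of the source matrix
    plus white sensor noise scaled so that the ratio of mean projected
    signal power to noise power equals ``config.snr``.
    """
    cfg = config or SimulationConfig()
    if not cfg.snr > 0:
        raise ValueError("snr must be positive (np.inf for noise-free)")
    rng = np.random.default_rng(seed)

    n_trials = cfg.n_trials_per_task * N_TASKS
    n_samples = int(round((cfg.tmax - cfg.tmin) * cfg.sfreq))
    t = cfg.tmin + np.arange(n_samples) / cfg.sfreq
    V = source_model.n_vertices
    L = source_model.leadfield
    amp = cfg.amplitudes

    labels = np.repeat(np.arange(N_TASKS), cfg.n_trials_per_task)
    rng.shuffle(labels)

    clusters = _task_clusters(source_model, cfg, rng)
    shared = np.argsort(
        np.linalg.norm(
            source_model.vertex_positions
            - source_model.vertex_positions.mean(axis=0),
            axis=1,
        )
    )[: max(8, 2 * cfg.cluster_size)]

    # spatial profiles within each cluster (Gaussian falloff from its centroid)
    profiles = {}
    for task, idx in clusters.items():
        c = source_model.vertex_positions[idx].mean(axis=0)
        d = np.linalg.norm(source_model.vertex_positions[idx] - c, axis=1)
        w = np.exp(-((d / (cfg.cluster_separation / 2.0 + 1e-12)) ** 2))
        profiles[task] = w / w.max()

    erd_mu = cfg.movement_duration / 2.0
    ers_mu = cfg.movement_duration + 0.7
    env_alpha = (
        1.0
        - cfg.erd_depth * _gauss(t, erd_mu, 0.35)
        + cfg.ers_gain * _gauss(t, ers_mu, 0.30)
    )
    env_beta = (
        1.0
        - cfg.erd_depth * _gauss(t, erd_mu, 0.30)
        + 1.2 * cfg.ers_gain * _gauss(t, ers_mu - 0.15, 0.25)
    )
    env_hg = _gauss(t, 0.0, 0.05)

    sigma_delta, sigma_theta = 0.40, 0.20

    data = np.empty((n_trials, source_model.n_channels, n_samples))
    signal_power = 0.0
    for i in range(n_trials):
        task = int(labels[i])
        S = np.zeros((V, n_samples))

        # phase-locked low-frequency bumps on the task cluster
        tau = rng.uniform(-cfg.latency_jitter, cfg.latency_jitter)
        gain = 1.0 + cfg.amp_jitter * rng.standard_normal()
        gain = max(gain, 0.1)
        wave_d = (
            amp.get("delta", 0.0)
            * gain
            * _gauss(t, tau, sigma_delta)
            * np.cos(2 * np.pi * cfg.f_delta * (t - tau))
        )
        wave_t = (
            amp.get("theta", 0.0)
            * gain
            * _gauss(t, tau, sigma_theta)
            * np.cos(2 * np.pi * cfg.f_theta * (t - tau))
        )
        S[clusters[task]] += profiles[task][:, None] * (wave_d + wave_t)[None, :]

        # non-phase-locked rhythms on the shared set
        for env, f0, a0 in (
            (env_alpha, cfg.f_alpha, amp.get("alpha", 0.0)),
            (env_beta, cfg.f_beta, amp.get("beta", 0.0)),
            (env_hg, cfg.f_high_gamma, amp.get("high_gamma", 0.0)),
        ):
            if a0 == 0.0:
                continue
            phases = rng.uniform(0, 2 * np.pi, size=shared.size)
            S[shared] += a0 * env[None, :] * np.cos(
                2 * np.pi * f0 * t[None, :] + phases[:, None]
            )

        bg = amp.get("background", 0.0)
        if bg > 0:
            S += bg * _one_over_f_noise(rng, V, n_samples, cfg.sfreq)

        x = L @ S
        data[i] = x
        signal_power += np.mean(x**2)

    signal_power /= n_trials
    if np.isfinite(cfg.snr):
        noise_std = np.sqrt(signal_power / cfg.snr)
        data += noise_std * rng.standard_normal(data.shape)

    epochs = SensorEpochs(
        data=data, sfreq=cfg.sfreq, t0=cfg.tmin, labels=labels, band="broadband"
    )
    active = {}
    for task, idx in clusters.items():
        active[(task, "delta")] = idx.copy()
        active[(task, "theta")] = idx.copy()
    active[("shared", "alpha")] = shared.copy()
    active[("shared", "beta")] = shared.copy()
    active[("shared", "high_gamma")] = shared.copy()
    truth = GroundTruth(
        task_labels=labels.copy(),
        active_vertex_sets=active,
        band_envelopes={
            "delta": (t.copy(), _gauss(t, 0.0, sigma_delta)),
            "theta": (t.copy(), _gauss(t, 0.0, sigma_theta)),
            "alpha": (t.copy(), env_alpha.copy()),
            "beta": (t.copy(), env_beta.copy()),
            "high_gamma": (t.copy(), env_hg.copy()),
        },
    )
    return epochs, truth


# ---------------------------------------------------------------------------
# EMG simulation
# ---------------------------------------------------------------------------

@dataclass
class EMGConfig:
    """Study conditions for the EMG generator.

    Epochs run from 1 s before to 3 s after the visual cue at 1 kHz.
    Reaction times are drawn around 0.64 s and per-task burst durations
    around 0.24-0.30 s, matching the emulated task's group timing; the
    per-task amplitude spread is what makes the four classes separable
    from two surface channels.  The burst attack is brisk (2 ms) --
    ballistic extension onsets are abrupt -- which is also what makes
    threshold-crossing onset detection sharp.
    """

    n_trials_per_task: int = 100
    sfreq: float = 1000.0
    tmin: float = -1.0  # relative to cue
    tmax: float = 3.0
    n_channels: int = 2
    baseline_noise: float = 1.0
    burst_amplitudes: tuple = (12.0, 16.0, 21.0, 27.0)
    burst_durations: tuple = (0.241, 0.253, 0.289, 0.295)  # per-task mean, s
    duration_sd: float = 0.09
    duration_range: tuple = (0.12, 0.60)
    rt_mean: float = 0.643
    rt_sd: float = 0.090
    rt_range: tuple = (0.30, 0.95)
    rise_time: float = 0.004
    fall_time: float = 0.040
    amp_jitter: float = 0.15
    # initial agonist-burst overshoot (triphasic EMG pattern): the envelope
    # starts at (1 + overshoot) x plateau and relaxes with time constant tau
    overshoot: float = 0.6
    overshoot_tau: float = 0.030
    # strength of the task-specific temporal recruitment profile (0 disables)
    shape_strength: float = 0.4


def _burst_envelope(
    n_samples: int,
    onset: int,
    offset: int,
    sfreq: float,
    rise: float,
    fall: float,
    overshoot: float = 0.0,
    overshoot_tau: float = 0.030,
) -> np.ndarray:
    """Burst support: half-cosine rise, plateau, half-cosine fall.

    Strictly zero outside [onset, offset]; the recorded true onset/offset
    are exactly the first/last nonzero samples.  A positive ``overshoot``
    superimposes the initial agonist transient of a ballistic movement:
    the envelope starts at (1 + overshoot) and relaxes to the plateau with
    time constant ``overshoot_tau``.
    """
    env = np.zeros(n_samples)
    n_rise = max(1, int(round(rise * sfreq)))
    n_fall = max(1, int(round(fall * sfreq)))
    length = offset - onset + 1
    n_rise = min(n_rise, length // 2)
    n_fall = min(n_fall, length - n_rise)
    ramp_up = 0.5 * (1 - np.cos(np.pi * (np.arange(1, n_rise + 1) / n_rise)))
    ramp_dn = 0.5 * (1 + np.cos(np.pi * (np.arange(1, n_fall + 1) / n_fall)))
    env[onset : onset + n_rise] = ramp_up
    env[onset + n_rise : offset - n_fall + 1] = 1.0
    env[offset - n_fall + 1 : offset + 1] = ramp_dn
    if overshoot > 0:
        k = np.arange(length)
        env[onset : offset + 1] *= 1.0 + overshoot * np.exp(
            -k / (overshoot_tau * sfreq)
        )
    return env


def simulate_emg(
    config: EMGConfig | None = None, seed: int = 0
) -> tuple[EMGEpochs, GroundTruth]:
    """Generate EMG epochs: baseline noise plus an envelope-modulated burst.

    Returns the epochs and a ground truth carrying the true per-trial
    onset/offset sample indices (first/last nonzero sample of the burst
    envelope).
    """
    cfg = config or EMGConfig()
    rng = np.random.default_rng(seed)
    n_trials = cfg.n_trials_per_task * N_TASKS
    n_samples = int(round((cfg.tmax - cfg.tmin) * cfg.sfreq))
    cue_sample = int(round(-cfg.tmin * cfg.sfreq))

    labels = np.repeat(np.arange(N_TASKS), cfg.n_trials_per_task)
    rng.shuffle(labels)

    data = np.empty((n_trials, cfg.n_channels, n_samples))
    onsets = np.empty(n_trials, dtype=int)
    offsets = np.empty(n_trials, dtype=int)
    for i in range(n_trials):
        task = int(labels[i])
        rt = float(
            np.clip(rng.normal(cfg.rt_mean, cfg.rt_sd), *cfg.rt_range)
        )
        dur = float(
            np.clip(
                rng.normal(cfg.burst_durations[task], cfg.duration_sd),
                *cfg.duration_range,
            )
        )
        onset = cue_sample + int(round(rt * cfg.sfreq))
        offset = onset + int(round(dur * cfg.sfreq))
        if offset >= n_samples or onset < 0:
            raise ValueError(
                f"trial {i}: burst [{onset}, {offset}] extends beyond the epoch "
                f"(0..{n_samples - 1})"
            )
        amp = cfg.burst_amplitudes[task] * max(
            1.0 + cfg.amp_jitter * rng.standard_normal(), 0.6
        )
        env = _burst_envelope(
            n_samples, onset, offset, cfg.sfreq, cfg.rise_time, cfg.fall_time,
            cfg.overshoot, cfg.overshoot_tau,
        )
        if cfg.shape_strength > 0:
            # Task-specific temporal recruitment profile.  The modulators
            # vanish at both burst edges so onset/offset timing is untouched,
            # and they are shape (not scale) differences: amplitude alone
            # cannot linearly separate the two middle classes of an
            # amplitude-ordered set, temporal profiles can.
            u = np.linspace(0.0, 1.0, offset - onset + 1)
            mod = {
                0: np.ones_like(u),
                1: 1.0 + cfg.shape_strength * np.sin(np.pi * u),
                2: 1.0 - cfg.shape_strength * np.sin(np.pi * u),
                3: 1.0 + cfg.shape_strength * np.sin(2 * np.pi * u),
            }[task]
            env[onset : offset + 1] *= mod
        for ch in range(cfg.n_channels):
            # per-channel gain difference (electrode placement)
            g = 1.0 if ch == 0 else 0.8
            x = cfg.baseline_noise * rng.standard_normal(n_samples)
            x += g * amp * env * rng.standard_normal(n_samples)
            data[i, ch] = x
        onsets[i] = onset
        offsets[i] = offset

    epochs = EMGEpochs(
        data=data, sfreq=cfg.sfreq, cue_sample=cue_sample, labels=labels
    )
    truth = GroundTruth(
        task_labels=labels.copy(), emg_onsets=onsets, emg_offsets=offsets
    )
    return epochs, truth
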