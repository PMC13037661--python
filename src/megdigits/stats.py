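"""Nonparametric statistical toolkit.

Friedman tests across conditions, Wilcoxon signed-rank tests (exact for
small tie-free samples, normal approximation with continuity correction
otherwise), Benjamini-Hochberg step-up adjustment, cluster-based sign-flip
permutation tests along time/window (and frequency) axes, and one-sided
vertex-wise permutation tests with BH correction.

Cluster test conventions: the per-point statistic is a one-sample (or
paired-difference) t across subjects; the cluster-forming threshold is
the t critical value at p < 0.05 (two-tailed for two-sided tests,
one-tailed otherwise) with subject degrees of freedom; cluster mass is
the sum of t within the cluster and the null is the permutation
distribution of the maximum cluster mass.  Permutation p-values carry
the +1 correction, so they are bounded below by 1/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterResult",
    "friedman",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "cluster_permutation",
    "vertex_permutation_bh",
]


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def friedman(block_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test on a subjects x conditions matrix.

    Midranks for ties; chi-square reference with k-1 degrees of freedom.
    """
    x = np.asarray(block_matrix, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) x (conditions >= 2) matrix")
    n, k = x.shape
    if np.any(np.ptp(x, axis=1) == 0):
        warnings.warn("constant rows contribute no rank information")
    if k >= 3:
        res = sps.friedmanchisquare(*(x[:, j] for j in range(k)))
        return float(res.statistic), float(res.pvalue)
    # k == 2: same rank statistic computed directly (scipy requires k >= 3)
    ranks = sps.rankdata(x, axis=1)
    rsum = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rsum**2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    if denom > 0:
        chi2 /= denom
    p = float(sps.chi2.sf(chi2, k - 1))
    return float(chi2), p


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray | float | None = None,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired samples or of x against a constant.

    Zero differences are dropped and midranks used.  ``method="auto"``
    uses the exact sign-flip distribution for small tie-free samples and
    the normal approximation with continuity correction otherwise.

    Returns
    -------
    (Z, p) : the signed normal-approximation statistic (negative when the
        positive-rank sum falls below its null mean) and the p-value.
    """
    x = np.asarray(x, float)
    if y is None:
        d = x
    else:
        d = x - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero: test undefined")
        return np.nan, np.nan
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    mu = n * (n + 1) / 4.0
    # tie-corrected variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    diff = w_plus - mu
    corr = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - corr) / sigma if sigma > 0 else np.nan
    res = sps.wilcoxon(
        d, zero_method="wilcox", correction=True, alternative=alternative,
        method=method,
    )
    return float(z), float(res.pvalue)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


# ---------------------------------------------------------------------------
# cluster-based permutation
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Clusters of contiguous supra-threshold points with permutation p-values."""

    clusters: list  # list of boolean masks over the point axis/lattice
    cluster_stats: np.ndarray  # summed t per cluster
    p_values: np.ndarray
    n_permutations: int
    alpha: float
    t_obs: np.ndarray
    threshold: float

    def significant_mask(self) -> np.ndarray:
        out = np.zeros(self.t_obs.shape, dtype=bool)
        for m, p in zip(self.clusters, self.p_values):
            if p < self.alpha:
                out |= m
        return out

    def significant_spans(self, times: np.ndarray) -> list[tuple[float, float]]:
        """Contiguous significant intervals in seconds (1-D series only)."""
        mask = self.significant_mask()
        if mask.ndim != 1:
            raise ValueError("spans are defined for 1-D series")
        times = np.asarray(times)
        spans = []
        lab, n = ndimage.label(mask)
        for i in range(1, n + 1):
            idx = np.flatnonzero(lab == i)
            spans.append((float(times[idx[0]]), float(times[idx[-1]])))
        return spans


def _t_one_sample(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd == 0, 0.0, mean / (sd / np.sqrt(n)))


def _clusters_and_masses(t: np.ndarray, threshold: float, tail: int):
    """Label contiguous supra-threshold regions; mass = summed t."""
    masks, masses = [], []
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]) if t.ndim == 2 else None
    sides = []
    if tail >= 0:
        sides.append(t > threshold)
    if tail <= 0:
        sides.append(t < -threshold)
    for supra in sides:
        lab, n = ndimage.label(supra, structure=structure)
        for i in range(1, n + 1):
            m = lab == i
            masks.append(m)
            masses.append(float(t[m].sum()))
    return masks, np.asarray(masses)


def _max_cluster_mass(t: np.ndarray, threshold: float, tail: int) -> float:
    _, masses = _clusters_and_masses(t, threshold, tail)
    return float(np.max(np.abs(masses))) if masses.size else 0.0


def cluster_permutation(
    series_per_subject: np.ndarray,
    null_value: float | np.ndarray = 0.0,
    paired: np.ndarray | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    tail: int = 0,
    threshold: float | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test.

    Parameters
    ----------
    series_per_subject : (n_subjects, n_points) or (n_subjects, n_freqs, n_times)
        Per-subject series (e.g. accuracies over windows, or TFR maps).
    null_value : scalar or array
        Value subtracted before the one-sample test (e.g. 0.25 for
        accuracy against chance).
    paired : optional second condition; the test is then on the
        difference ``series_per_subject - paired``.
    tail : 1 (greater), -1 (less) or 0 (two-sided).
    threshold : cluster-forming t threshold; defaults to the p < 0.05
        critical value with n_subjects - 1 degrees of freedom (two-tailed
        when ``tail == 0``).
    """
    if paired is not None:
        d = np.asarray(series_per_subject, float) - np.asarray(paired, float)
    else:
        d = np.asarray(series_per_subject, float) - null_value
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse")
    if threshold is None:
        if tail == 0:
            threshold = float(sps.t.ppf(1 - 0.05 / 2, n - 1))
        else:
            threshold = float(sps.t.ppf(1 - 0.05, n - 1))

    t_obs = _t_one_sample(d)
    masks, masses = _clusters_and_masses(t_obs, threshold, tail)

    rng = np.random.default_rng(seed)
    shape = d.shape
    flat = d.reshape(n, -1)
    sq_mean = np.mean(flat**2, axis=0)  # sign-flip invariant
    null_max = np.empty(n_perm)
    chunk = max(1, int(5e6 // max(flat.size, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n))
        means = signs @ flat / n  # (m, P)
        var = (sq_mean[None, :] - means**2) * n / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = np.where(var == 0, 0.0, means / np.sqrt(var / n))
        for j in range(m):
            null_max[done + j] = _max_cluster_mass(
                t_perm[j].reshape(shape[1:]), threshold, tail
            )
        done += m

    if masses.size:
        p = (1 + np.sum(null_max[None, :] >= np.abs(masses)[:, None], axis=1)) / (
            n_perm + 1
        )
    else:
        p = np.empty(0)
    return ClusterResult(
        clusters=masks,
        cluster_stats=masses,
        p_values=p,
        n_permutations=n_perm,
        alpha=alpha,
        t_obs=t_obs,
        threshold=threshold,
    )


def vertex_permutation_bh(
    accuracy_maps: np.ndarray,
    chance: float = 0.25,
    n_perm: int = 5000,
    alpha: float = 0.05,
    one_sided: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex-wise sign-flip permutation test with BH correction.

    ``accuracy_maps`` is ``(n_subjects, n_vertices)`` or
    ``(n_subjects, n_windows, n_vertices)``; the test statistic per vertex
    is the across-subject mean deviation from chance, the null is its
    sign-flip distribution, and BH runs across vertices (within each
    window for windowed input).

    Returns
    -------
    mask : boolean significance mask (adjusted p < alpha).
    p_adj : BH-adjusted p-values, same shape as the mask.
    """
    a = np.asarray(accuracy_maps, float)
    squeeze = a.ndim == 2
    if squeeze:
        a = a[:, None, :]
    n_subj, n_win, n_vert = a.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    d = a - chance
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    p_adj = np.empty((n_win, n_vert))
    for w in range(n_win):
        obs = d[:, w, :].mean(axis=0)
        perm = signs @ d[:, w, :] / n_subj  # (n_perm, V)
        if one_sided:
            exceed = perm >= obs[None, :]
        else:
            exceed = np.abs(perm) >= np.abs(obs)[None, :]
        p_raw = (1 + exceed.sum(axis=0)) / (n_perm + 1)
        p_adj[w] = bh_adjust(p_raw)
    mask = p_adj < alpha
    if squeeze:
        return mask[0], p_adj[0]
    return mask, p_adj
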