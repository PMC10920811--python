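"""Sensor-space group statistics: cluster-based permutation testing.

Mass-univariate two-sample T-maps over (channel, band) cells are
corrected for multiple comparisons nonparametrically: supra-threshold
cells are grouped into spatially adjacent clusters within each band
(positive and negative T separately), each cluster is scored by its mass
(sum of T), and the observed masses are referred to the permutation
distribution of the *maximum* cluster mass under random relabelling of
subjects. Subjects — not epochs — are the exchangeable unit: epochs of
one subject are strongly dependent, so subject-level mean power enters
the test.

A Spearman cluster correlation against a behavioral score is provided in
the same max-statistic spirit, with the Bonferroni per-band threshold
alpha/K reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sp_stats

from .synthetic import Montage


@dataclass
class AdjacencyGraph:
    """Symmetric channel adjacency without self-loops."""

    ch_names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, bool)
        n = len(self.ch_names)
        if m.shape != (n, n):
            raise ValueError("adjacency must be square over channels")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("adjacency must have no self-loops")
        self.matrix = m
        self.neighbors = [np.flatnonzero(m[i]) for i in range(n)]

    def n_components(self) -> int:
        from scipy.sparse.csgraph import connected_components

        return int(connected_components(self.matrix.astype(int), directed=False)[0])


def channel_adjacency(montage, scale: float = 1.3) -> AdjacencyGraph:
    """Adjacency by 3-D distance: neighbours within ``scale`` x the median
    nearest-neighbour distance.

    Recovers the 4-neighbourhood on a regular grid at the default scale
    and degrades gracefully on quasi-uniform montages.
    """
    if isinstance(montage, Montage):
        pos, names = np.asarray(montage.positions, float), list(montage.ch_names)
    else:
        pos = np.asarray(montage, float)
        names = [f"E{i + 1:03d}" for i in range(len(pos))]
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 channels")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    off = d[~np.eye(n, dtype=bool)]
    if np.any(off == 0):
        raise ValueError("duplicate channel positions")
    nn = np.where(np.eye(n, dtype=bool), np.inf, d).min(axis=1)
    thr = scale * np.median(nn)
    adj = (d <= thr) & ~np.eye(n, dtype=bool)
    g = AdjacencyGraph(names, adj)
    k = g.n_components()
    if k > 1:
        warnings.warn(f"adjacency graph has {k} connected components")
    return g


@dataclass
class ClusterResult:
    """Observed T-map, clusters with masses, and permutation p-values."""

    bands: list[str]
    ch_names: list[str]
    t_obs: np.ndarray  # (channels, bands)
    clusters: list[dict]
    n_perm: int
    threshold: float
    null_max_mass: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[dict]:
        return [c for c in self.clusters if c["p"] <= alpha]


def _t_maps(X: np.ndarray, group1_masks: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for many label assignments at once.

    ``X`` is (subjects, cells); ``group1_masks`` is (P, subjects) bool.
    Returns (P, cells).
    """
    G = group1_masks.astype(float)
    n = X.shape[0]
    n1 = G.sum(axis=1, keepdims=True)
    n2 = n - n1
    s1 = G @ X
    s2 = X.sum(axis=0)[None, :] - s1
    q1 = G @ (X**2)
    q2 = (X**2).sum(axis=0)[None, :] - q1
    m1, m2 = s1 / n1, s2 / n2
    ss = (q1 - n1 * m1**2) + (q2 - n2 * m2**2)
    pooled = ss / (n - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t


def _find_clusters(tmap: np.ndarray, threshold: float, neighbors) -> list[tuple[int, int, list[int], float]]:
    """Within-band, sign-separated connected clusters of supra-threshold cells.

    Returns (band, sign, channel list, mass) tuples.
    """
    n_ch, n_bands = tmap.shape
    out = []
    for b in range(n_bands):
        col = tmap[:, b]
        for sign in (1, -1):
            supra = sign * col > threshold
            if not supra.any():
                continue
            seen = np.zeros(n_ch, bool)
            for start in np.flatnonzero(supra):
                if seen[start]:
                    continue
                stack, comp = [start], []
                seen[start] = True
                while stack:
                    u = stack.pop()
                    comp.append(u)
                    for v in neighbors[u]:
                        if supra[v] and not seen[v]:
                            seen[v] = True
                            stack.append(v)
                out.append((b, sign, sorted(comp), float(col[comp].sum())))
    return out


def cluster_permutation_test(
    power_g1: np.ndarray,
    power_g2: np.ndarray,
    adjacency: AdjacencyGraph,
    bands: list[str],
    t_threshold: float = 6.0,
    n_perm: int = 1024,
    seed: int = 0,
) -> ClusterResult:
    """Two-sided cluster-mass permutation test on subject-level band power.

    ``power_g1``/``power_g2`` are (subjects, channels, bands) per group.
    The null distribution is the maximum absolute cluster mass over
    random subject-label permutations; when the permutation space is
    smaller than ``n_perm`` all distinct assignments are enumerated
    instead (with a warning). ``p = (1 + #{null >= observed}) / (n_used + 1)``,
    so p is never below ``1/(n_used+1)``.
    """
    if t_threshold <= 0:
        raise ValueError("t_threshold must be > 0")
    X1 = np.asarray(power_g1, float)
    X2 = np.asarray(power_g2, float)
    if X1.ndim != 3 or X2.ndim != 3 or X1.shape[1:] != X2.shape[1:]:
        raise ValueError("groups must be (subjects, channels, bands) with matching cells")
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    n1, n_ch, n_bands = X1.shape
    if n_ch != len(adjacency.ch_names):
        raise ValueError("adjacency channel count mismatch")
    if n_bands != len(bands):
        raise ValueError("band list mismatch")
    X = np.concatenate([X1, X2], axis=0).reshape(n1 + X2.shape[0], -1)
    n = X.shape[0]

    from math import comb

    n_distinct = comb(n, n1)
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct assignments; enumerating exhaustively"
        )
        masks = np.zeros((n_distinct, n), bool)
        for i, c in enumerate(combinations(range(n), n1)):
            masks[i, list(c)] = True
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), bool)
        for i in range(n_perm):
            masks[i, rng.choice(n, size=n1, replace=False)] = True

    obs_mask = np.zeros((1, n), bool)
    obs_mask[0, :n1] = True
    t_obs = _t_maps(X, obs_mask)[0].reshape(n_ch, n_bands)
    obs_clusters = _find_clusters(t_obs, t_threshold, adjacency.neighbors)

    t_perm = _t_maps(X, masks)
    null_max = np.zeros(len(masks))
    for i in range(len(masks)):
        tm = t_perm[i].reshape(n_ch, n_bands)
        if np.any(np.abs(tm) > t_threshold):
            cl = _find_clusters(tm, t_threshold, adjacency.neighbors)
            if cl:
                null_max[i] = max(abs(m) for *_ignore, m in cl)

    n_used = len(masks)
    clusters = []
    for b, sign, chans, mass in obs_clusters:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_used + 1.0)
        clusters.append(
            {
                "band": bands[b],
                "band_index": b,
                "sign": sign,
                "channel_idx": chans,
                "channels": [adjacency.ch_names[c] for c in chans],
                "mass": mass,
                "p": float(p),
            }
        )
    clusters.sort(key=lambda c: c["p"])
    return ClusterResult(
        bands=list(bands),
        ch_names=list(adjacency.ch_names),
        t_obs=t_obs,
        clusters=clusters,
        n_perm=n_used,
        threshold=t_threshold,
        null_max_mass=null_max,
    )


def cluster_test_from_psd(psd, adjacency=None, scale: float = 1.3, **kwargs) -> ClusterResult:
    """Convenience wrapper: subject-mean power from a PSDSet, then the test."""
    subs, groups, power = psd.subject_mean()
    if adjacency is None:
        src = psd.source
        adjacency = channel_adjacency(
            Montage(tuple(src.ch_names), src.ch_pos), scale=scale
        )
    g1 = power[np.asarray(groups) == "M"]
    g2 = power[np.asarray(groups) == "H"]
    return cluster_permutation_test(
        g1, g2, adjacency, [b.name for b in psd.bands], **kwargs
    )


def spearman_cluster_correlation(
    band_power: np.ndarray,
    behavior: np.ndarray,
    bands: list[str],
    n_perm: int = 1024,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Per-band Spearman correlation with a behavioral score, permutation p.

    ``band_power`` is (subjects, bands) channel-mean power. p-values come
    from shuffling the behavior vector; the Bonferroni-corrected per-band
    threshold ``alpha/K`` is reported alongside (0.05/7 ~ 0.00714 for the
    seven analysis bands).
    """
    X = np.asarray(band_power, float)
    y = np.asarray(behavior, float)
    if X.ndim != 2 or X.shape[1] != len(bands):
        raise ValueError("band_power must be (subjects, bands)")
    if X.shape[0] < 5:
        raise ValueError("need >= 5 subjects")
    if not np.all(np.isfinite(y)) or y.shape != (X.shape[0],):
        raise ValueError("behavior must be finite, one value per subject")
    if np.ptp(y) == 0:
        raise ValueError("behavior vector is constant")

    rng = np.random.default_rng(seed)
    rx = sp_stats.rankdata(X, axis=0)
    ry = sp_stats.rankdata(y)

    def rho_vec(ry_):
        a = rx - rx.mean(axis=0)
        b = ry_ - ry_.mean()
        return (a * b[:, None]).sum(axis=0) / np.sqrt((a**2).sum(axis=0) * (b**2).sum())

    rho = rho_vec(ry)
    count = np.zeros(len(bands))
    for _ in range(n_perm):
        rp = rho_vec(rng.permutation(ry))
        count += np.abs(rp) >= np.abs(rho) - 1e-12
    p = (1.0 + count) / (n_perm + 1.0)
    return {
        "bands": list(bands),
        "rho": rho,
        "p": p,
        "alpha": alpha,
        "corrected_threshold": alpha / len(bands),
        "significant": p < alpha / len(bands),
        "n_perm": n_perm,
    }
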