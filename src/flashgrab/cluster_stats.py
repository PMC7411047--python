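"""Cluster-mass permutation inference and bootstrap bands.

Family-wise error control for mass-univariate tests over time courses (1D)
and temporal-generalization matrices (2D): contiguous same-sign
suprathreshold samples form clusters, each cluster's mass is the sum of the
statistic over its members, and the observed masses are compared against
the permutation distribution of the maximum (and minimum) cluster mass.
The two-tailed critical values are the 97.5th percentile of the max-mass
null and the 2.5th percentile of the min-mass null; a cluster is
significant only if its mass strictly exceeds the matching critical value.

Within-subject left/right label exchange is equivalent to flipping the
sign of that subject's difference score, so one sign-flip engine serves
both permutation schemes.  When the number of subjects is small enough
(``2**n <= n_perm``) all sign patterns are enumerated exactly; otherwise
random patterns are drawn with the observed (identity) pattern included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "find_clusters",
    "permutation_test",
    "correlation_cluster_test",
    "bootstrap_band",
]


@dataclass(frozen=True)
class Cluster:
    """A same-sign suprathreshold connected component."""

    indices: tuple
    mass: float
    sign: int


@dataclass
class ClusterTestResult:
    """Observed statistic map, clusters, permutation null and verdicts."""

    statistic: np.ndarray
    threshold: float
    clusters: list[Cluster]
    null_max: np.ndarray
    null_min: np.ndarray
    critical_high: float
    critical_low: float
    significant: list[Cluster] = field(default_factory=list)
    n_perm: int = 0
    exhaustive: bool = False

    def significant_mask(self) -> np.ndarray:
        """Boolean map marking members of significant clusters."""
        mask = np.zeros(self.statistic.shape, dtype=bool)
        for c in self.significant:
            mask[c.indices] = True
        return mask

    def summary(self) -> str:
        lines = [
            "Cluster-mass permutation test",
            "-" * 34,
            f"{'map shape':<22s}{self.statistic.shape}",
            f"{'cluster threshold':<22s}{self.threshold:.4f}",
            f"{'permutations':<22s}{self.n_perm}"
            + (" (exhaustive)" if self.exhaustive else ""),
            f"{'critical mass hi/lo':<22s}{self.critical_high:.3f} / "
            f"{self.critical_low:.3f}",
            f"{'clusters (signif.)':<22s}{len(self.clusters)} "
            f"({len(self.significant)})",
        ]
        for c in self.significant:
            lines.append(f"  mass {c.mass: .3f}  size {len(c.indices[0])}")
        return "\n".join(lines)


def find_clusters(stat: np.ndarray, threshold: float,
                  connectivity: str = "auto") -> list[Cluster]:
    """Maximal same-sign connected components with ``|stat| > threshold``.

    ``connectivity``: ``"1d"`` for series, ``"4"`` or ``"8"`` neighbour for
    matrices, ``"auto"`` to infer from dimensionality (4-neighbour for 2D).
    Mass is the sum of the raw statistic over members; adjacency never
    crosses a sign change.
    """
    stat = np.asarray(stat, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map contains non-finite values")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if connectivity == "auto":
        connectivity = "1d" if stat.ndim == 1 else "4"
    if stat.ndim == 1:
        structure = np.ones(3, dtype=bool)
    elif connectivity == "8":
        structure = np.ones((3, 3), dtype=bool)
    else:
        structure = ndimage.generate_binary_structure(2, 1)

    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * stat) > threshold
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            idx = np.nonzero(labels == lab)
            clusters.append(
                Cluster(indices=idx, mass=float(stat[idx].sum()), sign=sign)
            )
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _sign_patterns(n: int, n_perm: int, rng: np.random.Generator):
    """Sign-flip matrix (P, n); exhaustive when 2^n fits in n_perm."""
    if n <= 30 and 2**n <= n_perm:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        return np.where(bits > 0, 1.0, -1.0), True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0  # include the observed labelling in the null
    return signs, False


def _t_maps(signed_means: np.ndarray, ssq: np.ndarray, n: int) -> np.ndarray:
    """t statistics for every sign pattern; zero-variance points masked to 0."""
    var = (ssq[None, :] - n * signed_means**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    se = np.sqrt(var / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, signed_means / se, 0.0)
    return t


def _batch_extremes_1d(maps: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-row max/min cluster mass for a (P, L) stack of 1-D maps."""
    P = maps.shape[0]
    row_ix = np.broadcast_to(np.arange(P)[:, None], maps.shape)
    structure = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]], dtype=bool)
    mx = np.zeros(P)
    mn = np.zeros(P)
    for sign, out, op in ((1, mx, np.maximum), (-1, mn, np.minimum)):
        mask = (sign * maps) > threshold
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        masses = ndimage.sum_labels(maps, labels, index=idx)
        rows = ndimage.minimum(row_ix, labels, index=idx).astype(int)
        op.at(out, rows, masses)
    return mx, mn


def _extremes_nd(maps: np.ndarray, threshold: float,
                 connectivity: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-permutation cluster-mass extremes for stacks of nD maps."""
    if maps.ndim == 2:
        return _batch_extremes_1d(maps, threshold)
    P = maps.shape[0]
    mx = np.zeros(P)
    mn = np.zeros(P)
    for p in range(P):
        cl = find_clusters(maps[p], threshold, connectivity)
        masses = [c.mass for c in cl]
        mx[p] = max((m for m in masses if m > 0), default=0.0)
        mn[p] = min((m for m in masses if m < 0), default=0.0)
    return mx, mn


def permutation_test(
    data,
    n_perm: int = 10000,
    cluster_p: float = 0.05,
    scheme: str = "sign-flip",
    seed=0,
    *,
    connectivity: str = "auto",
    two_tailed_threshold: bool = True,
) -> ClusterTestResult:
    """Cluster-mass permutation test of a zero-mean null per point.

    Parameters
    ----------
    data : array (n_subjects, *map_shape), or a pair ``(x, y)`` of such
        arrays for the paired two-condition case (``scheme="label-permute"``,
        reduced internally to the difference scores — per-subject label
        exchange is exactly a sign flip of the difference).
    n_perm : permutations; all ``2**n`` sign patterns are enumerated when
        they fit within this budget.
    cluster_p : cluster-defining p (two-tailed t critical value at
        ``n - 1`` df by default).
    """
    if isinstance(data, tuple):
        if scheme != "label-permute":
            raise ValueError("pass a single difference array for sign-flip")
        x, y = data
        data = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small", stacklevel=2)
    map_shape = data.shape[1:]
    flat = data.reshape(n, -1)

    tail_p = cluster_p / 2 if two_tailed_threshold else cluster_p
    threshold = float(stats.t.ppf(1 - tail_p, df=n - 1))

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_patterns(n, n_perm, rng)
    ssq = (flat**2).sum(axis=0)
    means = (signs @ flat) / n
    tmaps = _t_maps(means, ssq, n).reshape((signs.shape[0],) + map_shape)

    obs_t = _t_maps((flat.mean(axis=0))[None, :], ssq, n)[0].reshape(map_shape)
    clusters = find_clusters(obs_t, threshold, connectivity)

    mx, mn = _extremes_nd(tmaps, threshold, connectivity)
    # outward-rounded order statistics: guarantees FWER <= alpha for the
    # discrete permutation distribution (interpolated percentiles are
    # slightly liberal)
    critical_high = float(np.percentile(mx, 97.5, method="higher"))
    critical_low = float(np.percentile(mn, 2.5, method="lower"))
    significant = [
        c for c in clusters
        if (c.mass > critical_high and c.sign > 0)
        or (c.mass < critical_low and c.sign < 0)
    ]
    return ClusterTestResult(
        statistic=obs_t, threshold=threshold, clusters=clusters,
        null_max=mx, null_min=mn,
        critical_high=critical_high, critical_low=critical_low,
        significant=significant, n_perm=signs.shape[0], exhaustive=exhaustive,
    )


def correlation_cluster_test(
    amplitudes,
    sizes,
    r_threshold: float = 0.5,
    n_perm: int = 10000,
    seed=0,
    *,
    fisher_z: bool = False,
) -> ClusterTestResult:
    """Cluster test of the inter-subject amplitude-illusion correlation.

    Observed clusters are runs of time points with ``|r| > r_threshold``;
    cluster mass sums the raw r values (Fisher-z transformed first when
    ``fisher_z``).  The null permutes the illusion-size vector across
    subjects, destroying any amplitude-size pairing while keeping both
    marginals intact.
    """
    amp = np.asarray(amplitudes, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if amp.ndim != 2 or amp.shape[0] != sizes.size:
        raise ValueError("amplitudes must be subjects x time, one size each")
    n = sizes.size
    if n < 3:
        raise ValueError("need >= 3 subjects")
    if sizes.std() == 0:
        raise ValueError("illusion sizes have zero variance")

    a = amp - amp.mean(axis=0, keepdims=True)
    denom_a = np.sqrt((a**2).sum(axis=0))
    s = sizes - sizes.mean()
    denom_s = np.sqrt((s**2).sum())

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=int)
    perms[0] = np.arange(n)  # observed pairing included in the null
    for p in range(1, n_perm):
        perms[p] = rng.permutation(n)
    s_perm = s[perms]                              # (P, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmaps = np.where(denom_a > 0, (s_perm @ a) / (denom_a * denom_s), 0.0)
    if fisher_z:
        rmaps = np.arctanh(np.clip(rmaps, -0.999999, 0.999999))
        r_threshold = float(np.arctanh(r_threshold))

    obs = rmaps[0]
    clusters = find_clusters(obs, r_threshold, "1d")
    mx, mn = _batch_extremes_1d(rmaps, r_threshold)
    critical_high = float(np.percentile(mx, 97.5, method="higher"))
    critical_low = float(np.percentile(mn, 2.5, method="lower"))
    significant = [
        c for c in clusters
        if (c.mass > critical_high and c.sign > 0)
        or (c.mass < critical_low and c.sign < 0)
    ]
    return ClusterTestResult(
        statistic=obs, threshold=r_threshold, clusters=clusters,
        null_max=mx, null_min=mn,
        critical_high=critical_high, critical_low=critical_low,
        significant=significant, n_perm=n_perm, exhaustive=False,
    )


def bootstrap_band(
    timecourses, n_boot: int = 1000, level: float = 0.95, seed=0
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap percentile band of the subject-mean time course.

    Subjects are resampled with replacement ``n_boot`` times; the band is
    the central ``level`` percentile interval of the resampled means at
    each time point.  Returns ``(low, high)`` arrays.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[0] < 2:
        raise ValueError("need a 2-D subjects x time array with >= 2 subjects")
    rng = np.random.default_rng(seed)
    n = tc.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = tc[idx].mean(axis=1)              # (n_boot, time)
    alpha = 100 * (1 - level) / 2
    lo = np.percentile(boot_means, alpha, axis=0)
    hi = np.percentile(boot_means, 100 - alpha, axis=0)
    return lo, hi
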