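"""Group-level mass-univariate permutation inference on classification arrays.

Participants' z-scored classification arrays are combined pointwise into
either a one-sample t map (is the group mean array nonzero?) or a Pearson
r map against bubbles-block accuracy (do better performers show stronger
classification values?). Familywise error over the many frames/pixels is
controlled two ways, both permutation-based:

* **cluster test** — points whose statistic exceeds a cluster-forming
  threshold are grouped by contiguity, each cluster summarized by its mass
  (sum of suprathreshold |statistic|) or extent, and compared with the
  permutation distribution of the *maximal* cluster metric;
* **max-statistic (single-threshold) test** — each point's statistic is
  compared with the permutation distribution of the maximal |statistic| over
  the whole array.

The null is built by sign-flipping each participant's whole array (t maps;
exact under per-participant symmetry about zero) or by permuting the accuracy
vector across participants (r maps). Full enumeration of the 2^n sign
patterns or n! orderings replaces Monte-Carlo sampling whenever it fits the
permutation budget. Stat maps are also reported normalized by the forming
threshold, so |normalized| > 1 marks potential cluster membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "StatConfig",
    "Cluster",
    "ClusterResult",
    "t_map",
    "r_map",
    "cluster_permutation_test",
    "transformed_r_ci",
]


@dataclass
class StatConfig:
    """Settings for a group permutation test.

    ``cluster_forming_threshold`` defaults to the parametric critical value of
    the statistic's null distribution at the config's tail and alpha (e.g. the
    two-tailed p = .05 Student-t critical value at n-1 df for t maps).
    ``connectivity`` = 1 gives 4-connectivity in 2-D (edge-sharing neighbors),
    2 gives 8-connectivity.
    """

    statistic: str = "t"
    cluster_forming_threshold: float | None = None
    cluster_metric: str = "mass"
    n_permutations: int = 10000
    tail: str = "two"
    alpha: float = 0.05
    connectivity: int = 1
    seed: int | None = None
    force_monte_carlo: bool = False

    def __post_init__(self) -> None:
        if self.statistic not in ("t", "r"):
            raise ValueError(f"statistic must be 't' or 'r', got {self.statistic!r}")
        if self.cluster_metric not in ("mass", "extent"):
            raise ValueError(f"unknown cluster_metric {self.cluster_metric!r}")
        if self.tail not in ("two", "one"):
            raise ValueError(f"tail must be 'two' or 'one', got {self.tail!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if (
            self.cluster_forming_threshold is not None
            and self.cluster_forming_threshold <= 0
        ):
            raise ValueError("cluster_forming_threshold must be > 0")

    def forming_threshold(self, n_participants: int) -> float:
        if self.cluster_forming_threshold is not None:
            return self.cluster_forming_threshold
        q = 1 - self.alpha / 2 if self.tail == "two" else 1 - self.alpha
        if self.statistic == "t":
            return float(stats.t.ppf(q, n_participants - 1))
        tc = stats.t.ppf(q, n_participants - 2)
        return float(tc / math.sqrt(n_participants - 2 + tc**2))


@dataclass
class Cluster:
    """A contiguous suprathreshold region with its corrected p-value."""

    members: np.ndarray  # boolean mask over the domain
    sign: int
    extent: int
    mass: float
    metric: float
    p: float

    def bounds(self) -> list[tuple[int, int]]:
        """Inclusive index bounds per axis (0-based array indices)."""
        idx = np.nonzero(self.members)
        return [(int(ax.min()), int(ax.max())) for ax in idx]

    def to_dict(self) -> dict:
        return {
            "sign": self.sign,
            "extent": self.extent,
            "mass": float(self.mass),
            "metric": float(self.metric),
            "p": float(self.p),
            "bounds": self.bounds(),
        }


@dataclass
class ClusterResult:
    """Output of :func:`cluster_permutation_test`."""

    stat_map: np.ndarray
    normalized_map: np.ndarray
    threshold: float
    clusters: list[Cluster]
    pointwise_max_p: np.ndarray
    degenerate: np.ndarray
    method: str  # "enumeration" or "monte-carlo"
    n_null: int
    config: StatConfig
    ci_halfwidth: float | None = None
    ci_infinite: np.ndarray | None = None

    def significant_clusters(self, alpha: float | None = None) -> list[Cluster]:
        a = self.config.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p <= a]


def t_map(z_arrays) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise one-sample t of participant arrays against zero.

    Returns ``(t, degenerate)``; points with zero across-participant SD are
    flagged degenerate and get t = 0.
    """
    Z = np.asarray(z_arrays, dtype=float)
    n = Z.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 participants, got {n}")
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    degenerate = sd == 0
    t = np.zeros_like(mean)
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / math.sqrt(n))
    return t, degenerate


def r_map(z_arrays, performance) -> np.ndarray:
    """Pointwise Pearson correlation of participant arrays with accuracy."""
    Z = np.asarray(z_arrays, dtype=float)
    perf = np.asarray(performance, dtype=float)
    n = Z.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 participants, got {n}")
    if len(perf) != n:
        raise ValueError("performance length does not match participants")
    if np.std(perf) == 0:
        raise ValueError("performance has zero variance; r map undefined")
    pz = (perf - perf.mean()) / perf.std(ddof=1)
    flat = Z.reshape(n, -1)
    zm = flat - flat.mean(axis=0)
    zsd = flat.std(axis=0, ddof=1)
    r = np.zeros(flat.shape[1])
    ok = zsd > 0
    r[ok] = (pz @ zm[:, ok]) / ((n - 1) * zsd[ok])
    return np.clip(r, -1.0, 1.0).reshape(Z.shape[1:])


def _label_clusters(exceed: np.ndarray, connectivity: int):
    structure = ndimage.generate_binary_structure(exceed.ndim, connectivity)
    return ndimage.label(exceed, structure=structure)


def _cluster_metrics(
    stat: np.ndarray, threshold: float, tail: str, metric: str, connectivity: int
):
    """Yield (mask, sign, extent, mass) for every suprathreshold cluster."""
    signs = (1, -1) if tail == "two" else (1,)
    out = []
    for sign in signs:
        exceed = stat > threshold if sign == 1 else stat < -threshold
        labels, n_lab = _label_clusters(exceed, connectivity)
        for lab in range(1, n_lab + 1):
            mask = labels == lab
            mass = float(np.abs(stat[mask]).sum())
            out.append((mask, sign, int(mask.sum()), mass))
    return out


def _max_cluster_metric(
    stat: np.ndarray, threshold: float, tail: str, metric: str, connectivity: int
) -> float:
    best = 0.0
    for _, _, extent, mass in _cluster_metrics(stat, threshold, tail, metric, connectivity):
        best = max(best, extent if metric == "extent" else mass)
    return best


def _sign_patterns(
    n: int, n_permutations: int, rng: np.random.Generator, force_mc: bool = False
):
    if not force_mc and 2**n <= n_permutations:
        codes = np.arange(2**n, dtype=np.int64)
        S = ((codes[:, None] >> np.arange(n)) & 1) * 2 - 1
        return S.astype(float), "enumeration"
    S = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    return S, "monte-carlo"


def _perf_orders(
    n: int, n_permutations: int, rng: np.random.Generator, force_mc: bool = False
):
    if not force_mc and math.factorial(n) <= n_permutations:
        P = np.array(list(iter_permutations(range(n))), dtype=np.intp)
        return P, "enumeration"
    P = np.array(
        [rng.permutation(n) for _ in range(n_permutations)], dtype=np.intp
    )
    return P, "monte-carlo"


def _null_t_maps(flat: np.ndarray, S: np.ndarray) -> np.ndarray:
    """One-sample t maps for every sign-flip pattern; (n_patterns, m)."""
    n = flat.shape[0]
    ss = np.einsum("ij,ij->j", flat, flat)  # invariant under sign flips
    M = (S @ flat) / n
    var = (ss[None, :] - n * M**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = M / np.sqrt(var / n)
    T[~np.isfinite(T)] = 0.0
    return T


def _null_r_maps(flat: np.ndarray, perf: np.ndarray, P: np.ndarray) -> np.ndarray:
    n = flat.shape[0]
    pz = (perf - perf.mean()) / perf.std(ddof=1)
    zm = flat - flat.mean(axis=0)
    zsd = flat.std(axis=0, ddof=1)
    denom = np.where(zsd > 0, (n - 1) * zsd, np.inf)
    R = (pz[P] @ zm) / denom[None, :]
    return np.clip(R, -1.0, 1.0)


def cluster_permutation_test(
    z_arrays,
    config: StatConfig,
    performance=None,
    exclude=None,
) -> ClusterResult:
    """Cluster-based and max-statistic corrected group permutation test.

    ``z_arrays``: per-participant arrays stacked on axis 0. For ``statistic
    = "r"`` a per-participant ``performance`` vector (proportion correct) is
    required. ``exclude`` optionally masks points (e.g. degenerate
    within-participant flags) out of cluster formation and the max-statistic
    scan while keeping output shapes intact.

    Corrected p-values use the exact count over a full enumeration when the
    null space fits within ``config.n_permutations``, otherwise the add-one
    Monte-Carlo estimator (1 + #null >= observed) / (1 + n_permutations).
    A threshold so high that no cluster forms gives a valid result with an
    empty cluster list.
    """
    Z = np.asarray(z_arrays, dtype=float)
    n = Z.shape[0]
    domain_shape = Z.shape[1:]
    rng = np.random.default_rng(config.seed)

    if config.statistic == "r":
        if performance is None:
            raise ValueError("statistic 'r' requires a performance vector")
        stat = r_map(Z, performance)
        degenerate = np.std(Z, axis=0, ddof=1) == 0
    else:
        stat, degenerate = t_map(Z)

    valid = ~degenerate
    if exclude is not None:
        valid &= ~np.asarray(exclude, dtype=bool)
    threshold = config.forming_threshold(n)

    masked = np.where(valid, stat, 0.0)
    observed = _cluster_metrics(
        masked, threshold, config.tail, config.cluster_metric, config.connectivity
    )

    flat = Z.reshape(n, -1)[:, valid.ravel()]
    if config.statistic == "r":
        P, method = _perf_orders(
            n, config.n_permutations, rng, config.force_monte_carlo
        )
        null_flat = _null_r_maps(flat, np.asarray(performance, float), P)
    else:
        S, method = _sign_patterns(
            n, config.n_permutations, rng, config.force_monte_carlo
        )
        null_flat = _null_t_maps(flat, S)
    n_null = null_flat.shape[0]

    null_map = np.zeros(domain_shape)
    vidx = valid.ravel()
    null_max_metric = np.empty(n_null)
    for i in range(n_null):
        null_map.reshape(-1)[vidx] = null_flat[i]
        null_max_metric[i] = _max_cluster_metric(
            null_map,
            threshold,
            config.tail,
            config.cluster_metric,
            config.connectivity,
        )
    if config.tail == "two":
        null_max_stat = np.abs(null_flat).max(axis=1, initial=0.0)
    else:
        null_max_stat = null_flat.max(axis=1, initial=-np.inf)

    def corrected_p(count_ge: np.ndarray | float):
        if method == "enumeration":
            return np.asarray(count_ge) / n_null
        return (1.0 + np.asarray(count_ge)) / (1.0 + n_null)

    clusters = []
    for mask, sign, extent, mass in observed:
        metric = float(extent if config.cluster_metric == "extent" else mass)
        p = float(corrected_p(np.sum(null_max_metric >= metric)))
        clusters.append(
            Cluster(members=mask, sign=sign, extent=extent, mass=mass,
                    metric=metric, p=min(p, 1.0))
        )
    clusters.sort(key=lambda c: c.p)

    obs_cmp = np.abs(masked) if config.tail == "two" else masked
    counts = (null_max_stat[:, None] >= obs_cmp.reshape(1, -1)).sum(axis=0)
    pointwise = np.minimum(corrected_p(counts), 1.0).reshape(domain_shape)
    pointwise[~valid] = 1.0

    ci_halfwidth = None
    ci_infinite = None
    if config.statistic == "r" and n >= 4:
        level = 1 - config.alpha
        ci_halfwidth = float(stats.norm.ppf((1 + level) / 2) / math.sqrt(n - 3))
        ci_infinite = np.abs(stat) >= 1.0

    return ClusterResult(
        stat_map=stat,
        normalized_map=stat / threshold,
        threshold=threshold,
        clusters=clusters,
        pointwise_max_p=pointwise,
        degenerate=~valid,
        method=method,
        n_null=n_null,
        config=config,
        ci_halfwidth=ci_halfwidth,
        ci_infinite=ci_infinite,
    )


def transformed_r_ci(r_values, n: int, level: float = 0.95):
    """Constant-width confidence interval for r on the Fisher-z scale.

    Returns ``(center, halfwidth, infinite)``: atanh(r) with half-width
    z_(1+level)/2 / sqrt(n - 3), constant across points; the interval excludes
    zero exactly where the uncorrected two-tailed test at ``1 - level`` is
    significant. Points with |r| = 1 map to infinity and are flagged.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 participants, got {n}")
    r = np.asarray(r_values, dtype=float)
    infinite = np.abs(r) >= 1.0
    with np.errstate(divide="ignore"):
        center = np.arctanh(np.clip(r, -1.0, 1.0))
    halfwidth = float(stats.norm.ppf((1 + level) / 2) / math.sqrt(n - 3))
    return center, halfwidth, infinite
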