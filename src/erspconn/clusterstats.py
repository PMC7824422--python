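"""Cluster-based non-parametric permutation test over electrodes.

Dependent-samples t-maps are thresholded at an uncorrected cluster-forming
alpha, supra-threshold electrodes are grouped into sign-homogeneous
connected components of the electrode-neighborhood graph, and cluster mass
(summed t) is compared against a max-statistic permutation null built by
sign-flipping per-subject condition differences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import spatial, stats

__all__ = [
    "NeighborGraph",
    "TMap",
    "Cluster",
    "ClusterResult",
    "paired_t_map",
    "build_neighbors",
    "find_clusters",
    "permutation_test",
]


@dataclass
class NeighborGraph:
    """Symmetric electrode adjacency with zero diagonal."""

    adjacency: np.ndarray
    labels: list[str] | None = None
    method: str = "distance"
    threshold: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a
        self._neighbors = [np.nonzero(a[i])[0] for i in range(a.shape[0])]

    @property
    def n_electrodes(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self._neighbors[i]


@dataclass
class TMap:
    """Per-electrode dependent-samples t statistic."""

    t: np.ndarray
    df: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        if not np.all(np.isfinite(self.t)):
            raise ValueError("t values must be finite")
        if self.df < 1:
            raise ValueError("df must be ≥ 1")


@dataclass
class Cluster:
    electrodes: list[int]
    mass: float
    sign: int
    p_corrected: float | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max: np.ndarray
    n_permutations: int
    mode: str = "montecarlo"  # or "exact"
    alpha: float = 0.05

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < self.alpha]


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray) -> TMap:
    """Per-electrode dependent-samples t for d = cond_a − cond_b.

    Electrodes with zero variance of d get t = 0 (undefined statistic,
    conservative).
    """
    a = np.asarray(cond_a, dtype=np.float64)
    b = np.asarray(cond_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have the same shape")
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need subjects × electrodes with n_subjects ≥ 2")
    d = a - b
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return TMap(t, n - 1)


def build_neighbors(
    montage,
    threshold: float | None = None,
    method: str = "distance",
) -> NeighborGraph:
    """Electrode adjacency from 2-D positions.

    ``method="distance"``: neighbors are electrode pairs closer than the
    threshold (default 1.3 × median nearest-neighbor distance).
    ``method="delaunay"``: edges of the Delaunay triangulation.
    """
    pos = np.asarray(montage.pos2d, dtype=np.float64)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("need at least 2 electrodes")
    if method == "distance":
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if threshold is None:
            threshold = 1.3 * float(np.median(d.min(axis=1)))
        adj = d < threshold
        np.fill_diagonal(adj, False)
    elif method == "delaunay":
        tri = spatial.Delaunay(pos)
        adj = np.zeros((n, n), dtype=bool)
        for simplex in tri.simplices:
            for i in simplex:
                for j in simplex:
                    if i != j:
                        adj[i, j] = True
    else:
        raise ValueError(f"unknown neighbor method {method!r}")
    if not adj.any(axis=1).all():
        warnings.warn("neighbor graph has isolated electrodes", stacklevel=2)
    return NeighborGraph(adj, list(getattr(montage, "labels", [])) or None,
                         method, threshold)


def _components(candidates: np.ndarray, graph: NeighborGraph) -> list[list[int]]:
    """Connected components restricted to ``candidates`` (boolean mask)."""
    seen = np.zeros(len(candidates), dtype=bool)
    comps = []
    for start in np.nonzero(candidates)[0]:
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            node = stack.pop()
            comp.append(int(node))
            for nb in graph.neighbors(node):
                if candidates[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps


def find_clusters(
    tmap: TMap, graph: NeighborGraph, alpha_cluster: float = 0.05
) -> list[Cluster]:
    """Sign-homogeneous connected clusters of supra-threshold electrodes.

    The cluster-forming threshold is the two-tailed critical t at
    ``alpha_cluster`` for the map's df; cluster mass is the sum of member
    t values.
    """
    if graph.n_electrodes != len(tmap.t):
        raise ValueError("graph size does not match t-map")
    tcrit = float(stats.t.ppf(1.0 - alpha_cluster / 2.0, tmap.df))
    clusters = []
    for sign in (1, -1):
        mask = sign * tmap.t > tcrit
        for comp in _components(mask, graph):
            mass = float(tmap.t[comp].sum())
            clusters.append(Cluster(comp, mass, sign))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_cluster_mass(
    t: np.ndarray, tcrit: float, graph: NeighborGraph
) -> float:
    best = 0.0
    for sign in (1, -1):
        mask = sign * t > tcrit
        if not mask.any():
            continue
        for comp in _components(mask, graph):
            best = max(best, abs(float(t[comp].sum())))
    return best


def _t_for_signs(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized paired t-maps for many sign-flip patterns.

    ``d`` is subjects × electrodes, ``signs`` patterns × subjects (±1).
    Uses the identity mean((s·d)²) = mean(d²), so only the mean changes
    per pattern.
    """
    n = d.shape[0]
    mean = signs @ d / n  # patterns × electrodes
    meansq = (d**2).mean(axis=0)  # electrodes
    var = (meansq - mean**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    t = np.zeros_like(mean)
    ok = var > 0
    t[ok] = mean[ok] / np.sqrt(var[ok] / n)
    return t


def permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha_cluster: float = 0.05,
    alpha: float = 0.05,
    exact_max_subjects: int = 12,
) -> ClusterResult:
    """Cluster permutation test with max-statistic correction.

    Condition labels are swapped within subjects (sign flips of d), the
    t-map recomputed, and the maximum |cluster mass| collected into the
    null.  Observed clusters get p = (1 + #{null ≥ |mass|}) / (n_perm + 1);
    with n ≤ ``exact_max_subjects`` and n_perm > 2ⁿ the full set of 2ⁿ
    sign patterns is enumerated instead and p is the exact fraction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    d = np.asarray(cond_a, dtype=np.float64) - np.asarray(cond_b, dtype=np.float64)
    n = d.shape[0]
    tmap = paired_t_map(cond_a, cond_b)
    observed = find_clusters(tmap, graph, alpha_cluster)
    tcrit = float(stats.t.ppf(1.0 - alpha_cluster / 2.0, tmap.df))

    if n <= exact_max_subjects and n_perm > 2**n:
        mode = "exact"
        bits = np.arange(2**n)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
    else:
        mode = "montecarlo"
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_all = _t_for_signs(d, signs.astype(np.float64))
    null_max = np.array(
        [_max_cluster_mass(t_all[p], tcrit, graph) for p in range(signs.shape[0])]
    )
    for c in observed:
        count = int(np.sum(null_max >= abs(c.mass) - 1e-12))
        if mode == "exact":
            c.p_corrected = count / len(null_max)
        else:
            c.p_corrected = (1 + count) / (len(null_max) + 1)
    return ClusterResult(observed, null_max, len(null_max), mode, alpha)
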