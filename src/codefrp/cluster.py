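"""Spatiotemporal cluster-based paired permutation test on FRP difference
waves.

Per (electrode, time) point a paired t statistic is computed across
participants. Points exceeding the one-sided critical t (p < .05, df =
n - 1) are clustered under the union of spatial adjacency (neighbouring
electrodes at the same time point) and temporal adjacency (consecutive
time points at the same electrode); clusters need at least two members.
The cluster statistic is the mass (sum of member t values). Its null
distribution is the maximum (or minimum, for the "less" direction)
cluster mass over sign-flips of each participant's difference wave -
exhaustive over all 2^n assignments when feasible, seeded Monte Carlo
otherwise (always including the identity assignment, so p >= 1/N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DifferenceWaveSet
from .montage import AdjacencyGraph

__all__ = [
    "TMap",
    "Cluster",
    "PermutationResult",
    "paired_t_map",
    "form_clusters",
    "cluster_permutation_test",
    "summarize_clusters",
]


@dataclass
class TMap:
    electrodes: tuple[str, ...]
    times_ms: np.ndarray
    t: np.ndarray  # electrodes x times
    df: int
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be at least 1")
        if self.t.shape != (len(self.electrodes), len(self.times_ms)):
            raise ValueError("t must be electrodes x times")


@dataclass
class Cluster:
    members: tuple[tuple[int, int], ...]  # (electrode index, time index)
    mass: float
    direction: str
    electrodes: tuple[str, ...]
    tmin_ms: float
    tmax_ms: float
    p_value: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PermutationResult:
    clusters: list[Cluster]
    n_permutations: int
    mode: str  # "exhaustive" or "monte_carlo"
    direction: str
    alpha: float
    threshold_t: float
    df: int
    seed: int | None = None
    null_extrema: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value < self.alpha]


# --------------------------------------------------------------------------
# t maps


def _t_rows(signs: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Paired t statistics for many sign assignments at once.

    signs is (P, n); X is (n, M). Sign-flipping leaves per-point second
    moments untouched, so t follows from the flipped means alone. Points
    with zero variance get t = 0 when the mean is 0, else sign-consistent
    infinity.
    """
    n = X.shape[0]
    m = signs @ X / n
    msq = np.mean(X * X, axis=0)
    var = (msq[None, :] - m * m) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    zero_var = var <= 1e-24
    t = np.where(zero_var & (m == 0), 0.0, t)
    t = np.where(zero_var & (m > 0), np.inf, t)
    t = np.where(zero_var & (m < 0), -np.inf, t)
    return t


def paired_t_map(
    diffs: DifferenceWaveSet, window_ms: tuple[float, float] = (100.0, 1000.0)
) -> TMap:
    """Pointwise paired t statistics of the difference waves against zero,
    restricted to the analysis window."""
    if diffs.n < 2:
        raise ValueError("need at least 2 participants")
    sel = (diffs.times_ms >= window_ms[0]) & (diffs.times_ms <= window_ms[1])
    X = diffs.data[:, :, sel]
    n, E, T = X.shape
    t = _t_rows(np.ones((1, n)), X.reshape(n, -1)).reshape(E, T)
    return TMap(
        electrodes=diffs.channels,
        times_ms=diffs.times_ms[sel],
        t=t,
        df=n - 1,
        window_ms=window_ms,
    )


# --------------------------------------------------------------------------
# clustering


def _grid_edges(
    electrodes: tuple[str, ...], n_times: int, adjacency: AdjacencyGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-index edge list of the spatiotemporal grid graph."""
    index = {ch: i for i, ch in enumerate(electrodes)}
    ea, eb = [], []
    for a, b in sorted(adjacency.edges):
        if a not in index or b not in index:
            continue
        ia, ib = index[a], index[b]
        for t in range(n_times):
            ea.append(ia * n_times + t)
            eb.append(ib * n_times + t)
    for e in range(len(electrodes)):
        for t in range(n_times - 1):
            ea.append(e * n_times + t)
            eb.append(e * n_times + t + 1)
    return np.asarray(ea, dtype=np.int64), np.asarray(eb, dtype=np.int64)


def _components(
    sel_a: np.ndarray, sel_b: np.ndarray
) -> dict[int, list[int]]:
    """Connected components (as root -> nodes) of the selected edges."""
    parent: dict[int, int] = {}

    def find(u: int) -> int:
        root = u
        while parent[root] != root:
            root = parent[root]
        while parent[u] != root:
            parent[u], u = root, parent[u]
        return root

    for a, b in zip(sel_a, sel_b):
        a, b = int(a), int(b)
        if a not in parent:
            parent[a] = a
        if b not in parent:
            parent[b] = b
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for u in parent:
        comps.setdefault(find(u), []).append(u)
    return comps


def form_clusters(
    tmap: TMap,
    threshold_t: float,
    adjacency: AdjacencyGraph,
    direction: str = "greater",
    min_size: int = 2,
) -> list[Cluster]:
    """Connected suprathreshold sets with at least ``min_size`` members.

    For direction "greater" the suprathreshold mask is t > threshold_t;
    for "less" it is t < -threshold_t. Isolated suprathreshold points are
    discarded (a cluster needs at least two adjacent points).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    E, T = tmap.t.shape
    flat_t = tmap.t.ravel()
    mask = flat_t > threshold_t if direction == "greater" else flat_t < -threshold_t
    ea, eb = _grid_edges(tmap.electrodes, T, adjacency)
    on = mask[ea] & mask[eb]
    comps = _components(ea[on], eb[on])
    in_edge = set()
    for nodes in comps.values():
        in_edge.update(nodes)
    if min_size <= 1:
        for u in np.flatnonzero(mask):
            if int(u) not in in_edge:
                comps[int(u)] = [int(u)]
    clusters = []
    for nodes in comps.values():
        if len(nodes) < min_size:
            continue
        nodes = sorted(nodes)
        members = tuple((u // T, u % T) for u in nodes)
        mass = float(flat_t[nodes].sum())
        els = tuple(sorted({tmap.electrodes[e] for e, _ in members}))
        ts = [tmap.times_ms[t] for _, t in members]
        clusters.append(
            Cluster(
                members=members,
                mass=mass,
                direction=direction,
                electrodes=els,
                tmin_ms=float(min(ts)),
                tmax_ms=float(max(ts)),
            )
        )
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _grid_csr(ea: np.ndarray, eb: np.ndarray, n_nodes: int):
    from scipy import sparse

    return sparse.csr_matrix(
        (np.ones(2 * len(ea)), (np.r_[ea, eb], np.r_[eb, ea])),
        shape=(n_nodes, n_nodes),
    )


def _null_extrema(
    t_rows: np.ndarray,
    threshold_t: float,
    direction: str,
    grid_csr,
    min_size: int = 2,
) -> np.ndarray:
    """Extreme cluster mass per sign assignment (0 when no cluster)."""
    from scipy.sparse.csgraph import connected_components

    out = np.zeros(t_rows.shape[0])
    if direction == "greater":
        masks = t_rows > threshold_t
    else:
        masks = t_rows < -threshold_t
    for i in range(t_rows.shape[0]):
        idx = np.flatnonzero(masks[i])
        if idx.size < min_size:
            continue
        sub = grid_csr[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        masses = np.bincount(labels, weights=t_rows[i, idx], minlength=n_comp)
        sizes = np.bincount(labels, minlength=n_comp)
        ok = sizes >= min_size
        if not ok.any():
            continue
        out[i] = masses[ok].max() if direction == "greater" else masses[ok].min()
    return out


def cluster_permutation_test(
    diffs: DifferenceWaveSet,
    adjacency: AdjacencyGraph,
    direction: str = "greater",
    alpha: float = 0.05,
    threshold_t: float | None = None,
    window_ms: tuple[float, float] = (100.0, 1000.0),
    min_size: int = 2,
    max_exhaustive: int = 2**20,
    n_monte_carlo: int = 10_000,
    seed: int | None = None,
    chunk: int = 2048,
) -> PermutationResult:
    """One-sided spatiotemporal cluster permutation test.

    Channels are restricted to the adjacency nodes and time points to the
    analysis window. The cluster-forming threshold defaults to the
    one-sided critical t at p < .05 with df = n - 1.
    """
    keep = [i for i, ch in enumerate(diffs.channels) if ch in set(adjacency.nodes)]
    channels = tuple(diffs.channels[i] for i in keep)
    sel = (diffs.times_ms >= window_ms[0]) & (diffs.times_ms <= window_ms[1])
    X3 = diffs.data[:, keep, :][:, :, sel]
    n, E, T = X3.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    X = X3.reshape(n, E * T)
    df = n - 1
    if threshold_t is None:
        threshold_t = float(stats.t.ppf(1 - 0.05, df))

    tmap = TMap(
        electrodes=channels,
        times_ms=diffs.times_ms[sel],
        t=_t_rows(np.ones((1, n)), X).reshape(E, T),
        df=df,
        window_ms=window_ms,
    )
    ea, eb = _grid_edges(channels, T, adjacency)
    clusters = form_clusters(tmap, threshold_t, adjacency, direction, min_size)

    n_exhaustive = 2**n
    if n_exhaustive <= max_exhaustive:
        mode = "exhaustive"
        bits = np.arange(n_exhaustive, dtype=np.int64)
        signs = np.where(
            (bits[:, None] >> np.arange(n)[None, :]) & 1, -1.0, 1.0
        )
        n_perm = n_exhaustive
    else:
        mode = "monte_carlo"
        if n_monte_carlo < 100:
            raise ValueError("n_monte_carlo below 100 gives unstable p values")
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_monte_carlo, n))
        signs[0] = 1.0  # the observed assignment is always part of the null
        n_perm = n_monte_carlo

    grid = _grid_csr(ea, eb, E * T)
    null = np.empty(n_perm)
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        t_rows = _t_rows(signs[lo:hi], X)
        null[lo:hi] = _null_extrema(t_rows, threshold_t, direction, grid, min_size)

    for c in clusters:
        if direction == "greater":
            c.p_value = float(np.mean(null >= c.mass))
        else:
            c.p_value = float(np.mean(null <= c.mass))
    clusters.sort(key=lambda c: (c.p_value, -abs(c.mass)))
    return PermutationResult(
        clusters=clusters,
        n_permutations=n_perm,
        mode=mode,
        direction=direction,
        alpha=alpha,
        threshold_t=threshold_t,
        df=df,
        seed=seed,
        null_extrema=null,
    )


def summarize_clusters(results: list[PermutationResult] | PermutationResult) -> pd.DataFrame:
    """One row per cluster: direction, time extent, electrodes, mass, p.

    Sorted by p ascending, ties by larger |mass| first.
    """
    if isinstance(results, PermutationResult):
        results = [results]
    rows = []
    for res in results:
        for c in res.clusters:
            rows.append(
                {
                    "direction": c.direction,
                    "tmin_ms": c.tmin_ms,
                    "tmax_ms": c.tmax_ms,
                    "n_points": c.size,
                    "electrodes": ",".join(c.electrodes),
                    "mass": c.mass,
                    "p_value": c.p_value,
                    "significant": c.p_value is not None and c.p_value < res.alpha,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "direction",
            "tmin_ms",
            "tmax_ms",
            "n_points",
            "electrodes",
            "mass",
            "p_value",
            "significant",
        ],
    )
    if len(out):
        out = out.sort_values(
            by=["p_value", "mass"],
            key=lambda s: s.abs().rsub(0) if s.name == "mass" else s,
        ).reset_index(drop=True)
    return out
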