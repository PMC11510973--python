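"""Binary functional brain networks and their graph-theoretic analysis.

A connectivity matrix is binarized at a threshold (strictly greater-than:
an edge exists where WPLI exceeds the threshold).  The threshold is
either given per band — the usual published choices for this pipeline
are 0.36/0.42/0.40/0.26 for delta/theta/alpha/beta and 0.35 for fNIRS —
or selected automatically as the largest grid value under two
constraints: mean node degree >= ln(N), and the network is small-world
(sigma > 1 against degree-preserving rewired surrogates).

Metrics: node degree, clustering coefficient (per node and network
mean), global and local efficiency (Latora-Marchiori, per node and
network), normalized betweenness centrality with a key-node rule, the
small-world index sigma, and Mann-Whitney group comparisons between the
non-motion-sickness and motion-sickness segment groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .connectivity import ConnectivityMatrix

#: published per-band binarization thresholds for this pipeline
DEFAULT_THRESHOLDS: dict[str, float] = {
    "delta": 0.36, "theta": 0.42, "alpha": 0.40, "beta": 0.26, "COE": 0.35,
}


class NetworkError(ValueError):
    """Raised on invalid network operations."""


class ThresholdInfeasibleError(NetworkError):
    """No grid threshold satisfies the degree and small-world constraints."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "no feasible threshold; constraint violations per grid value:\n  "
            + "\n  ".join(violations))


@dataclass(frozen=True)
class BrainNetwork:
    """Binary undirected graph over channels with threshold provenance."""

    adjacency: np.ndarray
    channel_names: tuple[str, ...]
    threshold: float
    band: str

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.issubdtype(a.dtype, np.integer):
            if not np.all(np.isin(a, (0, 1))):
                raise NetworkError("adjacency must be binary")
            a = a.astype(int)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        n = len(self.channel_names)
        if a.shape != (n, n):
            raise NetworkError(f"adjacency shape {a.shape} != ({n}, {n})")
        if not np.array_equal(a, a.T):
            raise NetworkError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise NetworkError("self-loops are not allowed")
        if not np.all(np.isin(a, (0, 1))):
            raise NetworkError("adjacency must be binary")

    @property
    def n_nodes(self) -> int:
        return len(self.channel_names)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.channel_names)))


def binarize(conn: ConnectivityMatrix, threshold: float) -> BrainNetwork:
    """Edge where connectivity strictly exceeds the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise NetworkError(f"threshold {threshold} not in [0, 1]")
    a = (conn.values > threshold).astype(int)
    np.fill_diagonal(a, 0)
    return BrainNetwork(a, conn.channel_names, threshold, conn.band)


# ---------------------------------------------------------------------------
# metrics

def degree(net: BrainNetwork) -> np.ndarray:
    return net.adjacency.sum(axis=1).astype(int)


def clustering(net: BrainNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients C_i = 2 E_i / (k_i (k_i - 1)) and mean.

    C_i is 0 for nodes with fewer than two neighbours.
    """
    cc = nx.clustering(net.graph())
    per_node = np.array([cc[name] for name in net.channel_names])
    return per_node, float(per_node.mean())


def _efficiency_from_adj(a: np.ndarray) -> tuple[float, np.ndarray]:
    """Global efficiency of a binary adjacency: scalar and per-node values.

    E(i) = (1/(N-1)) sum_{j != i} 1/d_ij, with 1/inf = 0 for unreachable
    pairs; E(G) is the mean over nodes.  Shortest paths by BFS.
    """
    n = a.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    g = nx.from_numpy_array(a)
    per_node = np.zeros(n)
    for i in range(n):
        dists = nx.single_source_shortest_path_length(g, i)
        per_node[i] = sum(1.0 / d for j, d in dists.items() if j != i) / (n - 1)
    return float(per_node.mean()), per_node


def global_efficiency(net: BrainNetwork) -> tuple[float, np.ndarray]:
    return _efficiency_from_adj(net.adjacency)


def local_efficiency(net: BrainNetwork) -> tuple[float, np.ndarray]:
    """E_loc(i): global efficiency of the subgraph induced by i's neighbours."""
    a = net.adjacency
    n = net.n_nodes
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        per_node[i] = _efficiency_from_adj(sub)[0]
    return float(per_node.mean()), per_node


def betweenness(net: BrainNetwork) -> np.ndarray:
    """Normalized betweenness centrality (Brandes), in node order."""
    bc = nx.betweenness_centrality(net.graph(), normalized=True)
    return np.array([bc[name] for name in net.channel_names])


def key_nodes(net: BrainNetwork, rule: str = "mean_sd",
              k: int | None = None) -> set[str]:
    """Key network nodes by normalized betweenness centrality.

    ``mean_sd`` (default): nodes whose betweenness exceeds mean + 1 SD.
    ``topk``: the ``k`` highest-betweenness nodes, ties included.
    """
    bc = betweenness(net)
    names = net.channel_names
    if rule == "mean_sd":
        cut = bc.mean() + bc.std()
        return {names[i] for i in np.flatnonzero(bc > cut)}
    if rule == "topk":
        if not k or k < 1:
            raise NetworkError("topk rule needs k >= 1")
        if k >= len(names):
            return set(names)
        cut = np.sort(bc)[::-1][k - 1]
        return {names[i] for i in np.flatnonzero(bc >= cut)}
    raise NetworkError(f"unknown key-node rule {rule!r}")


def _char_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over reachable pairs (0 if none)."""
    total, count = 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    return total / count if count else 0.0


def small_world_sigma(net: BrainNetwork, n_rand: int = 100,
                      seed: int = 0) -> float:
    """Small-world index sigma = (C/C_rand) / (L/L_rand).

    C is the mean clustering coefficient and L the characteristic path
    length over reachable pairs; C_rand, L_rand are averaged over
    ``n_rand`` degree-preserving rewired surrogates (10 x m attempted
    swaps each).  Graphs too dense to rewire (e.g. complete) keep their
    surrogates identical, giving sigma = 1 exactly.
    """
    g = nx.from_numpy_array(net.adjacency)
    n = net.n_nodes
    giant = max((len(c) for c in nx.connected_components(g)), default=0)
    if giant < n - 2:
        raise NetworkError(
            f"giant component has {giant} < {n - 2} nodes; "
            "sigma is not meaningful on fragmented graphs")
    m = g.number_of_edges()
    if m < 2:
        raise NetworkError("graph too sparse to rewire")
    c_obs = nx.average_clustering(g)
    l_obs = _char_path_length(g)

    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    for _ in range(n_rand):
        h = g.copy()
        try:
            nx.double_edge_swap(h, nswap=10 * m, max_tries=200 * m,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
        except nx.NetworkXException:
            pass  # no swap possible (e.g. complete graph): keep as-is
        c_rand.append(nx.average_clustering(h))
        l_rand.append(_char_path_length(h))
    c_r = float(np.mean(c_rand))
    l_r = float(np.mean(l_rand))
    if c_r == 0 or l_obs == 0:
        return float("inf") if c_obs > 0 else 1.0
    return float((c_obs / c_r) / (l_obs / l_r))


# ---------------------------------------------------------------------------
# threshold selection

@dataclass(frozen=True)
class ThresholdReport:
    """Selected threshold with the constraint values it achieved."""

    threshold: float
    mean_degree: float
    sigma: float
    min_mean_degree: float
    n_nodes: int

    def __float__(self) -> float:
        return self.threshold


def mean_degree(net: BrainNetwork) -> float:
    return float(degree(net).mean())


def select_threshold(conns: list[ConnectivityMatrix], grid_step: float = 0.02,
                     n_rand: int = 50, seed: int = 0,
                     grid_min: float | None = None) -> ThresholdReport:
    """Largest grid threshold meeting the degree and small-world constraints.

    The group-average connectivity matrix is binarized at each grid value
    t = grid_step, 2*grid_step, ... (descending search); the first t with
    mean degree >= ln(N) and sigma > 1 is returned together with the
    achieved constraint values.  If no grid value qualifies, a
    :class:`ThresholdInfeasibleError` lists the violation at every t.
    """
    if not conns:
        raise NetworkError("need at least one connectivity matrix")
    names = conns[0].channel_names
    if any(c.channel_names != names for c in conns):
        raise NetworkError("all matrices must share channel names")
    avg = np.mean([c.values for c in conns], axis=0)
    avg_conn = ConnectivityMatrix(avg, names, conns[0].band)

    n = len(names)
    min_deg = math.log(n)
    lo = grid_step if grid_min is None else grid_min
    grid = np.arange(lo, 1.0, grid_step)
    violations: list[str] = []
    for t in grid[::-1]:
        net = binarize(avg_conn, float(t))
        md = mean_degree(net)
        if md < min_deg:
            violations.append(
                f"t={t:.3f}: mean degree {md:.2f} < ln({n}) = {min_deg:.3f}")
            continue
        try:
            sig = small_world_sigma(net, n_rand=n_rand, seed=seed)
        except NetworkError as exc:
            violations.append(f"t={t:.3f}: {exc}")
            continue
        if sig <= 1.0:
            violations.append(f"t={t:.3f}: sigma {sig:.3f} <= 1")
            continue
        return ThresholdReport(float(t), md, sig, min_deg, n)
    raise ThresholdInfeasibleError(violations)


# ---------------------------------------------------------------------------
# group comparison

@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison of a metric between NM and MS groups."""

    u: float
    p: float
    stars: str
    n_nm: int
    n_ms: int


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(values_nm, values_ms) -> GroupComparison:
    """Two-sided Mann-Whitney U test (normal approximation, tie-corrected)."""
    a = np.asarray(values_nm, dtype=float)
    b = np.asarray(values_ms, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise NetworkError("each group needs at least 3 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    p = float(res.pvalue)
    return GroupComparison(float(res.statistic), p, significance_stars(p),
                           len(a), len(b))
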