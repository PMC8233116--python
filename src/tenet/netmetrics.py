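"""Micro- and macroscale scoring of inferred networks against ground truth.

Microscale: link classification over all ordered non-self node pairs
(precision, recall, specificity, false positive rate), with undirected
MI links expanded to two directed links first.

Macroscale: summary statistics computed identically on truth and
inferred networks — characteristic path length, global/local efficiency,
Fagiolo directed clustering, small-world coefficient sigma (normalized
by size- and link-matched Erdos-Renyi ensembles), discrete power-law
degree fit (Clauset-style MLE with KS xmin selection), betweenness
centrality, directed modularity of a given partition, and the rich-club
coefficient phi(k) on the undirected projection. All metrics operate on
binary non-self graphs; self-loops carry dynamics self-weights and are
excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, special

from .infer import InferredNetwork
from .netgen import StructuralNetwork

__all__ = [
    "ConfusionCounts",
    "confusion",
    "char_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering",
    "mean_clustering",
    "small_world_sigma",
    "powerlaw_fit",
    "betweenness",
    "modularity",
    "rich_club",
    "within_between_fp",
    "macro_summary",
]


def _nonself_bool(net) -> np.ndarray:
    if isinstance(net, StructuralNetwork):
        return net.nonself_adjacency()
    if isinstance(net, InferredNetwork):
        adj = net.directed_adjacency()
    else:
        adj = np.asarray(net, dtype=bool).copy()
    np.fill_diagonal(adj, False)
    return adj


def _digraph(net) -> nx.DiGraph:
    adj = _nonself_bool(net)
    g = nx.DiGraph()
    g.add_nodes_from(range(adj.shape[0]))
    g.add_edges_from(zip(*np.nonzero(adj)))
    return g


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")


def confusion(inferred, truth) -> ConfusionCounts:
    """Binary link classification over all ordered non-self pairs."""
    pred = _nonself_bool(inferred)
    real = _nonself_bool(truth)
    if pred.shape != real.shape:
        raise ValueError("inferred and truth networks differ in size")
    off = ~np.eye(pred.shape[0], dtype=bool)
    tp = int(np.sum(pred & real & off))
    fp = int(np.sum(pred & ~real & off))
    fn = int(np.sum(~pred & real & off))
    tn = int(np.sum(~pred & ~real & off))
    return ConfusionCounts(tp, fp, tn, fn)


def char_path_length(net) -> float:
    """Mean directed BFS distance over all ordered distinct pairs; raises
    on non-strongly-connected input (unreachable pairs would make the
    average undefined)."""
    g = _digraph(net)
    if not nx.is_strongly_connected(g):
        raise ValueError("characteristic path length needs strong connectivity")
    return nx.average_shortest_path_length(g)


def global_efficiency(net) -> float:
    """Mean inverse directed distance over ordered distinct pairs
    (unreachable pairs contribute 0); defined for any network."""
    g = _digraph(net)
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for tgt, d in dists.items():
            if tgt != src:
                total += 1.0 / d
    return total / (n * (n - 1))


def local_efficiency(net) -> float:
    """Mean over nodes of the global efficiency of the subgraph induced by
    each node's neighbourhood (successors and predecessors)."""
    adj = _nonself_bool(net)
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] | adj[:, i])
        if nbrs.size < 2:
            vals.append(0.0)
            continue
        vals.append(global_efficiency(adj[np.ix_(nbrs, nbrs)]))
    return float(np.mean(vals))


def clustering(net) -> np.ndarray:
    """Directed clustering coefficient per node (Fagiolo's formulation on
    the binary non-self adjacency); nodes with total degree < 2 get 0."""
    g = _digraph(net)
    vals = nx.clustering(g)
    return np.array([vals[i] for i in range(g.number_of_nodes())])


def mean_clustering(net) -> float:
    return float(np.mean(clustering(net)))


def small_world_sigma(
    net, n_random: int = 100, rng_seed: int = 0, max_draws_factor: int = 60
) -> float:
    """Small-world coefficient sigma = (C / C_rand) / (L / L_rand).

    C_rand and L_rand are averaged over up to ``n_random`` directed
    Erdos-Renyi realizations with the same node and non-self link counts;
    non-strongly-connected realizations are discarded (path length is
    undefined there). Raises if fewer than n_random / 2 connected
    realizations can be drawn.
    """
    adj = _nonself_bool(net)
    n = adj.shape[0]
    m = int(adj.sum())
    C = mean_clustering(adj)
    L = char_path_length(adj)
    rng = np.random.default_rng(rng_seed)
    c_vals, l_vals = [], []
    for _ in range(max_draws_factor * n_random):
        if len(c_vals) >= n_random:
            break
        g = nx.gnm_random_graph(
            n, m, seed=int(rng.integers(2**31 - 1)), directed=True
        )
        if not nx.is_strongly_connected(g):
            continue
        rand_adj = nx.to_numpy_array(g, dtype=bool)
        c_vals.append(mean_clustering(rand_adj))
        l_vals.append(char_path_length(rand_adj))
    if len(c_vals) < n_random / 2:
        raise RuntimeError(
            "too few strongly connected random realizations for normalization"
        )
    c_rand = float(np.mean(c_vals))
    l_rand = float(np.mean(l_vals))
    return (C / c_rand) / (L / l_rand)


# ---------------------------------------------------------------------------
# discrete power-law fit (MLE exponent, KS-minimizing xmin)


def _discrete_powerlaw_ll(beta: float, tail: np.ndarray, xmin: int) -> float:
    return -tail.size * np.log(special.zeta(beta, xmin)) - beta * np.sum(
        np.log(tail)
    )


def _fit_exponent(tail: np.ndarray, xmin: int) -> float:
    res = optimize.minimize_scalar(
        lambda b: -_discrete_powerlaw_ll(b, tail, xmin),
        bounds=(1.01, 8.0),
        method="bounded",
    )
    return float(res.x)


def powerlaw_fit(degrees: np.ndarray) -> tuple[float, int]:
    """Discrete maximum-likelihood power-law fit with KS xmin selection.

    For each candidate xmin, the exponent maximizes the zeta-function
    likelihood over the tail x >= xmin; the returned (beta, xmin) pair
    minimizes the Kolmogorov-Smirnov distance between the empirical and
    model tail CDFs. Requires >= 50 observations with >= 5 distinct
    values and x >= 1.
    """
    x = np.asarray(degrees)
    x = x[x >= 1].astype(int)
    if x.size < 50:
        raise ValueError("need at least 50 positive observations")
    uniq = np.unique(x)
    if uniq.size < 5:
        raise ValueError("degenerate (near-constant) degree sequence")
    best = None
    # keep enough tail mass for a stable fit
    for xmin in uniq[:-2]:
        tail = x[x >= xmin]
        if tail.size < 10:
            break
        beta = _fit_exponent(tail, int(xmin))
        support = np.arange(xmin, tail.max() + 1)
        pmf = support ** (-beta) / special.zeta(beta, xmin)
        cdf_model = np.cumsum(pmf)
        cdf_emp = np.searchsorted(np.sort(tail), support, side="right") / tail.size
        ks = float(np.max(np.abs(cdf_emp - cdf_model)))
        if best is None or ks < best[0]:
            best = (ks, beta, int(xmin))
    assert best is not None
    return best[1], best[2]


def betweenness(net) -> np.ndarray:
    """Directed shortest-path betweenness, endpoints excluded, normalized
    by (N-1)(N-2); equal-length shortest paths share credit fractionally."""
    g = _digraph(net)
    vals = nx.betweenness_centrality(g, normalized=True)
    return np.array([vals[i] for i in range(g.number_of_nodes())])


def modularity(net, partition: np.ndarray) -> float:
    """Directed Newman-Girvan modularity of a *given* partition:
    Q = sum_g [ m_gg / m - (k_g_out / m) (k_g_in / m) ] on the binary
    non-self graph. No community detection is performed."""
    adj = _nonself_bool(net)
    part = np.asarray(partition)
    if part.shape != (adj.shape[0],):
        raise ValueError("partition must cover all nodes")
    m = adj.sum()
    if m == 0:
        return 0.0
    q = 0.0
    for g in np.unique(part):
        members = part == g
        m_gg = adj[np.ix_(members, members)].sum()
        k_out = adj[members, :].sum()
        k_in = adj[:, members].sum()
        q += m_gg / m - (k_out / m) * (k_in / m)
    return float(q)


def rich_club(net) -> dict[int, float]:
    """Rich-club coefficient phi(k) = 2 E_>k / (N_>k (N_>k - 1)) on the
    undirected projection, using total degree; k with fewer than two
    qualifying nodes are omitted."""
    adj = _nonself_bool(net)
    und = adj | adj.T
    degree = und.sum(axis=1)
    out: dict[int, float] = {}
    for k in range(int(degree.max())):
        rich = np.flatnonzero(degree > k)
        if rich.size < 2:
            continue
        e = und[np.ix_(rich, rich)].sum() // 2
        out[k] = 2.0 * e / (rich.size * (rich.size - 1))
    return out


def within_between_fp(
    inferred, truth, partition: np.ndarray
) -> dict[str, float]:
    """False positives split by whether source and target share a group.

    Counts are normalized per node; rates are normalized by the number of
    absent ordered pairs available in each class.
    """
    if partition is None:
        raise ValueError("partition required")
    pred = _nonself_bool(inferred)
    real = _nonself_bool(truth)
    part = np.asarray(partition)
    n = pred.shape[0]
    off = ~np.eye(n, dtype=bool)
    same = (part[:, None] == part[None, :]) & off
    fp = pred & ~real & off
    absent_within = int(np.sum(~real & same))
    absent_between = int(np.sum(~real & ~same & off))
    fp_within = int(np.sum(fp & same))
    fp_between = int(np.sum(fp & ~same))
    return {
        "fp_within_per_node": fp_within / n,
        "fp_between_per_node": fp_between / n,
        "fpr_within": fp_within / absent_within if absent_within else float("nan"),
        "fpr_between": fp_between / absent_between if absent_between else float("nan"),
    }


def macro_summary(
    net,
    partition: np.ndarray | None = None,
    sigma_n_random: int = 0,
    rng_seed: int = 0,
) -> dict[str, float]:
    """Bundle of macroscale statistics computed identically on truth and
    inferred networks. Path length and sigma are NaN when the network is
    not strongly connected; sigma is computed only when sigma_n_random > 0."""
    out: dict[str, float] = {}
    try:
        out["char_path_length"] = char_path_length(net)
    except ValueError:
        out["char_path_length"] = float("nan")
    out["mean_clustering"] = mean_clustering(net)
    out["global_efficiency"] = global_efficiency(net)
    if sigma_n_random > 0:
        try:
            out["small_world_sigma"] = small_world_sigma(
                net, n_random=sigma_n_random, rng_seed=rng_seed
            )
        except (ValueError, RuntimeError):
            out["small_world_sigma"] = float("nan")
    if partition is not None:
        out["modularity_q"] = modularity(net, partition)
    adj = _nonself_bool(net)
    out["n_links"] = float(adj.sum())
    out["density"] = float(adj.sum() / adj.shape[0] ** 2)
    return out
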