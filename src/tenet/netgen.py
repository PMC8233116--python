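"""Ground-truth network generators and text-format I/O.

Three directed topologies are provided, each with a self-loop on every
node (the self-loop carries the self-coupling weight of the dynamics and
is excluded from all degree, density and path computations):

* a Watts-Strogatz-style directed ring lattice with fixed in-degree,
  rewired by changing link *sources*;
* linear preferential attachment with bidirectional links (scale-free);
* a five-group-style modular network with a controlled number of
  between-group links per node.

Networks and coupling matrices round-trip through delimited adjacency
matrices and three-column edge lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csgraph, csr_matrix

__all__ = [
    "StructuralNetwork",
    "WeightedCoupling",
    "make_ws_ring",
    "make_preferential_attachment",
    "make_modular",
    "assign_weights",
    "read_network",
    "write_network",
    "read_partition",
    "write_partition",
]


@dataclass
class StructuralNetwork:
    """Directed boolean adjacency with self-loops and an optional partition.

    ``adjacency[i, j]`` is True iff the directed link i -> j exists. The
    diagonal holds self-loops. ``partition`` maps each node to a group
    label (used by the modular generator and the modularity metrics).
    """

    adjacency: np.ndarray
    partition: np.ndarray | None = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        self.adjacency = adj
        if self.partition is not None:
            part = np.asarray(self.partition)
            if part.shape != (adj.shape[0],):
                raise ValueError("partition must label every node exactly once")
            self.partition = part

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def self_loops(self) -> np.ndarray:
        return np.diag(self.adjacency).copy()

    def nonself_adjacency(self) -> np.ndarray:
        """Adjacency with the diagonal (self-loops) removed."""
        out = self.adjacency.copy()
        np.fill_diagonal(out, False)
        return out

    def in_degrees(self) -> np.ndarray:
        """Non-self in-degree of every node."""
        return self.nonself_adjacency().sum(axis=0)

    def out_degrees(self) -> np.ndarray:
        """Non-self out-degree of every node."""
        return self.nonself_adjacency().sum(axis=1)

    def n_links(self) -> int:
        """Number of directed non-self links."""
        return int(self.nonself_adjacency().sum())

    def density(self) -> float:
        """Directed non-self links divided by n^2."""
        return self.n_links() / self.n_nodes**2


@dataclass
class WeightedCoupling:
    """Real coupling matrix driving the simulators.

    ``weights[i, j]`` is the weight of i -> j (0 where no link), including
    diagonal self-weights. ``delays`` (optional) holds nonnegative integer
    delays in integration steps; ``noise_std`` is the innovation standard
    deviation theta of the VAR dynamics.
    """

    weights: np.ndarray
    delays: np.ndarray | None = None
    noise_std: float = 0.1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        self.weights = w
        if self.delays is not None:
            d = np.asarray(self.delays)
            if d.shape != w.shape:
                raise ValueError("delays must match weights in shape")
            if np.any(d < 0) or not np.issubdtype(d.dtype, np.integer):
                d = d.astype(int)
                if np.any(d < 0):
                    raise ValueError("delays must be nonnegative integers")
            self.delays = d
        if not self.noise_std > 0:
            raise ValueError("noise_std must be positive")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.weights))))

    def structure(self) -> StructuralNetwork:
        return StructuralNetwork(self.weights != 0)


def _is_strongly_connected(adj_nonself: np.ndarray) -> bool:
    n_comp = csgraph.connected_components(
        csr_matrix(adj_nonself), directed=True, connection="strong",
        return_labels=False,
    )
    return n_comp == 1


def make_ws_ring(
    n_nodes: int,
    neighbors_per_side: int,
    rewire_prob: float,
    rng_seed: int,
    retry_budget: int = 100,
) -> StructuralNetwork:
    """Directed ring lattice with source-rewired links (small-world family).

    Every node starts with incoming links from ``neighbors_per_side``
    neighbours on each side (fixed non-self in-degree 2k) plus a
    self-loop. Each non-self link's *source* is then rewired with
    probability ``rewire_prob`` to a uniformly drawn node that is not the
    target and does not already link to it; a rewiring is accepted only if
    the non-self graph stays strongly connected (directed shortest paths
    must remain defined). In-degrees are preserved exactly for every
    rewiring probability.
    """
    k = neighbors_per_side
    if k < 1 or n_nodes <= 2 * k:
        raise ValueError("need n_nodes > 2 * neighbors_per_side and k >= 1")
    if not 0.0 <= rewire_prob <= 1.0:
        raise ValueError("rewire_prob must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    np.fill_diagonal(adj, True)
    for j in range(n_nodes):
        for off in range(1, k + 1):
            adj[(j - off) % n_nodes, j] = True
            adj[(j + off) % n_nodes, j] = True
    if rewire_prob == 0.0:
        return StructuralNetwork(adj)
    # Fixed iteration order over the initial links; only sources change.
    links = [
        (j, off_src % n_nodes)
        for j in range(n_nodes)
        for off_src in [*range(j - k, j), *range(j + 1, j + k + 1)]
    ]
    for target, source in links:
        if rng.random() >= rewire_prob:
            continue
        rewired = False
        for _ in range(retry_budget):
            new_source = int(rng.integers(n_nodes))
            if new_source == target or adj[new_source, target]:
                continue
            adj[source, target] = False
            adj[new_source, target] = True
            nonself = adj.copy()
            np.fill_diagonal(nonself, False)
            if _is_strongly_connected(nonself):
                rewired = True
                break
            adj[new_source, target] = False
            adj[source, target] = True
        if not rewired and retry_budget <= 0:
            raise RuntimeError("rewiring retry budget must be positive")
    nonself = adj.copy()
    np.fill_diagonal(nonself, False)
    if not _is_strongly_connected(nonself):
        raise RuntimeError("could not keep the rewired network connected")
    return StructuralNetwork(adj)


def make_preferential_attachment(
    n_nodes: int, links_per_new_node: int, rng_seed: int
) -> StructuralNetwork:
    """Scale-free network by linear preferential attachment.

    Starts from two reciprocally connected nodes; each new node is linked
    bidirectionally to ``links_per_new_node`` distinct existing nodes
    chosen with probability proportional to their current total degree
    (sampled without replacement per new node). Self-loops are added on
    every node for the dynamics' self-weights but do not enter the degree
    accounting.
    """
    m = links_per_new_node
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if m < 1:
        raise ValueError("links_per_new_node must be >= 1")
    rng = np.random.default_rng(rng_seed)
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    np.fill_diagonal(adj, True)
    adj[0, 1] = adj[1, 0] = True
    # repeated-node list: each node appears once per unit of total degree
    degree_pool: list[int] = [0, 0, 1, 1]
    for new in range(2, n_nodes):
        if m > new:
            raise ValueError(
                "links_per_new_node must be smaller than the current node count"
            )
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(degree_pool[rng.integers(len(degree_pool))])
        for t in targets:
            adj[new, t] = adj[t, new] = True
            degree_pool.extend([new, new, t, t])
    return StructuralNetwork(adj)


def make_modular(
    n_nodes: int,
    n_groups: int,
    out_degree: int,
    links_between_per_node: int,
    rng_seed: int,
) -> StructuralNetwork:
    """Modular network with a controlled number of between-group links.

    Nodes are equally partitioned into ``n_groups`` groups. Each node is
    first linked to ``out_degree`` random targets inside its own group;
    then ``links_between_per_node`` of its out-links are redirected to
    uniformly chosen nodes of uniformly chosen *other* groups, preserving
    the out-degree and the overall density exactly. Self-loops are added
    on every node.
    """
    if n_nodes % n_groups != 0:
        raise ValueError("n_nodes must be divisible by n_groups")
    group_size = n_nodes // n_groups
    if not 0 <= links_between_per_node <= out_degree:
        raise ValueError("links_between_per_node must lie in [0, out_degree]")
    if out_degree >= group_size:
        raise ValueError("out_degree must be smaller than the group size")
    if n_groups < 2 and links_between_per_node > 0:
        raise ValueError("between-group links require at least two groups")
    rng = np.random.default_rng(rng_seed)
    partition = np.repeat(np.arange(n_groups), group_size)
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    np.fill_diagonal(adj, True)
    for node in range(n_nodes):
        g = partition[node]
        members = np.flatnonzero(partition == g)
        candidates = members[members != node]
        targets = rng.choice(candidates, size=out_degree, replace=False)
        # redirect a subset of the out-links to other groups
        to_move = rng.choice(out_degree, size=links_between_per_node, replace=False)
        keep = np.delete(targets, to_move)
        adj[node, keep] = True
        n_placed = 0
        attempts = 0
        while n_placed < links_between_per_node:
            attempts += 1
            if attempts > 10000:
                raise RuntimeError("could not place between-group links")
            other = int(rng.integers(n_groups - 1))
            other = other if other < g else other + 1
            tgt = int(rng.integers(group_size)) + other * group_size
            if adj[node, tgt]:
                continue
            adj[node, tgt] = True
            n_placed += 1
    return StructuralNetwork(adj, partition=partition)


def assign_weights(
    net: StructuralNetwork,
    cross_weight: float | None = None,
    incoming_total: float | None = None,
    self_weight: float = 0.0,
    theta: float = 0.1,
) -> WeightedCoupling:
    """Attach coupling weights to a structural network.

    Either ``cross_weight`` sets one uniform weight on every non-self link,
    or ``incoming_total`` (the sum of incoming non-self weights per target,
    C_in) is split equally among each target's parents. Diagonal entries
    get ``self_weight``. Raises if the resulting coupling matrix has
    spectral radius >= 1, which would make the VAR dynamics nonstationary.
    """
    if (cross_weight is None) == (incoming_total is None):
        raise ValueError("supply exactly one of cross_weight / incoming_total")
    nonself = net.nonself_adjacency()
    weights = np.zeros((net.n_nodes, net.n_nodes), dtype=float)
    if cross_weight is not None:
        weights[nonself] = cross_weight
    else:
        n_parents = nonself.sum(axis=0)
        for j in range(net.n_nodes):
            if n_parents[j] > 0:
                weights[nonself[:, j], j] = incoming_total / n_parents[j]
    weights[np.diag_indices_from(weights)] = np.where(
        net.self_loops, self_weight, 0.0
    )
    coupling = WeightedCoupling(weights, noise_std=theta)
    rho = coupling.spectral_radius()
    if rho >= 1.0:
        raise ValueError(
            f"coupling spectral radius {rho:.3f} >= 1: VAR would be nonstationary"
        )
    return coupling


# ---------------------------------------------------------------------------
# text I/O


def write_network(
    net: StructuralNetwork | WeightedCoupling,
    path: str | Path,
    format: str = "matrix",
    delimiter: str = "\t",
) -> None:
    """Write a network as a delimited adjacency matrix or 3-column edge list.

    Matrix format: square numeric table, row = source, column = target,
    entry = weight (0 = absent). Edge list: ``source<TAB>target<TAB>weight``
    with 0-based integer ids. Boolean adjacencies are written with weight 1.
    """
    path = Path(path)
    if isinstance(net, WeightedCoupling):
        mat = net.weights
    else:
        mat = net.adjacency.astype(float)
    if format == "matrix":
        np.savetxt(path, mat, delimiter=delimiter, fmt="%.12g")
    elif format == "edgelist":
        src, tgt = np.nonzero(mat)
        with path.open("w") as fh:
            for i, j in zip(src, tgt):
                fh.write(f"{i}\t{j}\t{mat[i, j]:.12g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(
    path: str | Path,
    format: str = "matrix",
    weighted: bool = False,
    delimiter: str | None = None,
) -> StructuralNetwork | WeightedCoupling:
    """Read a network written by :func:`write_network`.

    Returns a :class:`WeightedCoupling` when ``weighted`` is True, else a
    :class:`StructuralNetwork` (any nonzero entry is a link).
    """
    path = Path(path)
    if format == "matrix":
        try:
            mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-numeric entries in {path}") from exc
        if mat.shape[0] != mat.shape[1]:
            raise ValueError(
                f"adjacency matrix in {path} is not square: {mat.shape}"
            )
    elif format == "edgelist":
        rows = np.loadtxt(path, ndmin=2)
        if rows.size == 0:
            raise ValueError(f"empty edge list in {path}")
        if rows.shape[1] != 3:
            raise ValueError("edge list must have columns source, target, weight")
        src = rows[:, 0].astype(int)
        tgt = rows[:, 1].astype(int)
        if np.any(rows[:, :2] < 0):
            raise ValueError("node ids must be nonnegative")
        n = int(max(src.max(), tgt.max())) + 1
        seen = set()
        mat = np.zeros((n, n))
        for i, j, w in zip(src, tgt, rows[:, 2]):
            if (i, j) in seen:
                raise ValueError(f"duplicate edge {i}->{j} in {path}")
            seen.add((i, j))
            mat[i, j] = w
        if mat.shape[0] != mat.shape[1]:  # pragma: no cover - square by build
            raise ValueError("edge list produced a non-square matrix")
    else:
        raise ValueError(f"unknown format {format!r}")
    if weighted:
        return WeightedCoupling(mat)
    return StructuralNetwork(mat != 0)


def write_partition(partition: np.ndarray, path: str | Path) -> None:
    """Write ``node<TAB>group`` lines."""
    with Path(path).open("w") as fh:
        for node, group in enumerate(partition):
            fh.write(f"{node}\t{group}\n")


def read_partition(path: str | Path) -> np.ndarray:
    rows = np.loadtxt(path, dtype=int, ndmin=2)
    part = np.full(rows[:, 0].max() + 1, -1, dtype=int)
    part[rows[:, 0]] = rows[:, 1]
    if np.any(part < 0):
        raise ValueError("partition file does not cover all nodes")
    return part
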