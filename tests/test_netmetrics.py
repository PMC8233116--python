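"""Graph metrics against exhaustive brute-force oracles on small digraphs,
plus the closed-form examples."""

import numpy as np
import pytest

from tenet import netgen, netmetrics
from tenet.netmetrics import (
    betweenness,
    char_path_length,
    clustering,
    confusion,
    global_efficiency,
    local_efficiency,
    mean_clustering,
    modularity,
    powerlaw_fit,
    rich_club,
    small_world_sigma,
    within_between_fp,
)

# ---------------------------------------------------------------------------
# brute-force oracles (independent of networkx)


def bf_distances(adj):
    """All-pairs BFS distances on a boolean digraph; inf if unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def bf_char_path_length(adj):
    n = adj.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = bf_distances(adj)[off]
    assert np.all(np.isfinite(d))
    return d.mean()


def bf_betweenness(adj):
    """Enumerate every simple path, keep the shortest per ordered pair,
    and share credit among equal-length shortest paths."""
    n = adj.shape[0]
    paths = {}  # (s, t) -> list of shortest paths

    def dfs(path):
        u = path[-1]
        for v in np.flatnonzero(adj[u]):
            if v in path:
                continue
            key = (path[0], v)
            new = path + [v]
            cur = paths.get(key)
            if cur is None or len(new) < len(cur[0]):
                paths[key] = [new]
            elif len(new) == len(cur[0]):
                cur.append(new)
            dfs(new)

    for s in range(n):
        dfs([s])
    bc = np.zeros(n)
    for (s, t), plist in paths.items():
        if s == t:
            continue
        for p in plist:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(plist)
    return bc / ((n - 1) * (n - 2))


def bf_clustering(adj):
    """Directed clustering by explicit triangle counting over node pairs
    (all link orientations count, reciprocal links counted twice)."""
    n = adj.shape[0]
    a = adj.astype(int)
    out = np.zeros(n)
    for i in range(n):
        tri = 0
        for j in range(n):
            for h in range(n):
                if i in (j, h):
                    continue
                tri += (a[i, j] + a[j, i]) * (a[j, h] + a[h, j]) * (a[h, i] + a[i, h])
        d_tot = a[i].sum() + a[:, i].sum()
        d_bi = int(np.sum(a[i] & a[:, i]))
        denom = 2 * (d_tot * (d_tot - 1) - 2 * d_bi)
        out[i] = tri / denom if denom > 0 else 0.0
    return out


def _random_strong_digraphs():
    """Fixed fixture set: strongly connected digraphs with <= 7 nodes."""
    rng = np.random.default_rng(42)
    graphs = []
    # deterministic shapes
    cyc = np.zeros((5, 5), dtype=bool)
    for i in range(5):
        cyc[i, (i + 1) % 5] = True
    graphs.append(cyc)
    graphs.append(~np.eye(4, dtype=bool))  # complete digraph
    star = np.zeros((6, 6), dtype=bool)
    star[0, 1:] = True
    star[1:, 0] = True
    graphs.append(star)
    # random ones
    while len(graphs) < 15:
        n = int(rng.integers(3, 8))
        adj = rng.random((n, n)) < 0.45
        np.fill_diagonal(adj, False)
        if np.all(np.isfinite(bf_distances(adj))):
            graphs.append(adj)
    return graphs


FIXTURE_GRAPHS = _random_strong_digraphs()


@pytest.mark.parametrize("adj", FIXTURE_GRAPHS)
def test_path_betweenness_clustering_match_bruteforce(adj):
    """Path length, betweenness and directed clustering agree with
    exhaustive enumeration on every fixture digraph."""
    assert char_path_length(adj) == pytest.approx(bf_char_path_length(adj))
    assert betweenness(adj) == pytest.approx(bf_betweenness(adj), abs=1e-12)
    assert clustering(adj) == pytest.approx(bf_clustering(adj), abs=1e-12)


@pytest.mark.parametrize("adj", FIXTURE_GRAPHS[:6])
def test_rich_club_matches_bruteforce_edge_counting(adj):
    und = adj | adj.T
    np.fill_diagonal(und, False)
    deg = und.sum(axis=1)
    phi = rich_club(adj)
    for k, val in phi.items():
        rich = np.flatnonzero(deg > k)
        e = sum(
            und[i, j] for a, i in enumerate(rich) for j in rich[a + 1 :]
        )
        assert val == pytest.approx(2 * e / (rich.size * (rich.size - 1)))


def test_path_length_examples():
    complete = ~np.eye(5, dtype=bool)
    assert char_path_length(complete) == 1.0
    cycle4 = np.zeros((4, 4), dtype=bool)
    for i in range(4):
        cycle4[i, (i + 1) % 4] = True
    assert char_path_length(cycle4) == pytest.approx(2.0)
    disconnected = np.zeros((3, 3), dtype=bool)
    disconnected[0, 1] = True
    with pytest.raises(ValueError):
        char_path_length(disconnected)


def test_ws_lattice_path_length_matches_bfs_oracle(ws_lattice_100):
    adj = ws_lattice_100.nonself_adjacency()
    assert char_path_length(adj) == pytest.approx(bf_char_path_length(adj))


def test_efficiency_examples():
    complete = ~np.eye(4, dtype=bool)
    assert global_efficiency(complete) == 1.0
    assert local_efficiency(complete) == 1.0
    cycle4 = np.zeros((4, 4), dtype=bool)
    for i in range(4):
        cycle4[i, (i + 1) % 4] = True
    assert global_efficiency(cycle4) == pytest.approx((1 + 0.5 + 1 / 3) / 3)


def test_clustering_examples():
    assert np.all(clustering(~np.eye(5, dtype=bool)) == 1.0)
    hub_star = np.zeros((5, 5), dtype=bool)
    hub_star[0, 1:] = True
    assert np.all(clustering(hub_star) == 0.0)
    tri = np.zeros((3, 3), dtype=bool)
    tri[0, 1] = tri[1, 2] = tri[0, 2] = True
    assert clustering(tri) == pytest.approx(bf_clustering(tri))


def test_betweenness_examples():
    star = np.zeros((5, 5), dtype=bool)
    star[0, 1:] = True
    star[1:, 0] = True
    bc = betweenness(star)
    assert bc[0] == pytest.approx(1.0)
    assert np.all(bc[1:] == 0.0)
    path = np.zeros((4, 4), dtype=bool)
    path[0, 1] = path[1, 2] = path[2, 3] = True
    assert betweenness(path)[1] == pytest.approx(2 / 6)
    assert np.all(betweenness(~np.eye(6, dtype=bool)) == 0.0)


def test_modularity_closed_forms():
    net = netgen.make_modular(100, 5, 10, 0, rng_seed=0)
    assert modularity(net, net.partition) == pytest.approx(0.8)
    # rewiring b links per node: Q ~ (10 - b)/10 - 0.2, linear in b
    for b in (2, 4, 8):
        m = netgen.make_modular(100, 5, 10, b, rng_seed=b)
        assert modularity(m, m.partition) == pytest.approx(
            (10 - b) / 10 - 0.2, abs=0.03
        )


def test_modularity_of_random_partition_near_zero():
    import networkx as nx

    rng = np.random.default_rng(1)
    g = nx.gnm_random_graph(60, 400, seed=3, directed=True)
    adj = nx.to_numpy_array(g, dtype=bool)
    qs = [
        modularity(adj, rng.permutation(np.repeat(np.arange(4), 15)))
        for _ in range(10)
    ]
    assert abs(np.mean(qs)) < 0.02


def test_true_partition_beats_random_partitions():
    net = netgen.make_modular(100, 5, 10, 0, rng_seed=2)
    q_true = modularity(net, net.partition)
    rng = np.random.default_rng(3)
    for _ in range(10):
        assert q_true > modularity(net, rng.permutation(net.partition))


def test_rich_club_examples():
    complete = ~np.eye(6, dtype=bool)
    assert all(v == 1.0 for v in rich_club(complete).values())
    star = np.zeros((6, 6), dtype=bool)
    star[0, 1:] = True
    star[1:, 0] = True
    phi = rich_club(star)
    assert set(phi) == {0}  # only k=0 has >= 2 qualifying nodes


def test_small_world_sigma_er_baseline_and_lattice():
    import networkx as nx

    g = nx.gnm_random_graph(30, 180, seed=5, directed=True)
    assert nx.is_strongly_connected(g)
    adj = nx.to_numpy_array(g, dtype=bool)
    sigma = small_world_sigma(adj, n_random=30, rng_seed=0)
    assert 0.75 <= sigma <= 1.3
    ws = netgen.make_ws_ring(100, 2, 0.1, rng_seed=6)
    assert small_world_sigma(ws.nonself_adjacency(), n_random=20, rng_seed=1) > 1.3


def test_powerlaw_fit_recovers_synthetic_exponent():
    rng = np.random.default_rng(7)
    u = rng.random(100000)
    draws = np.floor((4 - 0.5) * (1 - u) ** (-1 / 2.0) + 0.5).astype(int)
    beta, xmin = powerlaw_fit(draws)
    assert 2.9 <= beta <= 3.1
    with pytest.raises(ValueError):
        powerlaw_fit(np.full(200, 5))
    with pytest.raises(ValueError):
        powerlaw_fit(np.arange(10))


def test_confusion_counts_and_derived_rates():
    truth = np.zeros((4, 4), dtype=bool)
    truth[0, 1] = truth[1, 2] = truth[2, 3] = True
    inferred = np.zeros((4, 4), dtype=bool)
    inferred[0, 1] = inferred[1, 2] = inferred[0, 2] = inferred[3, 0] = True
    cm = confusion(inferred, truth)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 2, 1, 7)
    assert cm.precision == 0.5
    assert cm.recall == pytest.approx(2 / 3)
    assert cm.specificity == pytest.approx(7 / 9)
    assert cm.specificity + cm.fpr == pytest.approx(1.0)

    perfect = confusion(truth, truth)
    assert perfect.precision == perfect.recall == perfect.specificity == 1.0
    empty = confusion(np.zeros((4, 4), dtype=bool), truth)
    assert empty.recall == 0.0 and empty.specificity == 1.0
    assert np.isnan(empty.precision)
    assert cm.tp + cm.fp + cm.tn + cm.fn == 12  # ordered non-self pairs


def test_confusion_size_mismatch():
    with pytest.raises(ValueError):
        confusion(np.zeros((3, 3), dtype=bool), np.zeros((4, 4), dtype=bool))


def test_within_between_false_positives():
    net = netgen.make_modular(100, 5, 10, 0, rng_seed=8)
    same = within_between_fp(net.adjacency, net, net.partition)
    assert same["fp_within_per_node"] == 0 and same["fp_between_per_node"] == 0
    # one spurious cross-group link
    inferred = net.adjacency.copy()
    assert net.partition[0] != net.partition[99]
    inferred[0, 99] = True
    one = within_between_fp(inferred, net, net.partition)
    assert one["fp_between_per_node"] == pytest.approx(0.01)
    assert one["fp_within_per_node"] == 0.0


def test_uniform_random_errors_have_equal_within_between_rates():
    net = netgen.make_modular(100, 5, 10, 4, rng_seed=9)
    rng = np.random.default_rng(10)
    ratios = []
    for _ in range(5):
        guess = rng.random((100, 100)) < 0.3
        r = within_between_fp(guess, net, net.partition)
        ratios.append(r["fpr_within"] / r["fpr_between"])
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)
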