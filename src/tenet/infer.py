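"""Network inference algorithms: bivariate MI, bivariate TE, and greedy
multivariate TE.

Bivariate methods test every pair of nodes independently against an
analytic chi-square null with a Bonferroni-style critical level
alpha / N (so that per target the chance of at least one spurious parent
is ~alpha under independent sources). The multivariate algorithm instead
models each target's dynamic update: it first builds a nonuniform
embedding of the target's own past, then greedily selects the minimal
set of lagged sources that maximizes the collective transfer entropy,
conditioning every new candidate on the sources already selected. The
per-target family-wise error rate is controlled at alpha via the
max-statistic surrogate test, and an optional backward pass prunes
sources made redundant by later selections.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .dynamics import TimeSeriesSet
from .gaussian_info import (
    LagVariable,
    _orthonormal_basis,
    chi_square_test,
    gaussian_mi,
    lagged_design,
    max_statistic_test,
    partial_corr_stat,
)

__all__ = [
    "InferenceConfig",
    "InferredNetwork",
    "ParentSet",
    "infer_bivariate_mi",
    "infer_bivariate_te",
    "infer_multivariate_te",
    "embed_target_past",
]


def derive_seed(*parts) -> int:
    """Deterministic sub-stream seed from a tuple of labels (< 2^31)."""
    digest = hashlib.blake2b(
        ":".join(str(p) for p in parts).encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass
class InferenceConfig:
    algorithm: str = "multi_te"  # biv_mi | biv_te | multi_te
    alpha: float = 0.01
    max_lag_L: int = 1
    n_surrogates: int = 500
    seed: int = 0
    prune: bool = True
    min_shift: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_lag_L < 1:
            raise ValueError("max_lag_L must be >= 1")
        if self.algorithm not in {"biv_mi", "biv_te", "multi_te"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class InferredNetwork:
    """Directed (or symmetrized) boolean adjacency with per-link statistic
    (nats) and p-value; the diagonal is always False (self-dynamics are
    handled by the target-past embedding, never reported as links)."""

    adjacency: np.ndarray
    symmetric: bool
    statistics: np.ndarray
    p_values: np.ndarray
    config: InferenceConfig

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def directed_adjacency(self) -> np.ndarray:
        """Adjacency for directed evaluation: undirected (MI) links count
        as two directed links in opposite directions."""
        return self.adjacency.copy()


@dataclass
class ParentSet:
    """The selected model of one target: its own-past embedding, its
    lagged sources, and the final collective TE statistic."""

    target: int
    target_past: list[LagVariable] = field(default_factory=list)
    sources: list[LagVariable] = field(default_factory=list)
    collective_te: float = 0.0


def _greedy_candidate_order(stats: dict[LagVariable, float]) -> LagVariable:
    """Winner = max statistic; ties (to 1e-12) broken by smaller lag, then
    smaller node index."""
    best = max(stats.values())
    tied = [v for v, s in stats.items() if best - s <= 1e-12]
    return min(tied, key=lambda v: (v.lag, v.node))


def _greedy_select(
    ts: TimeSeriesSet,
    target: int,
    candidates: list[LagVariable],
    base_conditioning: list[LagVariable],
    cfg: InferenceConfig,
    stage: str,
) -> list[LagVariable]:
    """Iterative greedy selection with the max-statistic stopping rule.

    Picks the candidate with the highest CMI with the target's present
    given ``base_conditioning`` plus previously selected candidates,
    accepts it if it passes the max-statistic surrogate test at
    cfg.alpha, and stops at the first rejection.
    """
    L = cfg.max_lag_L
    y = lagged_design(ts, [LagVariable(target, 0)], align_lag=L)[:, 0]
    selected: list[LagVariable] = []
    remaining = list(candidates)
    designs = {
        v: lagged_design(ts, [v], align_lag=L)[:, 0] for v in candidates
    }
    step = 0
    while remaining:
        Z = lagged_design(ts, base_conditioning + selected, align_lag=L)
        Q = _orthonormal_basis(Z)
        y_resid = y - Q @ (Q.T @ y)
        stats = {
            v: partial_corr_stat(designs[v], y_resid, Q) for v in remaining
        }
        winner = _greedy_candidate_order(stats)
        result = max_statistic_test(
            ts,
            candidates=remaining,
            winner=winner,
            conditioning=base_conditioning + selected,
            target=target,
            n_surrogates=cfg.n_surrogates,
            alpha=cfg.alpha,
            rng_seed=derive_seed(cfg.seed, stage, target, step),
            align_lag=L,
            min_shift=cfg.min_shift,
        )
        if not result.significant:
            break
        selected.append(winner)
        remaining.remove(winner)
        step += 1
    return selected


def embed_target_past(
    ts: TimeSeriesSet, target: int, cfg: InferenceConfig
) -> list[LagVariable]:
    """Nonuniform embedding of the target's own past: greedy selection of
    statistically significant lags 1..L of the target itself."""
    if cfg.max_lag_L >= ts.n_samples:
        raise ValueError("max_lag_L must be smaller than the series length")
    candidates = [LagVariable(target, lag) for lag in range(1, cfg.max_lag_L + 1)]
    return _greedy_select(ts, target, candidates, [], cfg, stage="embed")


def _prune_sources(
    ts: TimeSeriesSet,
    target: int,
    embedding: list[LagVariable],
    sources: list[LagVariable],
    cfg: InferenceConfig,
) -> list[LagVariable]:
    """Backward pass: drop any selected source whose CMI given all other
    selected variables fails a (single-candidate) surrogate test."""
    kept = list(sources)
    for v in sorted(sources, key=lambda v: (v.lag, v.node)):
        others = [u for u in kept if u != v]
        result = max_statistic_test(
            ts,
            candidates=[v],
            winner=v,
            conditioning=embedding + others,
            target=target,
            n_surrogates=cfg.n_surrogates,
            alpha=cfg.alpha,
            rng_seed=derive_seed(cfg.seed, "prune", target, v.node, v.lag),
            align_lag=cfg.max_lag_L,
            min_shift=cfg.min_shift,
        )
        if not result.significant:
            kept.remove(v)
    return kept


def infer_bivariate_mi(ts: TimeSeriesSet, cfg: InferenceConfig) -> InferredNetwork:
    """Functional network from pairwise zero-lag Gaussian MI.

    Every unordered pair is tested with the chi-square null at
    alpha / N; significant pairs become symmetric (undirected) links,
    represented as two directed links for downstream evaluation.
    """
    if cfg.algorithm != "biv_mi":
        raise ValueError("config algorithm must be 'biv_mi'")
    n = ts.n_nodes
    alpha_link = cfg.alpha / n
    adj = np.zeros((n, n), dtype=bool)
    stats_m = np.zeros((n, n))
    pvals = np.ones((n, n))
    degenerate = np.std(ts.samples, axis=0) == 0
    for i in range(n):
        for j in range(i + 1, n):
            if degenerate[i] or degenerate[j]:
                continue
            mi = gaussian_mi(ts.samples[:, i], ts.samples[:, j])
            res = chi_square_test(mi, ts.n_samples, dof=1, alpha=alpha_link)
            stats_m[i, j] = stats_m[j, i] = mi
            pvals[i, j] = pvals[j, i] = res.p_value
            if res.significant:
                adj[i, j] = adj[j, i] = True
    return InferredNetwork(adj, True, stats_m, pvals, cfg)


def infer_bivariate_te(ts: TimeSeriesSet, cfg: InferenceConfig) -> InferredNetwork:
    """Directed functional network from pairwise transfer entropy.

    Per target, the target-past embedding is built once; each source is
    then tested independently (conditioned on that embedding only)
    against the chi-square null at alpha / N. With L = 1 the source
    variable is its lag-1 sample; with L > 1 the source's lags are
    selected greedily (restricted to that source) before the final test.
    """
    if cfg.algorithm != "biv_te":
        raise ValueError("config algorithm must be 'biv_te'")
    n = ts.n_nodes
    L = cfg.max_lag_L
    alpha_link = cfg.alpha / n
    n_rows = ts.n_samples - L
    adj = np.zeros((n, n), dtype=bool)
    stats_m = np.zeros((n, n))
    pvals = np.ones((n, n))
    for target in range(n):
        embedding = embed_target_past(ts, target, cfg)
        y = lagged_design(ts, [LagVariable(target, 0)], align_lag=L)[:, 0]
        for source in range(n):
            if source == target:
                continue
            if L == 1:
                source_vars = [LagVariable(source, 1)]
            else:
                source_vars = _greedy_select(
                    ts,
                    target,
                    [LagVariable(source, lag) for lag in range(1, L + 1)],
                    embedding,
                    cfg,
                    stage=f"bivte-src{source}",
                )
                if not source_vars:
                    continue
            Z = lagged_design(ts, embedding, align_lag=L)
            X = lagged_design(ts, source_vars, align_lag=L)
            if len(source_vars) == 1:
                Q = _orthonormal_basis(Z)
                te = partial_corr_stat(X[:, 0], y - Q @ (Q.T @ y), Q)
            else:
                from .gaussian_info import gaussian_cmi

                te = gaussian_cmi(X, y, Z)
            res = chi_square_test(
                te, n_rows, dof=len(source_vars), alpha=alpha_link
            )
            stats_m[source, target] = te
            pvals[source, target] = res.p_value
            if res.significant:
                adj[source, target] = True
    return InferredNetwork(adj, False, stats_m, pvals, cfg)


def infer_multivariate_te(
    ts: TimeSeriesSet, cfg: InferenceConfig
) -> tuple[InferredNetwork, list[ParentSet]]:
    """Effective network from greedy multivariate TE source selection.

    Per target: (1) embed the target's own past; (2) greedily add the
    lagged source variable with the highest CMI conditioned on the
    embedding plus already-selected sources, accepting via the
    max-statistic test at cfg.alpha (per-target FWER) and stopping at the
    first rejection; (3) optionally prune sources that fail a surrogate
    test given all other selected variables. A directed link i -> j
    exists iff any lag of i remains in j's final parent set.
    """
    if cfg.algorithm != "multi_te":
        raise ValueError("config algorithm must be 'multi_te'")
    n = ts.n_nodes
    L = cfg.max_lag_L
    adj = np.zeros((n, n), dtype=bool)
    stats_m = np.zeros((n, n))
    pvals = np.ones((n, n))
    parent_sets: list[ParentSet] = []
    for target in range(n):
        embedding = embed_target_past(ts, target, cfg)
        candidates = [
            LagVariable(s, lag)
            for s in range(n)
            if s != target
            for lag in range(1, L + 1)
        ]
        sources = _greedy_select(
            ts, target, candidates, embedding, cfg, stage="sources"
        )
        if cfg.prune and len(sources) > 1:
            sources = _prune_sources(ts, target, embedding, sources, cfg)
        collective = 0.0
        if sources:
            from .gaussian_info import gaussian_te

            collective = gaussian_te(
                ts, sources, target, embedding, align_lag=L
            )
            y = lagged_design(ts, [LagVariable(target, 0)], align_lag=L)[:, 0]
            for v in sources:
                adj[v.node, target] = True
                others = [u for u in sources if u != v]
                Z = lagged_design(ts, embedding + others, align_lag=L)
                Q = _orthonormal_basis(Z)
                x = lagged_design(ts, [v], align_lag=L)[:, 0]
                stat = partial_corr_stat(x, y - Q @ (Q.T @ y), Q)
                stats_m[v.node, target] = max(stats_m[v.node, target], stat)
        parent_sets.append(
            ParentSet(target, embedding, sources, collective)
        )
    return InferredNetwork(adj, False, stats_m, pvals, cfg), parent_sets


def infer(ts: TimeSeriesSet, cfg: InferenceConfig) -> InferredNetwork:
    """Dispatch on cfg.algorithm; multivariate parent sets are dropped."""
    if cfg.algorithm == "biv_mi":
        return infer_bivariate_mi(ts, cfg)
    if cfg.algorithm == "biv_te":
        return infer_bivariate_te(ts, cfg)
    net, _ = infer_multivariate_te(ts, cfg)
    return net
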