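"""Signed coupling matrix and Bayesian-network structure learning.

Gene-gene coupling is the Pearson correlation of log2 profiles across all
samples of all conditions: pairs that move always in the same (or always the
opposite) direction regardless of condition are tightly coupled.  Structure
learning is greedy hill climbing over DAGs (add / delete / reverse moves)
maximizing the Gaussian BIC score, with the move space restricted to pairs
whose |coupling| reaches a threshold and an in-degree cap for tractability.
Retained edges carry the sign and magnitude of the marginal coupling, so red
(positive) and blue (negative) edges can be drawn directly.

The layout is a weighted force-directed (Fruchterman-Reingold) embedding in
which strongly coupled genes land close together; it is presentation-only and
no downstream computation reads it.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["BNConfig", "coupling_matrix", "learn_structure", "bic_score", "layout"]


def coupling_matrix(expr: pd.DataFrame, genes: list[str] | set[str]) -> pd.DataFrame:
    """Pearson correlation of log2 profiles for the selected genes.

    Constant-profile genes are defined to have zero coupling to every other
    gene (and unit self-coupling).
    """
    genes = sorted(genes)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate coupling")
    x = expr.loc[genes].to_numpy()
    sd = x.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x)
    constant = sd == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


@dataclass(frozen=True)
class BNConfig:
    """Structure-learning knobs.

    ``edge_inclusion_threshold`` restricts candidate edges to pairs with
    |coupling| at or above it; ``max_parents`` caps the in-degree;
    ``n_restarts`` hill climbs are run (the first from the empty DAG, the rest
    from random DAGs over the candidate skeleton) and the best-scoring result
    is kept.
    """

    max_parents: int = 3
    n_restarts: int = 10
    edge_inclusion_threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if not 0 < self.edge_inclusion_threshold < 1:
            raise ValueError("edge_inclusion_threshold must lie in (0, 1)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


class _GaussScore:
    """Decomposable Gaussian BIC from the sample covariance.

    The local score of node v with parent set P is the maximized Gaussian
    log-likelihood of the linear regression v ~ P (computed from covariance
    blocks, no data pass) minus 0.5*(|P| + 2)*log(n) for the coefficients,
    intercept and residual variance.
    """

    _FLOOR = 1e-12  # residual-variance floor against perfectly collinear parents

    def __init__(self, x: np.ndarray):
        self.n = x.shape[0]
        self.cov = np.cov(x, rowvar=False, bias=True)
        if self.cov.ndim == 0:  # single gene
            self.cov = self.cov.reshape(1, 1)
        self._resid_cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def resid(self, v: int, parents: tuple[int, ...]) -> float:
        """Residual variance of v regressed on its parents (MLE)."""
        key = (v, parents)
        hit = self._resid_cache.get(key)
        if hit is not None:
            return hit
        if parents:
            p = list(parents)
            s_pp = self.cov[np.ix_(p, p)]
            s_vp = self.cov[v, p]
            try:
                beta = np.linalg.solve(s_pp, s_vp)
            except np.linalg.LinAlgError:
                beta, *_ = np.linalg.lstsq(s_pp, s_vp, rcond=None)
            resid = self.cov[v, v] - float(s_vp @ beta)
        else:
            resid = self.cov[v, v]
        resid = max(resid, self._FLOOR)
        self._resid_cache[key] = resid
        return resid

    def resid_with_extra(
        self, v: int, parents: tuple[int, ...], extra: np.ndarray
    ) -> np.ndarray:
        """Residual variance of v on parents + one extra node, vectorized.

        Uses the rank-one Schur update: adding u to P reduces the residual by
        cov(v, u | P)^2 / var(u | P).
        """
        base = self.resid(v, parents)
        if extra.size == 0:
            return np.empty(0)
        if parents:
            p = list(parents)
            s_pp = self.cov[np.ix_(p, p)]
            s_pu = self.cov[np.ix_(p, extra)]
            try:
                w = np.linalg.solve(s_pp, s_pu)
            except np.linalg.LinAlgError:
                w, *_ = np.linalg.lstsq(s_pp, s_pu, rcond=None)
            var_u = self.cov[extra, extra] - np.einsum("pu,pu->u", s_pu, w)
            cov_vu = self.cov[v, extra] - self.cov[v, p] @ w
        else:
            var_u = self.cov[extra, extra]
            cov_vu = self.cov[v, extra]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = base - np.where(var_u > self._FLOOR, cov_vu**2 / var_u, 0.0)
        return np.maximum(out, self._FLOOR)

    def local(self, v: int, parents) -> float:
        p = tuple(sorted(parents))
        resid = self.resid(v, p)
        n = self.n
        ll = -0.5 * n * (math.log(2.0 * math.pi * resid) + 1.0)
        return ll - 0.5 * (len(p) + 2) * math.log(n)


def bic_score(expr: pd.DataFrame, network: nx.DiGraph) -> float:
    """Gaussian BIC of a DAG on the expression data (higher is better)."""
    genes = sorted(network.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    scorer = _GaussScore(expr.loc[genes].to_numpy().T)
    return sum(
        scorer.local(idx[v], frozenset(idx[u] for u in network.predecessors(v)))
        for v in genes
    )


def _has_path(children_mask: list[int], src: int, dst: int) -> bool:
    """Directed reachability via bitmask BFS (children_mask[v] = bitset)."""
    if src == dst:
        return True
    target = 1 << dst
    seen = 1 << src
    frontier = children_mask[src]
    while frontier:
        if frontier & target:
            return True
        seen |= frontier
        new = 0
        f = frontier
        while f:
            low = f & -f
            new |= children_mask[low.bit_length() - 1]
            f ^= low
        frontier = new & ~seen
    return False


class _HillClimber:
    """One greedy search over DAGs restricted to the candidate skeleton."""

    EPS = 1e-9

    def __init__(self, scorer, candidates, max_parents):
        self.scorer = scorer
        self.cand = candidates  # node -> sorted tuple of allowed neighbours
        self.max_parents = max_parents
        self.n_nodes = len(candidates)
        self.parents: dict[int, set[int]] = {v: set() for v in range(self.n_nodes)}
        self.children: dict[int, set[int]] = {v: set() for v in range(self.n_nodes)}
        self.cmask: list[int] = [0] * self.n_nodes  # children as bitsets
        self.delta: dict[tuple, float] = {}
        self.heap: list = []
        self.counter = 0

    # -- move bookkeeping ---------------------------------------------------

    def _set(self, move, d: float) -> None:
        self.delta[move] = d
        if d > self.EPS:
            self.counter += 1
            heapq.heappush(self.heap, (-d, self.counter, move, d))

    def _add_delta(self, u: int, v: int) -> float:
        """Score change from giving v the extra parent u."""
        pv = tuple(sorted(self.parents[v]))
        base = self.scorer.resid(v, pv)
        new = float(self.scorer.resid_with_extra(v, pv, np.array([u]))[0])
        n = self.scorer.n
        return -0.5 * n * (math.log(new) - math.log(base)) - 0.5 * math.log(n)

    def _del_delta(self, u: int, v: int) -> float:
        """Score change from removing parent u of v."""
        pv = tuple(sorted(self.parents[v]))
        reduced = tuple(x for x in pv if x != u)
        n = self.scorer.n
        return (
            -0.5
            * n
            * (math.log(self.scorer.resid(v, reduced)) - math.log(self.scorer.resid(v, pv)))
            + 0.5 * math.log(n)
        )

    def _rev_delta(self, u: int, v: int) -> float:
        # reverse u->v: v loses parent u, u gains parent v
        self.parents[v].discard(u)
        gain = self._add_delta(v, u)
        self.parents[v].add(u)
        return self._del_delta(u, v) + gain

    def _refresh(self, nodes):
        n = self.scorer.n
        logn = math.log(n)
        for v in nodes:
            pv = tuple(sorted(self.parents[v]))
            base = self.scorer.resid(v, pv)
            addable = np.array(
                [
                    u
                    for u in self.cand[v]
                    if u not in self.parents[v] and v not in self.parents[u]
                ],
                dtype=int,
            )
            if addable.size:
                new_resid = self.scorer.resid_with_extra(v, pv, addable)
                deltas = -0.5 * n * (np.log(new_resid) - math.log(base)) - 0.5 * logn
                for u, d in zip(addable.tolist(), deltas.tolist()):
                    self._set(("add", u, v), d)
            for u in sorted(self.parents[v]):
                self._set(("del", u, v), self._del_delta(u, v))
                self._set(("rev", u, v), self._rev_delta(u, v))
            for w in sorted(self.children[v]):
                self._set(("rev", v, w), self._rev_delta(v, w))

    def _applicable(self, move) -> bool:
        """Structural applicability; False means the entry is permanently stale."""
        kind, u, v = move
        if kind == "add":
            return u not in self.parents[v] and v not in self.parents[u]
        return u in self.parents[v]

    def _unblocked(self, move) -> bool:
        """Constraint check (in-degree cap, acyclicity) for applicable moves."""
        kind, u, v = move
        if kind == "add":
            return len(self.parents[v]) < self.max_parents and not _has_path(
                self.cmask, v, u
            )
        if kind == "del":
            return True
        # reverse: u must accept a new parent and no alternative path u ~> v
        if len(self.parents[u]) >= self.max_parents:
            return False
        self.cmask[u] &= ~(1 << v)
        blocked = _has_path(self.cmask, u, v)
        self.cmask[u] |= 1 << v
        return not blocked

    def _link(self, u, v):
        self.parents[v].add(u)
        self.children[u].add(v)
        self.cmask[u] |= 1 << v

    def _unlink(self, u, v):
        self.parents[v].discard(u)
        self.children[u].discard(v)
        self.cmask[u] &= ~(1 << v)

    def _apply(self, move):
        kind, u, v = move
        if kind == "add":
            self._link(u, v)
            return (v,)
        if kind == "del":
            self._unlink(u, v)
            return (u, v)  # the opposite-orientation add reopens at u
        self._unlink(u, v)
        self._link(v, u)
        return (u, v)

    # -- search -------------------------------------------------------------

    def seed_graph(self, edges):
        for u, v in edges:
            self._link(u, v)

    def run(self) -> dict[int, set[int]]:
        self._refresh(range(self.n_nodes))
        blocked: list = []
        while True:
            move = None
            while self.heap:
                neg_d, _, m, d_at_push = heapq.heappop(self.heap)
                if self.delta.get(m) != d_at_push or not self._applicable(m):
                    continue  # stale entry
                if not self._unblocked(m):
                    blocked.append((neg_d, m, d_at_push))
                    continue
                move = m
                break
            if move is None:
                return self.parents
            affected = self._apply(move)
            self._refresh(affected)
            # Adding an edge can only create new blocks, never remove one, so
            # constraint-blocked moves need re-queueing only after a move that
            # removed or reoriented an edge (and even then their deltas may
            # have been superseded by _refresh, which stale-checking handles).
            if move[0] != "add" and blocked:
                for neg_d, m, d_at_push in blocked:
                    self.counter += 1
                    heapq.heappush(self.heap, (neg_d, self.counter, m, d_at_push))
                blocked.clear()

    def total_score(self) -> float:
        return sum(
            self.scorer.local(v, self.parents[v]) for v in range(self.n_nodes)
        )


def learn_structure(
    expr: pd.DataFrame,
    genes: list[str] | set[str],
    coupling: pd.DataFrame,
    cfg: BNConfig = BNConfig(),
) -> nx.DiGraph:
    """Learn a DAG over the selected genes by BIC hill climbing.

    Edges are restricted to pairs with |coupling| >= the inclusion threshold;
    each retained edge is annotated with ``sign`` ("+"/"-") and ``weight``
    (|coupling|).  An empty candidate skeleton yields a network with nodes and
    no edges.  Deterministic given the config seed.
    """
    genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    c = coupling.loc[genes, genes].to_numpy()
    x = expr.loc[genes].to_numpy().T  # samples x genes
    scorer = _GaussScore(x)

    thr = cfg.edge_inclusion_threshold
    candidates = {
        v: tuple(
            u for u in range(len(genes)) if u != v and abs(c[u, v]) >= thr
        )
        for v in range(len(genes))
    }

    rng = np.random.default_rng(cfg.seed)
    cand_pairs = sorted(
        {(min(u, v), max(u, v)) for v, us in candidates.items() for u in us}
    )

    best_parents, best_score = None, -math.inf
    for restart in range(cfg.n_restarts):
        hc = _HillClimber(scorer, candidates, cfg.max_parents)
        if restart > 0 and cand_pairs:
            order = rng.permutation(len(genes))
            rank = np.empty(len(genes), dtype=int)
            rank[order] = np.arange(len(genes))
            keep = rng.random(len(cand_pairs)) < 0.2
            edges = []
            indeg = {v: 0 for v in range(len(genes))}
            for (a, b), k in zip(cand_pairs, keep):
                if not k:
                    continue
                u, v = (a, b) if rank[a] < rank[b] else (b, a)
                if indeg[v] < cfg.max_parents:
                    edges.append((u, v))
                    indeg[v] += 1
            hc.seed_graph(edges)
        parents = hc.run()
        score = hc.total_score()
        if score > best_score + 1e-9:
            best_score, best_parents = score, parents

    network = nx.DiGraph()
    network.add_nodes_from(genes)
    for v, pset in best_parents.items():
        for u in pset:
            coup = c[u, v]
            network.add_edge(
                genes[u],
                genes[v],
                sign="+" if coup >= 0 else "-",
                weight=float(abs(coup)),
            )
    return network


def layout(
    network: nx.DiGraph, seed: int = 0, iterations: int = 100
) -> dict[str, tuple[float, float]]:
    """Weighted force-directed 2-D embedding of the network.

    Attraction grows with edge weight, so tightly coupled genes are plotted
    close together.  A single node is placed at the origin.  Deterministic
    under a fixed seed.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network must have at least one node")
    if network.number_of_nodes() == 1:
        return {node: (0.0, 0.0) for node in network.nodes}
    pos = nx.spring_layout(
        network.to_undirected(as_view=True),
        weight="weight",
        seed=seed,
        iterations=iterations,
    )
    return {node: (float(p[0]), float(p[1])) for node, p in pos.items()}
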