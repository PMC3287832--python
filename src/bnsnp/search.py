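"""Score-based hill climbing over DAG structures with random restarts.

The search protocol: greedy best-improvement ascent over single-arc
moves (add / delete / reverse), restarted from random perturbations of
the incumbent best network.  Restart 0 always climbs from the empty
graph; each later restart perturbs the best structure found so far with
a configured number of random arc operations and climbs again, keeping
the best-scoring network overall.  Everything is deterministic given
the seed.

Tie-breaking among equal score deltas is fixed (delete < reverse < add,
then lexicographic arc order) so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .graph import Dag
from .scoring import SCORE_TYPES, DiscreteData, ScoreCache, network_score

_OP_RANK = {"delete": 0, "reverse": 1, "add": 2}


@dataclass(frozen=True)
class SearchConfig:
    """Hill-climbing search settings.

    ``restarts`` counts perturb-and-climb rounds after the initial climb
    from the empty graph; ``perturbations`` is the number of random arc
    operations attempted per restart.  ``max_parents`` bounds family
    size (pure log-likelihood scoring otherwise densifies toward
    near-complete graphs).  ``forbidden_arcs`` is an optional blacklist
    of directed arcs the search may never introduce.
    """

    score_type: str = "loglik"
    restarts: int = 1000
    perturbations: int = 2400
    max_parents: int = 3
    seed: int = 0
    iss: float = 1.0
    restart_mode: str = "perturb_best"  # or "fresh_random"
    forbidden_arcs: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        if self.score_type not in SCORE_TYPES:
            raise ValueError(f"unknown score type {self.score_type!r}")
        if self.restarts < 0 or self.perturbations < 0:
            raise ValueError("restarts and perturbations must be >= 0")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.restart_mode not in ("perturb_best", "fresh_random"):
            raise ValueError(f"unknown restart mode {self.restart_mode!r}")


@dataclass
class ScoredNetwork:
    """A learned structure with its score and accepted-move trace."""

    dag: Dag
    score: float
    score_type: str
    search_trace: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)


def _local(cache: ScoreCache, data: DiscreteData, cfg: SearchConfig,
           child: str, parents: Iterable[str]) -> float:
    return cache.local(data, child, parents, cfg.score_type, cfg.iss)


def best_neighbor(dag: Dag, data: DiscreteData, cfg: SearchConfig,
                  cache: ScoreCache) -> tuple[tuple[str, tuple[str, str]] | None, float]:
    """Best single-arc move, or ``(None, 0.0)`` if no move improves.

    Scans every legal add/delete/reverse respecting acyclicity,
    ``max_parents`` and the blacklist; exploits score decomposability so
    each candidate costs at most two local-score lookups.
    """
    nodes = dag.nodes
    base = {v: _local(cache, data, cfg, v, dag.parents(v)) for v in nodes}
    best_op: tuple[str, tuple[str, str]] | None = None
    best_delta = 0.0
    best_key: tuple[int, tuple[str, str]] | None = None

    def consider(op: str, arc: tuple[str, str], delta: float) -> None:
        nonlocal best_op, best_delta, best_key
        key = (_OP_RANK[op], arc)
        if delta > best_delta or (delta == best_delta and best_op is not None
                                  and key < best_key):
            best_op, best_delta, best_key = (op, arc), delta, key

    for u, v in dag.edges:
        pv = dag.parents(v)
        d_del = _local(cache, data, cfg, v, pv - {u}) - base[v]
        consider("delete", (u, v), d_del)
        # reverse u->v: delete plus add v->u
        if (v, u) not in cfg.forbidden_arcs and len(dag.parents(u)) < cfg.max_parents:
            stripped = dag.apply_arc_operation("delete", (u, v))
            if not stripped.reaches(u, v):
                d_rev = d_del + _local(cache, data, cfg, u, dag.parents(u) | {v}) - base[u]
                consider("reverse", (u, v), d_rev)
    for u in nodes:
        for v in nodes:
            if u == v or dag.has_edge(u, v) or dag.has_edge(v, u):
                continue
            if (u, v) in cfg.forbidden_arcs:
                continue
            if len(dag.parents(v)) >= cfg.max_parents:
                continue
            if dag.reaches(v, u):
                continue
            d_add = _local(cache, data, cfg, v, dag.parents(v) | {u}) - base[v]
            consider("add", (u, v), d_add)
    if best_op is None or best_delta <= 0.0:
        return None, 0.0
    return best_op, best_delta


def hill_climb(start: Dag, data: DiscreteData, cfg: SearchConfig,
               cache: ScoreCache | None = None) -> ScoredNetwork:
    """Greedy ascent from ``start`` until no single-arc move improves."""
    if cache is None:
        cache = ScoreCache()
    dag = start
    score = network_score(data, dag, cfg.score_type, cache, iss=cfg.iss)
    trace: list[tuple[str, tuple[str, str], float]] = []
    while True:
        move, delta = best_neighbor(dag, data, cfg, cache)
        if move is None:
            break
        op, arc = move
        nxt = dag.apply_arc_operation(op, arc)
        assert nxt is not None  # legality pre-checked during enumeration
        dag = nxt
        score += delta
        trace.append((op, arc, delta))
    return ScoredNetwork(dag, score, cfg.score_type, trace)


def perturb_dag(dag: Dag, n_ops: int, rng: np.random.Generator,
                max_parents: int | None = None,
                forbidden_arcs: frozenset[tuple[str, str]] = frozenset()) -> Dag:
    """Attempt ``n_ops`` uniformly random arc operations.

    Each attempt draws an operation type and an arc uniformly; attempts
    that would create a cycle, exceed ``max_parents``, hit the blacklist
    or lack a target arc are skipped (they still consume an attempt).
    The result is always acyclic.
    """
    nodes = dag.nodes
    current = dag
    for _ in range(n_ops):
        op = ("add", "delete", "reverse")[rng.integers(3)]
        if op == "add":
            u = nodes[rng.integers(len(nodes))]
            v = nodes[rng.integers(len(nodes))]
            if u == v or current.has_edge(u, v) or (u, v) in forbidden_arcs:
                continue
            if max_parents is not None and len(current.parents(v)) >= max_parents:
                continue
            nxt = current.apply_arc_operation("add", (u, v))
        else:
            edges = current.edges
            if not edges:
                continue
            u, v = edges[rng.integers(len(edges))]
            if op == "reverse":
                if (v, u) in forbidden_arcs:
                    continue
                if max_parents is not None and len(current.parents(u)) >= max_parents:
                    continue
            nxt = current.apply_arc_operation(op, (u, v))
        if nxt is not None:
            current = nxt
    return current


def learn_structure(data: DiscreteData, cfg: SearchConfig,
                    roles: dict[str, str] | None = None) -> ScoredNetwork:
    """Hill climbing with random restarts over all variables in ``data``.

    ``roles`` assigns node roles (default: every variable ``snp``);
    restart 0 climbs from the empty graph, subsequent restarts from a
    perturbation of the incumbent best (or a fresh random perturbation
    of the empty graph under ``restart_mode="fresh_random"``).
    """
    if data.n_rows == 0:
        raise ValueError("cannot learn a structure from empty data")
    if roles is None:
        roles = {name: "snp" for name in data.names}
    if set(roles) != set(data.names):
        raise ValueError("roles must cover exactly the data variables")
    rng = np.random.default_rng(cfg.seed)
    cache = ScoreCache()
    empty = Dag(roles)
    best = hill_climb(empty, data, cfg, cache)
    for _ in range(cfg.restarts):
        origin = best.dag if cfg.restart_mode == "perturb_best" else empty
        start = perturb_dag(origin, cfg.perturbations, rng,
                            cfg.max_parents, cfg.forbidden_arcs)
        candidate = hill_climb(start, data, cfg, cache)
        if candidate.score > best.score:
            best = candidate
    return best
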