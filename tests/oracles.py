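"""Independent brute-force oracles shared across tests.

Everything here deliberately avoids the package's own code paths: DAG
enumeration by edge-subset filtering, Markov blankets from the three
definitional clauses, exact rational hypergeometric arithmetic, and a
hand-rolled Newton logistic solver.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def all_dags(nodes: tuple[str, ...]):
    """Yield every acyclic edge set over ``nodes`` (brute force)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(2 ** len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        if _acyclic(nodes, edges):
            yield tuple(edges)


def _acyclic(nodes, edges) -> bool:
    children = {v: [] for v in nodes}
    for u, v in edges:
        children[u].append(v)
    state = {v: 0 for v in nodes}

    def dfs(v):
        state[v] = 1
        for c in children[v]:
            if state[c] == 1 or (state[c] == 0 and dfs(c)):
                return True
        state[v] = 2
        return False

    return not any(state[v] == 0 and dfs(v) for v in nodes)


def reachable_closure(nodes, edges, source):
    """Descendants by repeated boolean matrix powering (transitive closure)."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        adj[idx[u], idx[v]] = True
    closure = adj.copy()
    for _ in range(n):
        closure = closure | (closure @ adj)
    return {v for v in nodes if closure[idx[source], idx[v]]} - {source}


def markov_blanket_clauses(edges, v):
    """Markov blanket assembled clause by clause from the definition."""
    parents = {u for u, w in edges if w == v}
    children = {w for u, w in edges if u == v}
    coparents = {u for u, w in edges if w in children}
    return (parents | children | coparents) - {v}


def hypergeom_tail_exact(N: int, m: int, n: int, k: int) -> float:
    """Exact rational upper tail via big-integer combinatorics."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(n, m) + 1):
        total += Fraction(math.comb(m, i) * math.comb(N - m, n - i), denom)
    return float(total)


def newton_logistic(y: np.ndarray, X: np.ndarray, maxiter: int = 100,
                    tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Plain Newton-Raphson logistic MLE; returns (beta, deviance)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        W = mu * (1.0 - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, -2.0 * loglik


def sample_discrete_bn(nodes, edges, cpts, n, rng):
    """Ancestral sampling of binary variables from explicit CPTs.

    ``cpts[v]`` maps each tuple of (sorted) parent values to
    P(v = 1 | parents).
    """
    order = []
    remaining = set(nodes)
    parents = {v: sorted(u for u, w in edges if w == v) for v in nodes}
    while remaining:
        for v in sorted(remaining):
            if all(p not in remaining for p in parents[v]):
                order.append(v)
                remaining.discard(v)
                break
    data = {}
    for v in order:
        if parents[v]:
            pv = np.stack([data[p] for p in parents[v]], axis=1)
            prob = np.array([cpts[v][tuple(row)] for row in pv])
        else:
            prob = np.full(n, cpts[v][()])
        data[v] = (rng.random(n) < prob).astype(np.int64)
    return data


def random_binary_bn(nodes, rng, max_parents=2, strength=(0.1, 0.9)):
    """Random DAG + random strong CPTs over binary nodes."""
    order = list(nodes)
    rng.shuffle(order)
    edges = []
    for i, v in enumerate(order):
        pool = order[:i]
        k = int(rng.integers(0, min(len(pool), max_parents) + 1))
        for u in sorted(rng.choice(pool, size=k, replace=False)) if k else []:
            edges.append((u, v))
    lo, hi = strength
    cpts = {}
    parents = {v: sorted(u for u, w in edges if w == v) for v in nodes}
    for v in nodes:
        cpts[v] = {}
        for combo in itertools.product((0, 1), repeat=len(parents[v])):
            cpts[v][combo] = lo if rng.random() < 0.5 else hi
    return edges, cpts
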