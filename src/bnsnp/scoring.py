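"""Decomposable network scores for fully discrete data.

A Bayesian-network score here is a sum of per-family local scores, where
a *family* is a child variable together with its parent set.  The
maximised multinomial log-likelihood is the primary score; AIC, BIC and
Dirichlet marginal likelihoods (BDeu-style ``bde`` and the all-ones
``k2`` prior) are available as alternatives.  Local scores depend only
on the family's contingency counts, so a per-family cache makes
single-arc search moves cheap.

Conventions: natural logarithms throughout; ``0 * ln 0 = 0``; the
parameter count ``q`` for AIC/BIC uses the full state-space product of
the parents (not just configurations observed in the data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graph import Dag

SCORE_TYPES = ("loglik", "aic", "bic", "bde", "k2")


class DiscreteData:
    """Column-encoded categorical data table.

    Parameters
    ----------
    table
        ``(n_rows, n_vars)`` integer array; column ``j`` takes values in
        ``range(cards[j])``.
    names
        Variable names, one per column, unique.
    cards
        Declared cardinality (number of states) per variable.  States
        absent from the data still count toward model dimension.
    """

    def __init__(self, table: np.ndarray, names: Sequence[str], cards: Sequence[int]):
        table = np.asarray(table)
        if table.ndim != 2:
            raise ValueError("table must be 2-D (rows x variables)")
        if table.shape[1] != len(names) or len(names) != len(cards):
            raise ValueError("names/cards length must match table columns")
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if not np.issubdtype(table.dtype, np.integer):
            raise ValueError("table must be integer-coded")
        cards = [int(c) for c in cards]
        for j, (name, card) in enumerate(zip(names, cards)):
            col = table[:, j]
            if card < 2:
                raise ValueError(f"variable {name!r}: cardinality must be >= 2")
            if col.size and (col.min() < 0 or col.max() >= card):
                raise ValueError(
                    f"variable {name!r}: values outside [0, {card})"
                )
        self.table = np.ascontiguousarray(table, dtype=np.int64)
        self.names = tuple(names)
        self.cards = dict(zip(self.names, cards))
        self._index = {name: j for j, name in enumerate(self.names)}

    @property
    def n_rows(self) -> int:
        return self.table.shape[0]

    def column(self, name: str) -> np.ndarray:
        if name not in self._index:
            raise ValueError(f"unknown variable {name!r}")
        return self.table[:, self._index[name]]

    def card(self, name: str) -> int:
        if name not in self.cards:
            raise ValueError(f"unknown variable {name!r}")
        return self.cards[name]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cards: Mapping[str, int] | None = None) -> "DiscreteData":
        """Build from an integer-coded DataFrame.

        ``cards`` may declare cardinalities explicitly (e.g. 3 for SNP
        dosages even when only two dosage values are observed); columns
        not listed default to ``max + 1``.
        """
        names = list(df.columns)
        table = df.to_numpy(dtype=np.int64)
        resolved = []
        for j, name in enumerate(names):
            if cards is not None and name in cards:
                resolved.append(int(cards[name]))
            else:
                resolved.append(int(table[:, j].max()) + 1 if len(table) else 2)
        return cls(table, names, resolved)


@dataclass(frozen=True)
class FamilyCounts:
    """Contingency counts for one child / parent-set family.

    ``n_ijk[j, k]`` is the number of rows with parent configuration
    ``j`` and child state ``k``; ``n_ij`` is its row sum.  Parent
    configurations are indexed over the full state-space product, so
    unobserved configurations appear with zero counts.
    """

    child: str
    parents: tuple[str, ...]
    child_card: int
    parent_cards: tuple[int, ...]
    n_ijk: np.ndarray

    @property
    def n_ij(self) -> np.ndarray:
        return self.n_ijk.sum(axis=1)

    @property
    def n_total(self) -> int:
        return int(self.n_ijk.sum())

    @property
    def n_parent_configs(self) -> int:
        return self.n_ijk.shape[0]


def family_counts(data: DiscreteData, child: str, parents: Iterable[str]) -> FamilyCounts:
    """Exact cross-tabulation of ``child`` against its parent configurations."""
    parents = tuple(sorted(parents))
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    r = data.card(child)
    child_col = data.column(child)
    if parents:
        pcards = tuple(data.card(p) for p in parents)
        cols = [data.column(p) for p in parents]
        cfg = np.ravel_multi_index(cols, pcards)
        q = int(np.prod(pcards))
    else:
        pcards = ()
        cfg = np.zeros(data.n_rows, dtype=np.int64)
        q = 1
    flat = np.bincount(cfg * r + child_col, minlength=q * r)
    return FamilyCounts(child, parents, r, pcards, flat.reshape(q, r))


def _loglik(counts: FamilyCounts) -> float:
    n_ijk = counts.n_ijk
    n_ij = counts.n_ij
    mask = n_ijk > 0
    terms = n_ijk[mask] * (
        np.log(n_ijk[mask]) - np.log(np.broadcast_to(n_ij[:, None], n_ijk.shape)[mask])
    )
    return float(terms.sum())


def _dim(counts: FamilyCounts) -> int:
    return (counts.child_card - 1) * counts.n_parent_configs


def _dirichlet_marginal(counts: FamilyCounts, alpha_cell: float) -> float:
    """Log Dirichlet-multinomial marginal likelihood with a flat per-cell
    hyperparameter ``alpha_cell``."""
    n_ijk = counts.n_ijk
    n_ij = counts.n_ij
    r = counts.child_card
    a_ij = r * alpha_cell
    score = float(np.sum(gammaln(a_ij) - gammaln(a_ij + n_ij)))
    score += float(np.sum(gammaln(alpha_cell + n_ijk) - gammaln(alpha_cell)))
    return score


def local_score(counts: FamilyCounts, score_type: str, *, iss: float = 1.0) -> float:
    """Local (per-family) score.

    ``loglik`` is the maximised log-likelihood; ``aic`` and ``bic``
    subtract dimension penalties ``q`` and ``(ln N / 2) q`` with
    ``q = (r - 1) * (#parent configurations)``; ``bde`` is the BDeu
    Dirichlet marginal with imaginary sample size ``iss`` (per-cell
    hyperparameter ``iss / (q * r)``); ``k2`` is the Dirichlet marginal
    with every hyperparameter equal to 1.
    """
    if score_type == "loglik":
        return _loglik(counts)
    if score_type == "aic":
        return _loglik(counts) - _dim(counts)
    if score_type == "bic":
        n = counts.n_total
        return _loglik(counts) - 0.5 * np.log(n) * _dim(counts) if n else 0.0
    if score_type == "bde":
        if iss <= 0:
            raise ValueError("imaginary sample size must be > 0")
        alpha_cell = iss / (counts.n_parent_configs * counts.child_card)
        return _dirichlet_marginal(counts, alpha_cell)
    if score_type == "k2":
        return _dirichlet_marginal(counts, 1.0)
    raise ValueError(f"unknown score type {score_type!r}")


@dataclass
class ScoreCache:
    """Memo of local scores keyed by (child, parent set, score type, iss).

    Cache hits return bit-identical values to recomputation because the
    stored float is the recomputation's own result.
    """

    _store: dict = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def local(self, data: DiscreteData, child: str, parents: Iterable[str],
              score_type: str, iss: float = 1.0) -> float:
        key = (child, frozenset(parents), score_type, iss if score_type == "bde" else None)
        if key in self._store:
            self.hits += 1
            return self._store[key]
        self.misses += 1
        value = local_score(family_counts(data, child, parents), score_type, iss=iss)
        self._store[key] = value
        return value

    def __len__(self) -> int:
        return len(self._store)


def network_score(data: DiscreteData, dag: Dag, score_type: str,
                  cache: ScoreCache | None = None, *, iss: float = 1.0) -> float:
    """Decomposable network score: sum of local scores over all families."""
    if score_type not in SCORE_TYPES:
        raise ValueError(f"unknown score type {score_type!r}")
    if cache is None:
        cache = ScoreCache()
    total = 0.0
    for v in dag.nodes:
        total += cache.local(data, v, dag.parents(v), score_type, iss)
    return total
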