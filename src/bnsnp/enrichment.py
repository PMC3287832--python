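"""Candidate-SNP subset extraction and hypergeometric enrichment.

Given a learned network whose outcome node is the Affected phenotype,
three candidate sets are extracted: the descendants of Affected (DA),
the Markov blanket of Affected (MBA) and the children of Affected (CA).
Each set is reduced to SNP-role nodes and scored for enrichment of true
causal SNPs with the exact upper-tail hypergeometric probability

    P(X >= k) = sum_{i=k}^{min(n, m)} C(m, i) C(N-m, n-i) / C(N, n)

where N is the number of polymorphic SNPs analysed, m the number of
true causal SNPs among them, n the selected-set size and k the number
of causal SNPs selected.  The pmf is evaluated in log-gamma space and
the tail summed from its far (smallest-term) end for stability.

Note CA is computed directly as children(Affected): the identity
CA = DA ∩ MBA fails on graphs where a strict descendant of the outcome
is also a co-parent of one of its children, so the definitional set is
reported and callers may compare against the intersection themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln

from .graph import Dag

SUBSET_METHODS = ("DA", "MBA", "CA")


def _check_args(N: int, m: int, n: int, k: int) -> None:
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= m, n <= N; got N={N}, m={m}, n={n}")
    if not (0 <= k <= min(n, m)):
        raise ValueError(f"require 0 <= k <= min(n, m); got n={n}, m={m}, k={k}")


def _log_pmf(N: int, m: int, n: int, k: int) -> float:
    def log_comb(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return float(log_comb(m, k) + log_comb(N - m, n - k) - log_comb(N, n))


def hypergeom_pmf(N: int, m: int, n: int, k: int) -> float:
    """P(X = k) for a hypergeometric draw of ``n`` from ``N`` with ``m`` successes."""
    _check_args(N, m, n, k)
    if k < n + m - N:  # impossible cell below the support
        return 0.0
    return math.exp(_log_pmf(N, m, n, k))


def hypergeom_tail(N: int, m: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k); returns 1.0 at or below the support floor."""
    _check_args(N, m, n, k)
    lo = max(0, n + m - N)
    if k <= lo:
        return 1.0
    # ascending-magnitude summation: far tail first
    total = 0.0
    for i in range(min(n, m), k - 1, -1):
        total += math.exp(_log_pmf(N, m, n, i))
    return min(total, 1.0)


def select_subset(dag: Dag, method: str) -> frozenset[str]:
    """SNP-role nodes in the DA / MBA / CA set of the outcome node."""
    if method not in SUBSET_METHODS:
        raise ValueError(f"unknown subset method {method!r}; expected one of {SUBSET_METHODS}")
    outcome = dag.outcome_node
    if outcome is None:
        raise ValueError("graph has no outcome node")
    if method == "DA":
        raw = dag.descendants(outcome)
    elif method == "MBA":
        raw = dag.markov_blanket(outcome)
    else:
        raw = dag.children(outcome)
    return frozenset(v for v in raw if dag.roles[v] == "snp")


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment accounting for one selected SNP set.

    ``N``: polymorphic SNPs analysed; ``m``: causal SNPs among them;
    ``n``: SNPs selected; ``k``: causal SNPs selected; ``p_tail``:
    exact P(X >= k).
    """

    method: str
    selected_snps: frozenset[str]
    N: int
    m: int
    n: int
    k: int
    p_tail: float


def evaluate_enrichment(selected: frozenset[str] | set[str], truth: frozenset[str] | set[str],
                        N: int, m: int, *, universe: frozenset[str] | set[str] | None = None,
                        method: str = "custom") -> EnrichmentResult:
    """Score a selected SNP set against the causal truth set.

    ``truth`` is the causal SNP ids within the analysed universe (so
    ``m == len(truth)`` when both are restricted to it).  An empty
    selection scores ``p_tail = 1`` by the k = 0 convention.
    """
    selected = frozenset(selected)
    truth = frozenset(truth)
    if universe is not None and not selected <= frozenset(universe):
        extra = sorted(selected - frozenset(universe))
        raise ValueError(f"selected SNPs outside the analysed universe: {extra}")
    n = len(selected)
    k = len(selected & truth)
    return EnrichmentResult(method, selected, N, m, n, k, hypergeom_tail(N, m, n, k))


def evaluate_network_subsets(dag: Dag, truth: frozenset[str] | set[str],
                             N: int, m: int) -> list[EnrichmentResult]:
    """Evaluate all three subset methods on a learned network."""
    out = []
    for method in SUBSET_METHODS:
        sel = select_subset(dag, method)
        res = evaluate_enrichment(sel, truth, N, m, method=method)
        out.append(EnrichmentResult(method, res.selected_snps, N, m, res.n, res.k, res.p_tail))
    return out


def format_p(p: float) -> str:
    """3-significant-figure display used in report tables (``1`` stays ``1``)."""
    if p >= 1.0:
        return "1"
    return f"{p:.3g}"
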