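"""Directed-acyclic-graph core for discrete Bayesian networks.

Nodes carry a role — ``snp``, ``covariate`` or ``outcome`` — so that
downstream subset selection can separate genetic variables from the
phenotype machinery.  The graph itself is a plain parent/child adjacency
structure with acyclicity enforced on every mutation; single-arc
operations (add / delete / reverse) are the primitives the hill-climbing
search perturbs.

Cycle-creating add/reverse operations are *rejected* (``None`` return)
rather than raised, so the search loop can enumerate neighbours cheaply;
malformed requests (unknown nodes, deleting an absent arc) are hard
errors.
"""

from __future__ import annotations

from typing import Iterable, Mapping

ROLES = ("snp", "covariate", "outcome")
OUTCOME = "outcome"

#: Arc operations understood by :meth:`Dag.apply_arc_operation`.
ARC_OPS = ("add", "delete", "reverse")


def is_acyclic(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> bool:
    """True iff the directed graph ``(nodes, edges)`` has no directed cycle.

    Kahn-style peeling; raises ``ValueError`` if an edge references an
    unknown node.
    """
    nodes = list(nodes)
    known = set(nodes)
    children: dict[str, list[str]] = {v: [] for v in nodes}
    indeg = {v: 0 for v in nodes}
    for u, v in edges:
        if u not in known or v not in known:
            raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
        children[u].append(v)
        indeg[v] += 1
    stack = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return seen == len(nodes)


class Dag:
    """Directed acyclic graph over role-tagged nodes.

    Parameters
    ----------
    roles
        Mapping node id -> role in ``{"snp", "covariate", "outcome"}``.
        At most one node may carry the ``outcome`` role.
    edges
        Iterable of ``(parent, child)`` pairs; must be acyclic.
    """

    __slots__ = ("roles", "_parents", "_children")

    def __init__(self, roles: Mapping[str, str], edges: Iterable[tuple[str, str]] = ()):
        for node, role in roles.items():
            if role not in ROLES:
                raise ValueError(f"node {node!r} has unknown role {role!r}")
        outcomes = [v for v, r in roles.items() if r == OUTCOME]
        if len(outcomes) > 1:
            raise ValueError(f"multiple outcome nodes: {outcomes}")
        self.roles: dict[str, str] = dict(roles)
        self._parents: dict[str, set[str]] = {v: set() for v in self.roles}
        self._children: dict[str, set[str]] = {v: set() for v in self.roles}
        edges = list(edges)
        for u, v in edges:
            self._check_node(u)
            self._check_node(v)
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if v in self._children[u]:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            self._children[u].add(v)
            self._parents[v].add(u)
        if not is_acyclic(self.roles, edges):
            raise ValueError("edge set contains a directed cycle")

    # -- basic queries -------------------------------------------------

    def _check_node(self, v: str) -> None:
        if v not in self.roles:
            raise ValueError(f"unknown node {v!r}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.roles))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted((u, v) for u, cs in self._children.items() for v in cs))

    @property
    def n_edges(self) -> int:
        return sum(len(cs) for cs in self._children.values())

    @property
    def outcome_node(self) -> str | None:
        for v, r in self.roles.items():
            if r == OUTCOME:
                return v
        return None

    def parents(self, v: str) -> frozenset[str]:
        self._check_node(v)
        return frozenset(self._parents[v])

    def children(self, v: str) -> frozenset[str]:
        self._check_node(v)
        return frozenset(self._children[v])

    def has_edge(self, u: str, v: str) -> bool:
        self._check_node(u)
        self._check_node(v)
        return v in self._children[u]

    def copy(self) -> "Dag":
        new = Dag.__new__(Dag)
        new.roles = dict(self.roles)
        new._parents = {v: set(ps) for v, ps in self._parents.items()}
        new._children = {v: set(cs) for v, cs in self._children.items()}
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return self.roles == other.roles and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((tuple(sorted(self.roles.items())), self.edges))

    def __repr__(self) -> str:
        return f"Dag({len(self.roles)} nodes, {self.n_edges} edges)"

    # -- reachability / blanket ----------------------------------------

    def reaches(self, u: str, v: str) -> bool:
        """True iff a directed path u -> ... -> v exists (u != v trivially False)."""
        if u == v:
            return True
        stack = [u]
        seen = {u}
        while stack:
            w = stack.pop()
            for c in self._children[w]:
                if c == v:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def descendants(self, v: str) -> frozenset[str]:
        """All nodes reachable from ``v`` by a directed path, excluding ``v``."""
        self._check_node(v)
        out: set[str] = set()
        stack = [v]
        while stack:
            w = stack.pop()
            for c in self._children[w]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        out.discard(v)
        return frozenset(out)

    def markov_blanket(self, v: str) -> frozenset[str]:
        """Parents, children, and co-parents of the children of ``v``."""
        self._check_node(v)
        out = set(self._parents[v]) | set(self._children[v])
        for c in self._children[v]:
            out |= self._parents[c]
        out.discard(v)
        return frozenset(out)

    # -- arc operations ------------------------------------------------

    def apply_arc_operation(self, op: str, arc: tuple[str, str]) -> "Dag | None":
        """Return a new Dag with ``arc`` added/deleted/reversed.

        Returns ``None`` (a rejection signal, not an error) when an add
        or reverse would create a directed cycle.  Raises ``ValueError``
        for unknown operations/nodes, adding an existing arc, or
        deleting/reversing a missing one.
        """
        u, v = arc
        self._check_node(u)
        self._check_node(v)
        if op == "add":
            if u == v:
                raise ValueError("self-loops are not permitted")
            if self.has_edge(u, v):
                raise ValueError(f"arc ({u!r}, {v!r}) already present")
            if self.reaches(v, u):  # u -> v would close a cycle
                return None
            new = self.copy()
            new._children[u].add(v)
            new._parents[v].add(u)
            return new
        if op == "delete":
            if not self.has_edge(u, v):
                raise ValueError(f"arc ({u!r}, {v!r}) not present")
            new = self.copy()
            new._children[u].discard(v)
            new._parents[v].discard(u)
            return new
        if op == "reverse":
            if not self.has_edge(u, v):
                raise ValueError(f"arc ({u!r}, {v!r}) not present")
            new = self.copy()
            new._children[u].discard(v)
            new._parents[v].discard(u)
            if new.reaches(u, v):  # another u ~> v path: v -> u would cycle
                return None
            new._children[v].add(u)
            new._parents[u].add(v)
            return new
        raise ValueError(f"unknown arc operation {op!r}")


# -- serialisation -----------------------------------------------------

_DOT_SHAPE = {"snp": "ellipse", "covariate": "box", "outcome": "diamond"}
_DOT_FILL = {"snp": "white", "covariate": "lightgrey", "outcome": "lightcoral"}


def to_dot(dag: Dag) -> str:
    """Render ``dag`` as Graphviz DOT text.

    Node roles map to distinct shapes/fills; nodes and edges are emitted
    in lexicographic order so output is deterministic.
    """
    lines = ["digraph bn {"]
    for v in dag.nodes:
        role = dag.roles[v]
        lines.append(
            f'  "{v}" [shape={_DOT_SHAPE[role]}, style=filled, '
            f'fillcolor={_DOT_FILL[role]}];'
        )
    for u, v in dag.edges:
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_adjacency(dag: Dag, path) -> None:
    """Write the edge list as a two-column ``parent\\tchild`` TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("parent\tchild\n")
        for u, v in dag.edges:
            fh.write(f"{u}\t{v}\n")


def read_adjacency(path, roles: Mapping[str, str]) -> Dag:
    """Rebuild a Dag from an adjacency TSV plus an external role map."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["parent", "child"]:
            raise ValueError(f"unexpected adjacency header {header!r} in {path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, v = line.split("\t")
            edges.append((u, v))
    return Dag(roles, edges)
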