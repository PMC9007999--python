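"""Directed/partially-directed graph structures and prior-knowledge constraints.

Nodes are cell-level features (cell prevalences, state metrics, sample
attributes, an oncogene expression feature); directed arcs represent inferred
causal influence.  Prior biological knowledge enters through node *roles*:

* ``root`` — no in-arcs (e.g. a "Cancer" tissue attribute: oncogenesis causes
  everything downstream, nothing in the table causes it);
* ``leaf`` — no out-arcs (e.g. CD8 T cells as a therapeutic endpoint, or
  heavily zero-inflated features whose out-going arcs would be spurious);
* ``quasi_root`` — in-arcs only from an explicit allowed-parent set (the
  oncogene: child of the cancer attribute, potential root to everything else);
* ``free`` — unconstrained.

Roles compile to a deterministic arc blacklist consumed by structure learning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Graph",
    "NodeRoleMap",
    "ConstraintLists",
    "build_blacklist",
    "cycle_check",
    "to_cpdag",
]

Arc = tuple[str, str]


class Graph:
    """A graph with directed arcs and optionally undirected edges.

    Undirected edges appear in CPDAGs and in the output of local-discovery
    algorithms that identify adjacency without orientation.  An unordered
    pair may be represented either as a directed arc (one direction) or as an
    undirected edge, never both.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        arcs: Iterable[Arc] = (),
        undirected: Iterable[Iterable[str]] = (),
    ) -> None:
        self.nodes: tuple[str, ...] = tuple(dict.fromkeys(nodes))
        self._node_set = set(self.nodes)
        self.arcs: set[Arc] = set()
        self.undirected: set[frozenset[str]] = set()
        for a, b in arcs:
            self.add_arc(a, b)
        for pair in undirected:
            self.add_undirected(*pair)

    # -- construction -----------------------------------------------------
    def _check_pair(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on node {a!r} is not allowed")
        missing = {a, b} - self._node_set
        if missing:
            raise KeyError(f"unknown node(s): {sorted(missing)}")

    def add_arc(self, a: str, b: str) -> None:
        self._check_pair(a, b)
        if frozenset((a, b)) in self.undirected:
            raise ValueError(f"pair {{{a},{b}}} already present as undirected edge")
        if (b, a) in self.arcs:
            raise ValueError(f"arc {b}->{a} already present; remove it first")
        self.arcs.add((a, b))

    def add_undirected(self, a: str, b: str) -> None:
        self._check_pair(a, b)
        if (a, b) in self.arcs or (b, a) in self.arcs:
            raise ValueError(f"pair {{{a},{b}}} already present as directed arc")
        self.undirected.add(frozenset((a, b)))

    def remove_arc(self, a: str, b: str) -> None:
        self.arcs.discard((a, b))

    def copy(self) -> "Graph":
        return Graph(self.nodes, self.arcs, self.undirected)

    # -- queries ----------------------------------------------------------
    def parents(self, node: str) -> set[str]:
        return {a for a, b in self.arcs if b == node}

    def children(self, node: str) -> set[str]:
        return {b for a, b in self.arcs if a == node}

    def neighbours(self, node: str) -> set[str]:
        out = self.parents(node) | self.children(node)
        for pair in self.undirected:
            if node in pair:
                out |= set(pair) - {node}
        return out

    def adjacent(self, a: str, b: str) -> bool:
        return (
            (a, b) in self.arcs
            or (b, a) in self.arcs
            or frozenset((a, b)) in self.undirected
        )

    def has_directed_path(self, src: str, dst: str) -> bool:
        """True iff a directed path src -> ... -> dst exists (length >= 0)."""
        if src == dst:
            return True
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.arcs:
            children[a].append(b)
        stack, seen = [src], {src}
        while stack:
            for c in children[stack.pop()]:
                if c == dst:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def is_acyclic(self) -> bool:
        try:
            self.topological_order()
            return True
        except ValueError:
            return False

    def topological_order(self) -> list[str]:
        """Topological order of the directed part (undirected edges ignored)."""
        indeg = {n: 0 for n in self.nodes}
        for _, b in self.arcs:
            indeg[b] += 1
        frontier = sorted(n for n, d in indeg.items() if d == 0)
        order: list[str] = []
        while frontier:
            n = frontier.pop(0)
            order.append(n)
            for c in sorted(self.children(n)):
                indeg[c] -= 1
                if indeg[c] == 0:
                    frontier.append(c)
            frontier.sort()
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a directed cycle")
        return order

    def sorted_arcs(self) -> list[Arc]:
        return sorted(self.arcs)

    def sorted_undirected(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self.undirected)

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(a) for a in self.arcs} | set(self.undirected)

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Unshielded colliders (a, c, b) with a->c<-b, a,b non-adjacent; a<b."""
        out = set()
        for c in self.nodes:
            ps = sorted(self.parents(c))
            for a, b in itertools.combinations(ps, 2):
                if not self.adjacent(a, b):
                    out.add((a, c, b))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.arcs == other.arcs
            and self.undirected == other.undirected
        )

    def __repr__(self) -> str:
        return (
            f"Graph(nodes={len(self.nodes)}, arcs={len(self.arcs)}, "
            f"undirected={len(self.undirected)})"
        )


def cycle_check(graph: Graph, candidate_arc: Arc) -> bool:
    """Would adding ``candidate_arc`` create a directed cycle?

    True iff a directed path child -> parent already exists, or the arc is a
    self-loop.
    """
    a, b = candidate_arc
    if a == b:
        return True
    if a not in graph._node_set or b not in graph._node_set:
        raise KeyError(f"candidate arc endpoints {candidate_arc} not all in graph")
    return graph.has_directed_path(b, a)


@dataclass(frozen=True)
class NodeRoleMap:
    """Role assignment used to compile the prior-knowledge blacklist."""

    roots: frozenset[str] = frozenset()
    leaves: frozenset[str] = frozenset()
    quasi_roots: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        qr = {n: frozenset(ps) for n, ps in dict(self.quasi_roots).items()}
        object.__setattr__(self, "roots", frozenset(self.roots))
        object.__setattr__(self, "leaves", frozenset(self.leaves))
        object.__setattr__(self, "quasi_roots", qr)
        groups = [self.roots, self.leaves, set(qr)]
        for g1, g2 in itertools.combinations(groups, 2):
            overlap = set(g1) & set(g2)
            if overlap:
                raise ValueError(f"nodes with more than one role: {sorted(overlap)}")
        for n, ps in qr.items():
            if not ps:
                raise ValueError(f"quasi_root {n!r} needs a nonempty allowed-parent set")

    @classmethod
    def from_dict(cls, spec: Mapping) -> "NodeRoleMap":
        """Build from a config block ``{roles: {node: role}, quasi_root: {node: [..]}}``.

        Also accepts a flat mapping ``{node: "root"|"leaf"|"free"}`` plus an
        optional ``quasi_root`` key.
        """
        roles = dict(spec.get("roles", {k: v for k, v in spec.items() if k != "quasi_root"}))
        qr = {n: frozenset(ps) for n, ps in dict(spec.get("quasi_root", {})).items()}
        roots, leaves = set(), set()
        for node, role in roles.items():
            if role == "root":
                roots.add(node)
            elif role == "leaf":
                leaves.add(node)
            elif role != "free":
                raise ValueError(f"unknown role {role!r} for node {node!r}")
        return cls(frozenset(roots), frozenset(leaves), qr)

    def all_nodes(self) -> set[str]:
        return set(self.roots) | set(self.leaves) | set(self.quasi_roots)


def build_blacklist(nodes: Iterable[str], roles: NodeRoleMap) -> list[Arc]:
    """Compile node roles into a deterministic, deduplicated arc blacklist.

    Rules: every in-arc of a root, every out-arc of a leaf, and every in-arc
    of a quasi-root from outside its allowed-parent set is forbidden.
    """
    nodes = list(dict.fromkeys(nodes))
    node_set = set(nodes)
    unknown = roles.all_nodes() - node_set
    if unknown:
        raise KeyError(f"roles reference unknown node(s): {sorted(unknown)}")
    bl: set[Arc] = set()
    for r in roles.roots:
        bl.update((x, r) for x in nodes if x != r)
    for leaf in roles.leaves:
        bl.update((leaf, x) for x in nodes if x != leaf)
    for q, allowed in roles.quasi_roots.items():
        if not set(allowed) <= node_set:
            raise KeyError(
                f"allowed parents of quasi_root {q!r} not all in node set"
            )
        bl.update((x, q) for x in nodes if x != q and x not in allowed)
    return sorted(bl)


@dataclass(frozen=True)
class ConstraintLists:
    """Blacklist (forbidden) and whitelist (forced) arc sets.

    The two sets must be disjoint and the whitelist on its own acyclic; a
    cyclic whitelist could never be honoured by any DAG.
    """

    blacklist: frozenset[Arc] = frozenset()
    whitelist: frozenset[Arc] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "blacklist", frozenset(map(tuple, self.blacklist)))
        object.__setattr__(self, "whitelist", frozenset(map(tuple, self.whitelist)))
        clash = self.blacklist & self.whitelist
        if clash:
            raise ValueError(f"arcs both black- and whitelisted: {sorted(clash)}")
        nodes = sorted({n for arc in self.whitelist for n in arc})
        g = Graph(nodes)
        g.arcs.update(self.whitelist)  # bypass pair guards: 2-cycles are cycles
        if not g.is_acyclic():
            raise ValueError("whitelist is cyclic")

    def allows(self, arc: Arc) -> bool:
        return arc not in self.blacklist

    def with_whitelist(self, extra: Iterable[Arc]) -> "ConstraintLists":
        return ConstraintLists(self.blacklist, self.whitelist | set(map(tuple, extra)))


# ---------------------------------------------------------------------------
# CPDAG machinery


def _meek_closure(g: Graph) -> Graph:
    """Apply Meek's orientation-propagation rules R1-R4 until fixpoint.

    ``g`` is a partially directed graph; directed arcs are treated as
    background orientations that must be preserved.
    """
    changed = True
    while changed:
        changed = False
        for pair in sorted(g.undirected, key=sorted):
            x, y = sorted(pair)
            for a, b in ((x, y), (y, x)):
                if _meek_applies(g, a, b):
                    g.undirected.discard(pair)
                    g.arcs.add((a, b))
                    changed = True
                    break
            if changed:
                break
    return g


def _meek_applies(g: Graph, a: str, b: str) -> bool:
    """Should undirected a-b be oriented a->b under Meek R1-R4?"""
    # R1: c->a, c and b non-adjacent
    for c in g.parents(a):
        if not g.adjacent(c, b):
            return True
    # R2: directed path a->c->b (orienting b->a would create a cycle)
    for c in g.children(a):
        if (c, b) in g.arcs:
            return True
    # R3: a-c, a-d with c->b, d->b and c,d non-adjacent
    und_nb = {next(iter(p - {a})) for p in g.undirected if a in p}
    parents_b = g.parents(b)
    cands = sorted(und_nb & parents_b)
    for c, d in itertools.combinations(cands, 2):
        if not g.adjacent(c, d):
            return True
    # R4: a-d, d->c, c->b with b,d non-adjacent and a,c adjacent
    for d in und_nb:
        if g.adjacent(d, b):
            continue
        for c in g.children(d):
            if (c, b) in g.arcs and g.adjacent(a, c):
                return True
    return False


def to_cpdag(dag: Graph) -> Graph:
    """Completed partially directed graph of ``dag``'s Markov equivalence class.

    Compelled arcs (those shared by every DAG with the same skeleton and
    unshielded colliders) stay directed; reversible arcs become undirected.
    Computed by keeping v-structure arcs directed, undirecting everything
    else, and closing under Meek's rules.
    """
    if dag.undirected:
        raise ValueError("to_cpdag expects a fully directed graph")
    if not dag.is_acyclic():
        raise ValueError("to_cpdag expects an acyclic graph")
    vstruct_arcs = set()
    for a, c, b in dag.v_structures():
        vstruct_arcs.add((a, c))
        vstruct_arcs.add((b, c))
    out = Graph(dag.nodes)
    for a, b in dag.arcs:
        if (a, b) in vstruct_arcs:
            out.arcs.add((a, b))
        else:
            out.undirected.add(frozenset((a, b)))
    return _meek_closure(out)


def orient_pdag(pdag: Graph, prefer: Mapping[Arc, float] | None = None) -> Graph:
    """Extend a PDAG to a fully directed DAG (best-effort consistent extension).

    Undirected edges are oriented one at a time: pick an orientation that does
    not create a cycle or a new v-structure where possible, then re-close
    under Meek's rules.  Used to hand a concrete DAG to parameter fitting.
    """
    g = pdag.copy()
    _meek_closure(g)
    while g.undirected:
        pair = min(g.undirected, key=sorted)
        x, y = sorted(pair)
        g.undirected.discard(pair)
        oriented = False
        for a, b in ((x, y), (y, x)):
            if not cycle_check(g, (a, b)):
                g.arcs.add((a, b))
                oriented = True
                break
        if not oriented:  # pragma: no cover - cannot happen on consistent input
            raise ValueError(f"cannot orient edge {{{x},{y}}} without a cycle")
        _meek_closure(g)
    return g
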