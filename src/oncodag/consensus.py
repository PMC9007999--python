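"""Consensus seeding: aggregate the algorithm ensemble into a whitelist.

The averaged networks of the ensemble are collapsed into an *edge evidence*
table (how many algorithms detected each edge, whether the detected
orientations agree, and the extreme arc-significance p-values across the
detecting networks).  Sweeping a significance threshold over the
direction-consistent arcs yields candidate whitelists of growing size; each
candidate is scored per node with the L1-BIC, and the final consensus seed is
assembled from each node's minimum-BIC parent set, admitting arcs in order of
evidence and skipping any that would close a directed cycle.  The final
network is then learned with a hybrid algorithm under both blacklist and
consensus whitelist, with bootstrap averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graphs import Arc, ConstraintLists, Graph, cycle_check
from .stats import _as_frame, arc_significance, node_l1_bic, partial_correlation, exact_t_pvalue
from .structure import (
    BootStrengthTable,
    LearnConfig,
    averaged_network,
    bootstrap_arc_strengths,
    learn_structure,
)

__all__ = [
    "EdgeEvidence",
    "EdgeEvidenceTable",
    "BicSweepTable",
    "aggregate_ensemble",
    "sweep_whitelist",
    "select_consensus_seed",
    "final_learning",
    "classify_edges",
    "default_threshold_grid",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("directed_seeded", "undirected_seeded", "undirected_only", "excluded")


@dataclass
class EdgeEvidence:
    """Ensemble evidence for one unordered edge."""

    a: str
    b: str
    n_algorithms: int
    direction_consistent: bool
    orientation: Arc | None
    min_p: float
    max_p: float
    category: str | None = None

    def __post_init__(self) -> None:
        if self.n_algorithms < 1:
            raise ValueError("a listed edge needs at least one detection")
        if self.min_p > self.max_p:
            raise ValueError("min_p > max_p")


class EdgeEvidenceTable:
    """Container of :class:`EdgeEvidence` rows keyed by unordered pair."""

    def __init__(self, records: Iterable[EdgeEvidence]) -> None:
        self.records = sorted(records, key=lambda r: (r.a, r.b))
        self._by_pair = {frozenset((r.a, r.b)): r for r in self.records}
        if len(self._by_pair) != len(self.records):
            raise ValueError("duplicate edges in evidence table")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, a: str, b: str) -> EdgeEvidence | None:
        return self._by_pair.get(frozenset((a, b)))

    def consistent_arcs(self) -> dict[Arc, float]:
        """Direction-consistent oriented arcs with their gating p-values."""
        return {
            r.orientation: r.min_p
            for r in self.records
            if r.direction_consistent and r.orientation is not None
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "a": r.a,
                    "b": r.b,
                    "n_algorithms": r.n_algorithms,
                    "direction_consistent": r.direction_consistent,
                    "orientation": "->".join(r.orientation) if r.orientation else "",
                    "min_p": r.min_p,
                    "max_p": r.max_p,
                    "category": r.category or "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "a", "b", "n_algorithms", "direction_consistent",
                "orientation", "min_p", "max_p", "category",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def _edge_pvalue(g: Graph, a: str, b: str, frame: pd.DataFrame) -> float:
    """Arc-significance p-value of edge {a, b} within averaged network ``g``.

    Directed arcs condition on the child's other parents.  Undirected edges
    have no designated child; the conditioning set is the union of the
    directed parents of both endpoints (minus the pair itself).
    """
    if (a, b) in g.arcs:
        return arc_significance(g, (a, b), frame).p_value
    if (b, a) in g.arcs:
        return arc_significance(g, (b, a), frame).p_value
    Z = sorted((g.parents(a) | g.parents(b)) - {a, b})
    max_cond = max(len(frame) - 3, 0)
    Z = Z[:max_cond]
    r = partial_correlation(frame, a, b, Z)
    return exact_t_pvalue(r, len(frame), len(Z))


def aggregate_ensemble(
    averaged_networks: Mapping[str, Graph] | Sequence[Graph],
    data,
) -> EdgeEvidenceTable:
    """Collapse the ensemble's averaged networks into edge-level evidence.

    Detection counts include undirected adjacencies (local-discovery output
    counts as detection without a direction vote).  An edge is
    direction-consistent when at least one network orients it and all
    orienting networks agree.
    """
    if isinstance(averaged_networks, Mapping):
        networks = list(averaged_networks.values())
    else:
        networks = list(averaged_networks)
    if not networks:
        raise ValueError("need at least one averaged network")
    node_set = set(networks[0].nodes)
    for g in networks[1:]:
        if set(g.nodes) != node_set:
            raise ValueError("averaged networks do not share a node set")
    frame = _as_frame(data)
    records = []
    all_pairs = set()
    for g in networks:
        all_pairs |= g.skeleton()
    for pair in sorted(all_pairs, key=sorted):
        a, b = sorted(pair)
        n_det = 0
        votes: set[Arc] = set()
        pvals = []
        for g in networks:
            if not g.adjacent(a, b):
                continue
            n_det += 1
            if (a, b) in g.arcs:
                votes.add((a, b))
            elif (b, a) in g.arcs:
                votes.add((b, a))
            pvals.append(_edge_pvalue(g, a, b, frame))
        consistent = len(votes) == 1
        records.append(
            EdgeEvidence(
                a,
                b,
                n_det,
                consistent,
                next(iter(votes)) if consistent else None,
                min(pvals),
                max(pvals),
            )
        )
    return EdgeEvidenceTable(records)


def default_threshold_grid(n_points: int = 10) -> np.ndarray:
    """Log-spaced significance thresholds from 1e-20 to 1e-2."""
    return np.logspace(-20, -2, n_points)


@dataclass
class BicSweepTable:
    """Per-(node, threshold) L1-BIC values across candidate whitelists."""

    frame: pd.DataFrame  # columns: node, threshold, n_arcs, bic
    parent_sets: dict[tuple[str, float], tuple[str, ...]]
    arc_pvalues: dict[Arc, float]
    thresholds: tuple[float, ...]

    def min_bic_row(self, node: str) -> pd.Series:
        """Minimum-BIC row for a node; ties prefer fewer arcs, then the
        smaller threshold (parsimony first)."""
        sub = self.frame[self.frame["node"] == node]
        if sub.empty:
            raise KeyError(f"node {node!r} not in sweep")
        sub = sub.sort_values(["bic", "n_arcs", "threshold"], kind="stable")
        return sub.iloc[0]

    def min_bic_parents(self, node: str) -> tuple[str, ...]:
        row = self.min_bic_row(node)
        return self.parent_sets[(node, float(row["threshold"]))]

    def nodes(self) -> list[str]:
        return sorted(self.frame["node"].unique())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")


def _acyclic_whitelist(arcs: Mapping[Arc, float], nodes: Sequence[str]) -> list[Arc]:
    """Admit arcs in ascending p-value order, skipping cycle-forming ones."""
    g = Graph(nodes)
    admitted: list[Arc] = []
    for arc in sorted(arcs, key=lambda a: (arcs[a], a)):
        if cycle_check(g, arc):
            logger.info("whitelist candidate %s->%s skipped (cycle)", *arc)
            continue
        g.add_arc(*arc)
        admitted.append(arc)
    return sorted(admitted)


def sweep_whitelist(
    evidence: EdgeEvidenceTable,
    data,
    constraints: ConstraintLists | None = None,
    threshold_grid: Sequence[float] | None = None,
    p_selector: str = "min_p",
    learn_cfg: LearnConfig | None = None,
) -> BicSweepTable:
    """Sweep significance thresholds over candidate whitelists (node BIC table).

    At each threshold ``t`` the candidate whitelist contains the
    direction-consistent evidence arcs whose gating p-value (``min_p`` by
    default, the edge's best evidence) is <= t, minus blacklisted arcs and
    minus any arc whose admission would make the whitelist itself cyclic.
    A DAG is learned under that whitelist with the final-learning algorithm
    (a single run) and each node's L1-BIC given its learned parents is
    recorded.
    """
    if p_selector not in ("min_p", "max_p"):
        raise ValueError("p_selector must be 'min_p' or 'max_p'")
    constraints = constraints or ConstraintLists()
    learn_cfg = learn_cfg or LearnConfig(algorithm="mmhc")
    frame = _as_frame(data)
    nodes = list(frame.columns)
    grid = np.asarray(
        default_threshold_grid() if threshold_grid is None else threshold_grid,
        dtype=float,
    )
    if np.any(grid <= 0) or np.any(np.diff(grid) < 0):
        raise ValueError("threshold grid must be positive and ascending")

    arc_p: dict[Arc, float] = {}
    for r in evidence:
        if r.direction_consistent and r.orientation is not None:
            p = r.min_p if p_selector == "min_p" else r.max_p
            if r.orientation not in constraints.blacklist:
                arc_p[r.orientation] = p

    rows = []
    parent_sets: dict[tuple[str, float], tuple[str, ...]] = {}
    for t in grid:
        candidates = {arc: p for arc, p in arc_p.items() if p <= t}
        wl = _acyclic_whitelist(candidates, nodes)
        cons_t = ConstraintLists(constraints.blacklist, frozenset(wl) | constraints.whitelist)
        dag = learn_structure(frame, learn_cfg, cons_t)
        for node in nodes:
            parents = tuple(sorted(dag.parents(node)))
            rec = node_l1_bic(node, parents, frame)
            rows.append(
                {
                    "node": node,
                    "threshold": float(t),
                    "n_arcs": rec.n_arcs,
                    "bic": rec.bic,
                }
            )
            # only ensemble-corroborated arcs are eligible for the seed:
            # the recorded parent set is the learned in-arcs restricted to
            # direction-consistent evidence arcs at this threshold
            parent_sets[(node, float(t))] = tuple(
                p for p in parents if (p, node) in candidates
            )
    table = pd.DataFrame(rows, columns=["node", "threshold", "n_arcs", "bic"])
    return BicSweepTable(table, parent_sets, arc_p, tuple(float(t) for t in grid))


def select_consensus_seed(sweep: BicSweepTable) -> list[Arc]:
    """Assemble the consensus seed whitelist from node-level minimum BICs.

    Each node contributes the parent set at its minimum BIC (ties prefer
    fewer arcs, then the lower threshold).  The union is admitted greedily in
    ascending evidence p-value; arcs that would close a directed cycle are
    skipped (and logged).  The result is acyclic by construction.
    """
    if sweep.frame.empty:
        raise ValueError("empty sweep table")
    union: dict[Arc, float] = {}
    for node in sweep.nodes():
        for parent in sweep.min_bic_parents(node):
            arc = (parent, node)
            union[arc] = sweep.arc_pvalues.get(arc, 1.0)
    nodes = sorted({n for arc in union for n in arc} | set(sweep.nodes()))
    return _acyclic_whitelist(union, nodes)


def final_learning(
    data,
    constraints_with_seed: ConstraintLists,
    n_boot: int = 10_000,
    seed: int | None = None,
    learn_cfg: LearnConfig | None = None,
) -> tuple[BootStrengthTable, Graph]:
    """Final constrained learning: hybrid algorithm + bootstrap averaging.

    Runs the hybrid learner (``mmhc`` by default) under the blacklist and the
    consensus-seed whitelist over ``n_boot`` bootstrap resamples, and returns
    the strength table together with the averaged network.  Whitelisted arcs
    have strength 1 by construction; blacklisted arcs never appear.
    """
    learn_cfg = learn_cfg or LearnConfig(algorithm="mmhc")
    frame = _as_frame(data)
    strengths = bootstrap_arc_strengths(
        frame, learn_cfg, constraints_with_seed, n_boot=n_boot, seed=seed
    )
    avg = averaged_network(strengths, nodes=list(frame.columns))
    return strengths, avg


def classify_edges(
    evidence: EdgeEvidenceTable,
    seed_whitelist: Iterable[Arc],
    max_threshold: float = 1e-2,
) -> EdgeEvidenceTable:
    """Categorize evidence edges the way the consensus summary colours them.

    ``directed_seeded``: direction-consistent and in the consensus seed;
    ``undirected_seeded``: in the seed but with conflicting orientations;
    ``undirected_only``: significantly enriched yet direction-inconsistent;
    ``excluded``: everything else.
    """
    seed_pairs = {frozenset(arc) for arc in seed_whitelist}
    for r in evidence:
        pair = frozenset((r.a, r.b))
        if pair in seed_pairs:
            r.category = "directed_seeded" if r.direction_consistent else "undirected_seeded"
        elif not r.direction_consistent and r.min_p <= max_threshold:
            r.category = "undirected_only"
        else:
            r.category = "excluded"
    return evidence
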