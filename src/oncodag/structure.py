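"""Structure learning: ten algorithms, bootstrap arc strengths, model averaging.

The ensemble comprises score-based search (hill climbing ``hc``, Tabu search
``tabu``), constraint-based learners (``pc_stable``, ``gs``, ``iamb``,
``iamb_fdr``), local discovery of undirected parent-children sets (``mmpc``,
``si_hiton_pc``) and hybrid restrict-then-maximize learners (``mmhc``,
``rsmax2``).  All honour an arc blacklist (never present) and whitelist
(always present).

Arc strength is estimated by bootstrap resampling: the data are resampled
with replacement at the original size, a network is learned per resample, and
the inclusion frequency of each edge (and the frequency of each orientation)
is tabulated.  An automatic inclusion threshold on these frequencies picks
the averaged network: the threshold minimizing the L1 distance between the
empirical strength CDF and an ideal CDF in which every arc has strength 0 or
1 (the Scutari-Nagarajan significance-threshold construction, nominally 0.5).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graphs import Arc, ConstraintLists, Graph, cycle_check, _meek_closure
from .stats import CITester, DiscreteCITester, GaussianScorer, _as_frame

__all__ = [
    "ALGORITHMS",
    "LearnConfig",
    "BootStrengthTable",
    "learn_structure",
    "bootstrap_arc_strengths",
    "optimal_inclusion_threshold",
    "averaged_network",
]

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "hc",
    "tabu",
    "pc_stable",
    "gs",
    "iamb",
    "iamb_fdr",
    "mmpc",
    "si_hiton_pc",
    "mmhc",
    "rsmax2",
)

#: algorithms whose output carries no orientation votes
UNDIRECTED_ALGORITHMS = ("mmpc", "si_hiton_pc")

_EPS = 1e-12
_IMPROVE_TOL = 1e-8  # minimum score gain counted as an improvement


@dataclass(frozen=True)
class LearnConfig:
    """Settings for a single structure-learning run."""

    algorithm: str = "hc"
    alpha: float = 0.05
    max_parents: int | None = None
    tabu_length: int = 10
    tabu_noimprove: int = 15
    restarts: int = 0
    perturb: int = 5
    max_sepset: int | None = None
    ci_test: str = "pearson"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.ci_test not in ("pearson", "mi"):
            raise ValueError("ci_test must be 'pearson' or 'mi'")


# ---------------------------------------------------------------------------
# constraint helpers


def _prep_constraints(nodes: Sequence[str], constraints: ConstraintLists | None):
    constraints = constraints or ConstraintLists()
    node_set = set(nodes)
    for a, b in constraints.blacklist | constraints.whitelist:
        if a not in node_set or b not in node_set:
            raise KeyError(f"constraint arc ({a}, {b}) references unknown node")
    bl = set(constraints.blacklist)
    wl = set(constraints.whitelist)
    blocked_pairs = {
        frozenset((a, b)) for a, b in bl if (b, a) in bl
    }
    wl_pairs = {frozenset(arc) for arc in wl}
    return bl, wl, blocked_pairs, wl_pairs


# ---------------------------------------------------------------------------
# score-based search


def _greedy_search(
    scorer: GaussianScorer,
    nodes: Sequence[str],
    bl: set[Arc],
    wl: set[Arc],
    max_parents: int | None,
    restrict_pairs: set[frozenset] | None = None,
    tabu_length: int = 0,
    tabu_noimprove: int = 0,
    start_arcs: Iterable[Arc] = (),
    rng: np.random.Generator | None = None,
) -> Graph:
    """Greedy add/delete/reverse ascent on the decomposable Gaussian BIC.

    With ``tabu_length`` > 0 the search keeps a memory of recently visited
    structures and accepts the best non-improving admissible move for up to
    ``tabu_noimprove`` iterations, returning the best structure seen.

    Ties between moves — in particular the two orientations of a reversible
    arc, which have identical score by score equivalence — are broken by
    ``rng`` when given (essential under bootstrap model averaging, so that
    reversible orientations wash out to ~0.5 direction frequency instead of
    following a fixed enumeration bias), else by enumeration order.
    """
    g = Graph(nodes)
    for a, b in sorted(wl):
        g.add_arc(a, b)
    for a, b in sorted(set(start_arcs) - set(g.arcs)):
        if (a, b) not in bl and not cycle_check(g, (a, b)):
            g.add_arc(a, b)

    def ls(n: str, ps: Iterable[str]) -> float:
        return scorer.local_score(n, ps)

    def allowed_pair(a: str, b: str) -> bool:
        return restrict_pairs is None or frozenset((a, b)) in restrict_pairs

    tabu: deque = deque(maxlen=max(tabu_length, 1))
    tabu_set: set[frozenset] = set()

    def remember(arcs: set[Arc]) -> None:
        key = frozenset(arcs)
        if len(tabu) == tabu.maxlen:
            tabu_set.discard(tabu[0])
        tabu.append(key)
        tabu_set.add(key)

    remember(g.arcs)
    best_arcs, best_score = set(g.arcs), scorer.network_score(g)
    noimprove = 0
    # hard cap: plateaus in the tabu phase must terminate
    max_iter = 50 * max(len(nodes) ** 2, 1)
    tie_tol = 1e-9

    for _ in range(max_iter):
        best_move, best_delta = None, -np.inf
        tied_moves: list[tuple] = []

        def consider(move, delta) -> None:
            nonlocal best_move, best_delta, tied_moves
            if delta > best_delta + tie_tol:
                best_move, best_delta = move, delta
                tied_moves = [move]
            elif rng is not None and delta > best_delta - tie_tol:
                tied_moves.append(move)

        for b in g.nodes:
            pb = g.parents(b)
            base_b = ls(b, pb)
            # additions
            if max_parents is None or len(pb) < max_parents:
                for a in g.nodes:
                    if (
                        a == b
                        or (a, b) in g.arcs
                        or (b, a) in g.arcs
                        or (a, b) in bl
                        or not allowed_pair(a, b)
                    ):
                        continue
                    if cycle_check(g, (a, b)):
                        continue
                    delta = ls(b, pb | {a}) - base_b
                    if _admissible(g.arcs, ("add", a, b), tabu_set, tabu_length):
                        consider(("add", a, b), delta)
            # deletions and reversals
            for a in sorted(pb):
                if (a, b) not in wl:
                    delta = ls(b, pb - {a}) - base_b
                    if _admissible(g.arcs, ("del", a, b), tabu_set, tabu_length):
                        consider(("del", a, b), delta)
                    if (b, a) not in bl:
                        pa = g.parents(a)
                        if max_parents is None or len(pa) < max_parents:
                            g.arcs.discard((a, b))
                            makes_cycle = cycle_check(g, (b, a))
                            g.arcs.add((a, b))
                            if not makes_cycle:
                                delta = (
                                    ls(b, pb - {a})
                                    - base_b
                                    + ls(a, pa | {b})
                                    - ls(a, pa)
                                )
                                if _admissible(
                                    g.arcs, ("rev", a, b), tabu_set, tabu_length
                                ):
                                    consider(("rev", a, b), delta)
        if best_move is None:
            break
        if rng is not None and len(tied_moves) > 1:
            best_move = tied_moves[rng.integers(len(tied_moves))]
        if tabu_length == 0 and best_delta <= _IMPROVE_TOL:
            break
        _apply_move(g, best_move)
        # recompute from cached local scores: avoids float drift on plateaus
        current_score = scorer.network_score(g)
        remember(g.arcs)
        if current_score > best_score + _IMPROVE_TOL:
            best_score, best_arcs = current_score, set(g.arcs)
            noimprove = 0
        else:
            noimprove += 1
            if tabu_length == 0 or noimprove > tabu_noimprove:
                break
    return Graph(nodes, best_arcs)


def _admissible(
    arcs: set[Arc], move: tuple, tabu_set: set[frozenset], tabu_length: int
) -> bool:
    if tabu_length == 0:
        return True
    kind, a, b = move
    nxt = set(arcs)
    if kind == "add":
        nxt.add((a, b))
    elif kind == "del":
        nxt.discard((a, b))
    else:
        nxt.discard((a, b))
        nxt.add((b, a))
    return frozenset(nxt) not in tabu_set


def _apply_move(g: Graph, move: tuple) -> None:
    kind, a, b = move
    if kind == "add":
        g.arcs.add((a, b))
    elif kind == "del":
        g.arcs.discard((a, b))
    else:
        g.arcs.discard((a, b))
        g.arcs.add((b, a))


# ---------------------------------------------------------------------------
# constraint-based learners


def _subsets(pool: Sequence[str], max_size: int):
    for size in range(min(len(pool), max_size) + 1):
        yield from itertools.combinations(pool, size)


def _pc_stable_skeleton(
    tester: CITester,
    nodes: Sequence[str],
    alpha: float,
    blocked_pairs: set[frozenset],
    wl_pairs: set[frozenset],
    max_sepset: int | None,
):
    adj: dict[str, set[str]] = {
        x: {
            y
            for y in nodes
            if y != x and frozenset((x, y)) not in blocked_pairs
        }
        for x in nodes
    }
    sepset: dict[frozenset, tuple[str, ...]] = {}
    cap = tester.max_cond_size() if max_sepset is None else min(max_sepset, tester.max_cond_size())
    level = 0
    while True:
        frozen = {x: sorted(adj[x]) for x in nodes}
        if level > cap or all(len(frozen[x]) - 1 < level for x in nodes):
            break
        for x in sorted(nodes):
            for y in frozen[x]:
                if y not in adj[x] or frozenset((x, y)) in wl_pairs:
                    continue
                pool = [z for z in frozen[x] if z != y]
                if len(pool) < level:
                    continue
                for Z in itertools.combinations(pool, level):
                    if tester.pvalue(x, y, Z) > alpha:
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepset[frozenset((x, y))] = Z
                        break
        level += 1
    return adj, sepset


def _orient_from_sepsets(
    nodes: Sequence[str],
    adj: Mapping[str, set[str]],
    sepset: Mapping[frozenset, tuple[str, ...]],
    bl: set[Arc],
    wl: set[Arc],
) -> Graph:
    """Skeleton + sepsets -> PDAG via background orientations, unshielded
    colliders, and Meek propagation.  Blacklisted directions are never
    produced; whitelisted arcs are always present and directed."""
    g = Graph(nodes)
    pairs = {frozenset((x, y)) for x in nodes for y in adj[x]}
    pairs |= {frozenset(arc) for arc in wl}
    for pair in sorted(pairs, key=sorted):
        x, y = sorted(pair)
        g.add_undirected(x, y)

    def direct(a: str, b: str) -> None:
        pair = frozenset((a, b))
        if pair in g.undirected:
            g.undirected.discard(pair)
            g.arcs.add((a, b))

    for a, b in sorted(wl):
        direct(a, b)
    for a, b in sorted(bl):
        if frozenset((a, b)) in g.undirected and (b, a) not in bl:
            direct(b, a)
    # unshielded colliders x -> z <- y where z not in sepset(x, y)
    for z in sorted(nodes):
        nbrs = sorted(g.neighbours(z))
        for x, y in itertools.combinations(nbrs, 2):
            if g.adjacent(x, y):
                continue
            sep = sepset.get(frozenset((x, y)))
            if sep is None or z in sep:
                continue
            for a in (x, y):
                if (z, a) not in g.arcs and (a, z) not in bl:
                    direct(a, z)
    return _meek_closure(g)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * m / (rank + 1))
        adj[i] = running
    return adj


def _markov_blanket(
    tester: CITester,
    target: str,
    nodes: Sequence[str],
    alpha: float,
    variant: str,
    blocked_pairs: set[frozenset],
    forced: set[str],
) -> set[str]:
    candidates = [
        x
        for x in sorted(nodes)
        if x != target and frozenset((x, target)) not in blocked_pairs
    ]
    mb: list[str] = sorted(forced)
    cap = tester.max_cond_size()

    def grow_step() -> bool:
        pool = [x for x in candidates if x not in mb]
        if not pool or len(mb) >= cap:
            return False
        if variant == "gs":
            for x in pool:
                if tester.pvalue(target, x, mb) <= alpha:
                    mb.append(x)
                    return True
            return False
        pvals = np.array([tester.pvalue(target, x, mb) for x in pool])
        if variant == "iamb_fdr":
            pvals = _bh_adjust(pvals)
        i = int(np.argmin(pvals))
        if pvals[i] <= alpha:
            mb.append(pool[i])
            return True
        return False

    while grow_step():
        pass
    # shrink
    changed = True
    while changed:
        changed = False
        removable = [x for x in mb if x not in forced]
        if not removable:
            break
        pvals = {
            x: tester.pvalue(target, x, [z for z in mb if z != x]) for x in removable
        }
        if variant == "iamb_fdr":
            keys = list(pvals)
            adj = _bh_adjust(np.array([pvals[k] for k in keys]))
            pvals = dict(zip(keys, adj))
        worst = max(sorted(pvals), key=lambda x: pvals[x])
        if pvals[worst] > alpha:
            mb.remove(worst)
            changed = True
    return set(mb)


def _mb_based_learn(
    tester: CITester,
    nodes: Sequence[str],
    alpha: float,
    variant: str,
    bl: set[Arc],
    wl: set[Arc],
    blocked_pairs: set[frozenset],
    wl_pairs: set[frozenset],
    max_sepset: int | None,
) -> Graph:
    forced = {n: {next(iter(p - {n})) for p in wl_pairs if n in p} for n in nodes}
    mbs = {
        t: _markov_blanket(tester, t, nodes, alpha, variant, blocked_pairs, forced[t])
        for t in sorted(nodes)
    }
    # symmetry correction (AND), keeping whitelist-forced members
    for x in nodes:
        mbs[x] = {y for y in mbs[x] if x in mbs[y] or y in forced[x]}
    adj: dict[str, set[str]] = {x: set() for x in nodes}
    sepset: dict[frozenset, tuple[str, ...]] = {}
    cap = tester.max_cond_size() if max_sepset is None else min(max_sepset, tester.max_cond_size())
    for x, y in itertools.combinations(sorted(nodes), 2):
        pair = frozenset((x, y))
        if pair in wl_pairs:
            adj[x].add(y)
            adj[y].add(x)
            continue
        if y not in mbs[x]:
            sepset[pair] = tuple(sorted(mbs[x] - {y}))
            continue
        base = min(
            (sorted(mbs[x] - {y}), sorted(mbs[y] - {x})), key=len
        )
        sep = None
        for Z in _subsets(base, cap):
            if tester.pvalue(x, y, Z) > alpha:
                sep = Z
                break
        if sep is None:
            adj[x].add(y)
            adj[y].add(x)
        else:
            sepset[pair] = sep
    return _orient_from_sepsets(nodes, adj, sepset, bl, wl)


# ---------------------------------------------------------------------------
# local discovery (parents-and-children sets)


def _pc_set_mmpc(
    tester: CITester,
    target: str,
    nodes: Sequence[str],
    alpha: float,
    blocked_pairs: set[frozenset],
    forced: set[str],
    cap: int,
    sepset_out: dict,
):
    """Max-min parents-and-children of ``target`` (forward + backward phase)."""
    candidates = [
        x
        for x in sorted(nodes)
        if x != target and x not in forced and frozenset((x, target)) not in blocked_pairs
    ]
    cpc: list[str] = sorted(forced)
    subsets: list[tuple[str, ...]] = [
        tuple(s) for s in _subsets(cpc, min(len(cpc), cap))
    ]
    # max p-value over conditioning subsets seen so far, and its witness subset
    maxp: dict[str, float] = {}
    witness: dict[str, tuple[str, ...]] = {}
    for x in candidates:
        for Z in subsets:
            p = tester.pvalue(target, x, Z)
            if p > maxp.get(x, -1.0):
                maxp[x], witness[x] = p, Z
    while True:
        pool = [x for x in candidates if x not in cpc and maxp[x] <= alpha]
        if not pool:
            break
        new = min(pool, key=lambda x: (maxp[x], x))
        fresh = [
            tuple(sorted(set(Z) | {new}))
            for Z in subsets
            if len(Z) < cap
        ]
        cpc.append(new)
        subsets.extend(fresh)
        for x in candidates:
            # max-assoc p is monotone in the subset family: once a candidate
            # exceeds alpha it is excluded for good, no need to keep testing
            if x in cpc or maxp[x] > alpha:
                continue
            for Z in fresh:
                p = tester.pvalue(target, x, Z)
                if p > maxp[x]:
                    maxp[x], witness[x] = p, Z
                    if p > alpha:
                        break
    # backward: drop members separated by some subset of the rest
    changed = True
    while changed:
        changed = False
        for y in list(cpc):
            if y in forced:
                continue
            rest = [z for z in cpc if z != y]
            for Z in _subsets(rest, cap):
                if tester.pvalue(target, y, Z) > alpha:
                    cpc.remove(y)
                    sepset_out[frozenset((target, y))] = Z
                    changed = True
                    break
    for x in candidates:
        if x not in cpc:
            sepset_out.setdefault(frozenset((target, x)), witness.get(x, ()))
    return set(cpc)


def _pc_set_si_hiton(
    tester: CITester,
    target: str,
    nodes: Sequence[str],
    alpha: float,
    blocked_pairs: set[frozenset],
    forced: set[str],
    cap: int,
    sepset_out: dict,
):
    """Semi-interleaved HITON-PC of ``target``."""
    marg = {}
    for x in sorted(nodes):
        if x == target or x in forced or frozenset((x, target)) in blocked_pairs:
            continue
        marg[x] = tester.pvalue(target, x, ())
    order = sorted((x for x in marg if marg[x] <= alpha), key=lambda x: (marg[x], x))
    cpc: list[str] = sorted(forced)
    for x in order:
        cpc.append(x)
        for y in list(cpc):
            if y in forced:
                continue
            rest = [z for z in cpc if z != y]
            removed = False
            for Z in _subsets(rest, cap):
                if tester.pvalue(target, y, Z) > alpha:
                    cpc.remove(y)
                    sepset_out[frozenset((target, y))] = Z
                    removed = True
                    break
            if removed and y == x:
                break
    for x in marg:
        if x not in cpc:
            sepset_out.setdefault(frozenset((target, x)), ())
    return set(cpc)


def _local_discovery(
    tester: CITester,
    nodes: Sequence[str],
    alpha: float,
    method: str,
    bl: set[Arc],
    wl: set[Arc],
    blocked_pairs: set[frozenset],
    wl_pairs: set[frozenset],
    max_sepset: int | None,
):
    cap = tester.max_cond_size() if max_sepset is None else min(max_sepset, tester.max_cond_size())
    forced = {n: {next(iter(p - {n})) for p in wl_pairs if n in p} for n in nodes}
    fn = _pc_set_mmpc if method == "mmpc" else _pc_set_si_hiton
    sepset: dict[frozenset, tuple[str, ...]] = {}
    pc = {
        t: fn(tester, t, nodes, alpha, blocked_pairs, forced[t], cap, sepset)
        for t in sorted(nodes)
    }
    # AND symmetry correction
    adj = {
        x: {y for y in pc[x] if x in pc[y] or y in forced[x]} for x in nodes
    }
    return adj, sepset


def _undirected_graph(nodes: Sequence[str], adj: Mapping[str, set[str]], wl: set[Arc]) -> Graph:
    g = Graph(nodes)
    for a, b in sorted(wl):
        g.add_arc(a, b)
    for x, y in itertools.combinations(sorted(nodes), 2):
        if y in adj[x] and not g.adjacent(x, y):
            g.add_undirected(x, y)
    return g


# ---------------------------------------------------------------------------
# public API


def learn_structure(
    data,
    cfg: LearnConfig | None = None,
    constraints: ConstraintLists | None = None,
    rng: np.random.Generator | None = None,
) -> Graph:
    """Learn a network structure from a preprocessed feature table.

    Score-based and hybrid algorithms return a DAG; constraint-based
    algorithms may leave reversible edges undirected; the two local-discovery
    algorithms return an undirected adjacency graph (whitelist arcs excepted).
    """
    cfg = cfg or LearnConfig()
    frame = _as_frame(data)
    nodes = list(frame.columns)
    bl, wl, blocked_pairs, wl_pairs = _prep_constraints(nodes, constraints)
    alg = cfg.algorithm
    if rng is None and cfg.seed is not None:
        rng = np.random.default_rng(cfg.seed)

    if alg in ("hc", "tabu"):
        scorer = GaussianScorer(frame)
        tabu_len = cfg.tabu_length if alg == "tabu" else 0
        return _search_with_restarts(
            scorer, nodes, bl, wl, cfg, tabu_len, restrict_pairs=None, rng=rng
        )

    # the 'mi' variant runs the constraint-based learners on discretized codes
    tester = DiscreteCITester(frame) if cfg.ci_test == "mi" else CITester(frame)
    if alg == "pc_stable":
        adj, sepset = _pc_stable_skeleton(
            tester, nodes, cfg.alpha, blocked_pairs, wl_pairs, cfg.max_sepset
        )
        return _orient_from_sepsets(nodes, adj, sepset, bl, wl)
    if alg in ("gs", "iamb", "iamb_fdr"):
        return _mb_based_learn(
            tester, nodes, cfg.alpha, alg, bl, wl, blocked_pairs, wl_pairs, cfg.max_sepset
        )
    if alg in ("mmpc", "si_hiton_pc"):
        adj, _ = _local_discovery(
            tester, nodes, cfg.alpha, alg, bl, wl, blocked_pairs, wl_pairs, cfg.max_sepset
        )
        return _undirected_graph(nodes, adj, wl)
    if alg in ("mmhc", "rsmax2"):
        restrict = "mmpc" if alg == "mmhc" else "si_hiton_pc"
        adj, _ = _local_discovery(
            tester, nodes, cfg.alpha, restrict, bl, wl, blocked_pairs, wl_pairs, cfg.max_sepset
        )
        allowed = {
            frozenset((x, y)) for x in nodes for y in adj[x]
        } | wl_pairs
        scorer = GaussianScorer(frame)
        tabu_len = 0 if alg == "mmhc" else cfg.tabu_length
        return _search_with_restarts(
            scorer, nodes, bl, wl, cfg, tabu_len, restrict_pairs=allowed, rng=rng
        )
    raise AssertionError(f"unhandled algorithm {alg!r}")  # pragma: no cover


def _search_with_restarts(
    scorer: GaussianScorer,
    nodes: Sequence[str],
    bl: set[Arc],
    wl: set[Arc],
    cfg: LearnConfig,
    tabu_len: int,
    restrict_pairs: set[frozenset] | None,
    rng: np.random.Generator | None = None,
) -> Graph:
    """Greedy search plus iterated local search restarts.

    Each restart perturbs the incumbent optimum with a few random legal arc
    changes and re-climbs, keeping the better structure; this escapes the
    single-move local optima that plain greedy ascent from the empty graph
    is prone to.  Deterministic given the seed/generator.
    """
    kwargs = dict(
        max_parents=cfg.max_parents,
        restrict_pairs=restrict_pairs,
        tabu_length=tabu_len,
        tabu_noimprove=cfg.tabu_noimprove,
        rng=rng,
    )
    best = _greedy_search(scorer, nodes, bl, wl, **kwargs)
    if not cfg.restarts:
        return best
    best_score = scorer.network_score(best)
    if rng is None:
        rng = np.random.default_rng(cfg.seed if cfg.seed is not None else 0)
        kwargs["rng"] = None  # keep the climbs themselves deterministic
    for _ in range(cfg.restarts):
        start = _perturb(best, bl, wl, restrict_pairs, rng, n_changes=cfg.perturb)
        cand = _greedy_search(scorer, nodes, bl, wl, start_arcs=start, **kwargs)
        s = scorer.network_score(cand)
        if s > best_score + _IMPROVE_TOL:
            best, best_score = cand, s
    return best


def _perturb(
    g: Graph,
    bl: set[Arc],
    wl: set[Arc],
    restrict_pairs: set[frozenset] | None,
    rng: np.random.Generator,
    n_changes: int = 5,
) -> set[Arc]:
    """Apply random legal arc changes (add/delete/reverse) to a copy of ``g``."""
    h = g.copy()
    nodes = list(h.nodes)
    for _ in range(n_changes):
        kind = rng.integers(0, 3)
        arcs = sorted(h.arcs - wl)
        if kind == 0 or not arcs:
            i, j = rng.choice(len(nodes), 2, replace=False)
            a, b = nodes[i], nodes[j]
            if (
                (a, b) not in bl
                and not h.adjacent(a, b)
                and (restrict_pairs is None or frozenset((a, b)) in restrict_pairs)
                and not cycle_check(h, (a, b))
            ):
                h.arcs.add((a, b))
        else:
            a, b = arcs[rng.integers(len(arcs))]
            h.arcs.discard((a, b))
            if kind == 2 and (b, a) not in bl and not cycle_check(h, (b, a)):
                h.arcs.add((b, a))
    return set(h.arcs)


class BootStrengthTable:
    """Bootstrap edge-inclusion frequencies and orientation probabilities.

    For each unordered pair {a, b} ever observed: ``strength`` is the fraction
    of bootstrap networks containing the edge in either direction (undirected
    adjacency counts), and ``direction`` is the probability of the a -> b
    orientation among edge-containing networks (undirected occurrences vote
    half for each orientation), so direction(b, a) = 1 - direction(a, b).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        n_boot: int,
        algorithm: str,
        seed: int | None,
    ) -> None:
        required = {"from", "to", "strength", "direction"}
        if not required <= set(frame.columns):
            raise ValueError(f"strength table needs columns {sorted(required)}")
        self.frame = frame.reset_index(drop=True)
        self.n_boot = int(n_boot)
        self.algorithm = algorithm
        self.seed = seed
        self._by_pair = {
            frozenset((row["from"], row["to"])): (row["strength"], row["direction"])
            for _, row in self.frame.iterrows()
        }
        bad = self.frame[
            (self.frame["strength"] < 0)
            | (self.frame["strength"] > 1)
            | (self.frame["direction"] < 0)
            | (self.frame["direction"] > 1)
        ]
        if len(bad):
            raise ValueError("strength/direction outside [0, 1]")

    @classmethod
    def from_counts(
        cls,
        edge_counts: Mapping[frozenset, float],
        dir_counts: Mapping[Arc, float],
        n_boot: int,
        algorithm: str,
        seed: int | None,
    ) -> "BootStrengthTable":
        rows = []
        for pair in sorted(edge_counts, key=sorted):
            a, b = sorted(pair)
            count = edge_counts[pair]
            rows.append(
                {
                    "from": a,
                    "to": b,
                    "strength": count / n_boot,
                    "direction": (dir_counts.get((a, b), 0.0) / count) if count else 0.5,
                }
            )
        frame = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
        return cls(frame, n_boot, algorithm, seed)

    def strength(self, a: str, b: str) -> float:
        return self._by_pair.get(frozenset((a, b)), (0.0, 0.5))[0]

    def direction(self, a: str, b: str) -> float:
        pair = frozenset((a, b))
        if pair not in self._by_pair:
            return 0.5
        d = self._by_pair[pair][1]
        return d if a < b else 1.0 - d

    def strengths(self) -> np.ndarray:
        return self.frame["strength"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["algorithm"] = self.algorithm
        out["n_boot"] = self.n_boot
        out["seed"] = self.seed if self.seed is not None else ""
        out.to_csv(path, index=False, float_format="%.10g")

    def __len__(self) -> int:
        return len(self.frame)


def bootstrap_arc_strengths(
    data,
    cfg: LearnConfig | None = None,
    constraints: ConstraintLists | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> BootStrengthTable:
    """Bootstrap-resample the data and tabulate edge/orientation frequencies.

    Each resample draws ``n_obs`` rows with replacement; a network is learned
    per resample under the constraints.  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cfg = cfg or LearnConfig()
    frame = _as_frame(data)
    n = len(frame)
    rng = np.random.default_rng(seed)
    edge_counts: dict[frozenset, float] = {}
    dir_counts: dict[Arc, float] = {}
    values = frame.to_numpy(dtype=float)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        sub = pd.DataFrame(values[idx], columns=frame.columns)
        # independent tie-break stream per resample, all derived from `seed`
        g = learn_structure(
            sub, cfg, constraints,
            rng=np.random.default_rng(rng.integers(0, 2**31)),
        )
        for a, b in g.arcs:
            pair = frozenset((a, b))
            edge_counts[pair] = edge_counts.get(pair, 0.0) + 1.0
            lo = min(a, b)
            hi = max(a, b)
            if (a, b) == (lo, hi):
                dir_counts[(lo, hi)] = dir_counts.get((lo, hi), 0.0) + 1.0
        for pair in g.undirected:
            edge_counts[pair] = edge_counts.get(pair, 0.0) + 1.0
            lo, hi = sorted(pair)
            dir_counts[(lo, hi)] = dir_counts.get((lo, hi), 0.0) + 0.5
    return BootStrengthTable.from_counts(
        edge_counts, dir_counts, n_boot, cfg.algorithm, seed
    )


def optimal_inclusion_threshold(strengths: Sequence[float]) -> float:
    """Automatic inclusion threshold for model averaging.

    Picks the threshold minimizing the L1 distance between the empirical CDF
    of observed strengths and the ideal two-point CDF in which each arc has
    strength exactly 0 (absent) or 1 (present).  Candidate thresholds are the
    observed unique strengths (plus one just above the maximum, retaining
    nothing); ties break toward the larger threshold, i.e. the sparser
    network.  Arcs with strength >= the returned threshold are retained.
    """
    s = np.asarray(list(strengths), dtype=float)
    if s.size == 0:
        raise ValueError("empty strength vector")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("strengths must lie in [0, 1]")
    n = s.size
    uniq = np.unique(s)
    # piecewise-constant empirical CDF on [0, 1]
    breaks = np.unique(np.concatenate(([0.0], uniq, [1.0])))
    seg_lo = breaks[:-1]
    seg_len = np.diff(breaks)
    F = np.array([(s <= x).sum() / n for x in seg_lo])

    def l1(f: float) -> float:
        return float(np.sum(np.abs(F - f) * seg_len))

    candidates = list(uniq) + [float(np.nextafter(uniq[-1], 2.0))]
    best_t, best_val = None, np.inf
    for t in candidates:  # ascending; later (larger) wins ties
        val = l1((s < t).sum() / n)
        if val <= best_val + _EPS:
            best_t, best_val = t, min(val, best_val)
    return float(best_t)


def averaged_network(
    table: BootStrengthTable,
    threshold: float | None = None,
    nodes: Sequence[str] | None = None,
) -> Graph:
    """Model-averaged network from a bootstrap strength table.

    Edges at or above the inclusion threshold (automatic if not given) are
    kept; orientation follows the majority direction, with an exact 0.5 split
    left undirected.  If the directed part contains a cycle, the weakest arc
    in each cycle is dropped (with a warning) until the result is acyclic.
    """
    if threshold is None:
        if len(table) == 0:
            threshold = 1.0
        else:
            threshold = optimal_inclusion_threshold(table.strengths())
    node_set = set(nodes or ())
    for _, row in table.frame.iterrows():
        node_set.update((row["from"], row["to"]))
    g = Graph(sorted(node_set))
    kept = []
    for _, row in table.frame.iterrows():
        if row["strength"] < threshold:
            continue
        a, b = row["from"], row["to"]
        if row["direction"] > 0.5:
            g.add_arc(a, b)
            kept.append(((a, b), row["strength"]))
        elif row["direction"] < 0.5:
            g.add_arc(b, a)
            kept.append(((b, a), row["strength"]))
        else:
            g.add_undirected(a, b)
    strength_of = dict(kept)
    while not g.is_acyclic():
        cycle = _find_cycle(g)
        weakest = min(cycle, key=lambda arc: (strength_of.get(arc, 0.0), arc))
        warnings.warn(
            f"averaged network contained a cycle {cycle}; dropping weakest arc {weakest}",
            stacklevel=2,
        )
        g.remove_arc(*weakest)
    return g


def _find_cycle(g: Graph) -> list[Arc]:
    """Return the arcs of one directed cycle (g known cyclic)."""
    colour = {n: 0 for n in g.nodes}
    stack: list[str] = []

    def dfs(u: str) -> list[Arc] | None:
        colour[u] = 1
        stack.append(u)
        for v in sorted(g.children(u)):
            if colour[v] == 1:
                i = stack.index(v)
                path = stack[i:] + [v]
                return list(zip(path[:-1], path[1:]))
            if colour[v] == 0:
                found = dfs(v)
                if found:
                    return found
        colour[u] = 2
        stack.pop()
        return None

    for n in sorted(g.nodes):
        if colour[n] == 0:
            found = dfs(n)
            if found:
                return found
    raise AssertionError("no cycle found in cyclic graph")  # pragma: no cover
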