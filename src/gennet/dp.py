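"""Exact structure search by dynamic programming over generational orderings.

Every DAG has a sink, so the best network over a node set V decomposes as the
best network over ``V \\ {s}`` plus the best family score of the sink ``s``
with parents drawn from ``V \\ {s}``.  Iterating this recursion over the
subset lattice yields the exact optimum.  With screened possible-parent sets,
the lattice is restricted to *generational orderings*: a node may only be
appended to a subset in which it has at least one possible parent (singletons
start unconditionally).  Only subsets reachable along such orderings are ever
materialized, which is what makes the search scale past the classic
full-lattice dynamic program.

Subsets are encoded as bitmasks over feasible-set indices; levels are
processed in cardinality order so level k only consults level k-1.  The
module also carries brute-force oracles (exhaustive DAG enumeration, ordering
counts, realizability checks) used to validate the DP.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import TIE_TOL, Dataset, Network
from .scoring import NEG_INF, BgeScorer, LocalScoreTable, local_score
from .screening import FeasibleSet

logger = logging.getLogger(__name__)


class SearchError(ValueError):
    pass


def _popcount(mask: int) -> int:
    return bin(mask).count("1")


def _bits(mask: int) -> Iterable[int]:
    i = 0
    while mask:
        if mask & 1:
            yield i
        mask >>= 1
        i += 1


# ---------------------------------------------------------------------------
# Local score tables over the feasible set
# ---------------------------------------------------------------------------


def compute_local_scores(
    data: Dataset,
    feasible: FeasibleSet,
    score_type: str = "bic",
    indegree: int = 2,
) -> LocalScoreTable:
    """Score every family (v, g) with g a subset of pp(v) of size <= indegree.

    The empty parent set is always scored, so a node admitted to the lattice
    may still end up parentless if the empty family maximizes its score.
    """
    bge = None
    if score_type == "bge":
        bge = BgeScorer(data, nodes=feasible.nodes)
    scores: dict[str, dict[frozenset, float]] = {}
    for node in feasible.nodes:
        pp = feasible.reduced_pp[node]
        entry: dict[frozenset, float] = {}
        for size in range(0, min(indegree, len(pp)) + 1):
            for combo in itertools.combinations(pp, size):
                entry[frozenset(combo)] = local_score(
                    node, combo, data, score_type=score_type, bge_scorer=bge
                )
        scores[node] = entry
    return LocalScoreTable(scores=scores, score_type=score_type, indegree=indegree)


# ---------------------------------------------------------------------------
# Best parents
# ---------------------------------------------------------------------------


@dataclass
class BestParentsTable:
    """bestScore and tied maximizing subsets for every (node, U <= pp(node)).

    Per node the table is an array over bitmasks of that node's possible
    parents, filled by the subset recursion: the best over U is the better of
    U's own local score (if |U| <= indegree) and the best over the |U|
    one-smaller subsets.
    """

    node_pp: dict[str, tuple[str, ...]]
    best: dict[str, np.ndarray]
    bps: dict[str, list[list[frozenset]]]
    indegree: int

    def _mask_of(self, node: str, available: Iterable[str]) -> int:
        order = {p: i for i, p in enumerate(self.node_pp[node])}
        mask = 0
        for v in available:
            if v in order:
                mask |= 1 << order[v]
        return mask

    def best_for(self, node: str, available: Iterable[str]) -> tuple[float, list[frozenset]]:
        """Best score and tied best parent sets drawn from ``available``."""
        mask = self._mask_of(node, available)
        return float(self.best[node][mask]), self.bps[node][mask]


def compute_best_parents(
    table: LocalScoreTable, feasible: FeasibleSet, indegree: int | None = None
) -> BestParentsTable:
    if indegree is None:
        indegree = table.indegree
    best: dict[str, np.ndarray] = {}
    bps: dict[str, list[list[frozenset]]] = {}
    node_pp: dict[str, tuple[str, ...]] = {}
    for node in feasible.nodes:
        pp = tuple(feasible.reduced_pp[node])
        r = len(pp)
        if r > 22:
            raise SearchError(
                f"possible parent set of {node!r} has {r} members; "
                "tighten the screening threshold"
            )
        node_pp[node] = pp
        arr = np.full(1 << r, NEG_INF)
        tied: list[list[frozenset]] = [[] for _ in range(1 << r)]
        for mask in range(1 << r):
            cands: list[tuple[float, list[frozenset]]] = []
            if _popcount(mask) <= indegree:
                subset = frozenset(pp[i] for i in _bits(mask))
                cands.append((table.get(node, subset), [subset]))
            for i in _bits(mask):
                sub = mask ^ (1 << i)
                cands.append((float(arr[sub]), tied[sub]))
            top = max(c[0] for c in cands)
            arr[mask] = top
            sets: list[frozenset] = []
            for score, options in cands:
                if score >= top - TIE_TOL:
                    for g in options:
                        if g not in sets:
                            sets.append(g)
            tied[mask] = sets
        best[node] = arr
        bps[node] = tied
    return BestParentsTable(node_pp=node_pp, best=best, bps=bps, indegree=indegree)


# ---------------------------------------------------------------------------
# Sink lattice
# ---------------------------------------------------------------------------


@dataclass
class SinkLattice:
    """Reachable subsets with cumulative best scores and tied best sinks."""

    nodes: list[str]
    reachable: dict[int, tuple[float, tuple[int, ...]]]

    @property
    def p_bar(self) -> int:
        return len(self.nodes)

    def masks_at_level(self, k: int) -> list[int]:
        return [m for m in self.reachable if _popcount(m) == k]

    def max_level(self) -> int:
        return max(_popcount(m) for m in self.reachable)

    def names(self, mask: int) -> frozenset:
        return frozenset(self.nodes[i] for i in _bits(mask))

    def to_jsonable(self) -> dict:
        return {
            format(mask, "b"): {
                "subset": sorted(self.names(mask)),
                "cum_score": score,
                "best_sinks": [self.nodes[i] for i in sinks],
            }
            for mask, (score, sinks) in self.reachable.items()
        }


def _pp_masks(feasible: FeasibleSet) -> list[int]:
    index = {v: i for i, v in enumerate(feasible.nodes)}
    masks = []
    for v in feasible.nodes:
        m = 0
        for u in feasible.reduced_pp[v]:
            m |= 1 << index[u]
        masks.append(m)
    return masks


def generational_successors(
    subset: Iterable[str], feasible: FeasibleSet
) -> set[str]:
    """Nodes admissible as the next offspring of ``subset``.

    A node is admissible if it is outside the subset and has at least one
    possible parent inside it; every node is admissible at the empty set
    (singleton starts).
    """
    members = set(subset)
    unknown = members - set(feasible.nodes)
    if unknown:
        raise SearchError(f"subset contains non-feasible nodes: {sorted(unknown)}")
    if not members:
        return set(feasible.nodes)
    return {
        v
        for v in feasible.nodes
        if v not in members and members & set(feasible.reduced_pp[v])
    }


def compute_best_sinks(feasible: FeasibleSet, bp: BestParentsTable) -> SinkLattice:
    """Breadth-first best-sink computation over reachable subsets."""
    nodes = feasible.nodes
    p_bar = len(nodes)
    pp_masks = _pp_masks(feasible)
    reachable: dict[int, tuple[float, tuple[int, ...]]] = {0: (0.0, ())}
    frontier = [0]
    for _ in range(p_bar):
        nxt: dict[int, tuple[float, list[int]]] = {}
        for mask in frontier:
            cum = reachable[mask][0]
            for i in range(p_bar):
                bit = 1 << i
                if mask & bit:
                    continue
                if mask and not (pp_masks[i] & mask):
                    continue  # not a possible offspring of this subset
                available = [nodes[j] for j in _bits(pp_masks[i] & mask)]
                score, _ = bp.best_for(nodes[i], available)
                total = cum + score
                new = mask | bit
                if new not in nxt or total > nxt[new][0] + TIE_TOL:
                    nxt[new] = (total, [i])
                elif total >= nxt[new][0] - TIE_TOL:
                    prev_total, sinks = nxt[new]
                    if i not in sinks:
                        sinks.append(i)
                    nxt[new] = (max(prev_total, total), sinks)
        for mask, (score, sinks) in nxt.items():
            reachable[mask] = (score, tuple(sorted(sinks)))
        frontier = list(nxt)
        if not frontier:
            break
    return SinkLattice(nodes=list(nodes), reachable=reachable)


# ---------------------------------------------------------------------------
# Network reconstruction
# ---------------------------------------------------------------------------


def _orderings_from(
    lattice: SinkLattice, mask: int, limit: int
) -> list[tuple[int, ...]]:
    """All tied removal sequences from ``mask`` down to the empty set."""
    if mask == 0:
        return [()]
    out: list[tuple[int, ...]] = []
    _, sinks = lattice.reachable[mask]
    for s in sinks:
        for rest in _orderings_from(lattice, mask ^ (1 << s), limit - len(out)):
            out.append(rest + (s,))
            if len(out) >= limit:
                return out
    return out


def reconstruct_networks(
    lattice: SinkLattice,
    bp: BestParentsTable,
    table: LocalScoreTable,
    feasible: FeasibleSet,
    max_tied: int = 32,
) -> list[Network]:
    """Walk the recorded best sinks back into explicit optimal networks.

    If no subset of full cardinality is reachable (no complete generational
    ordering exists) the networks are rebuilt from the best maximal-cardinality
    reachable subsets, with the remaining nodes attached as isolated,
    empty-parent nodes; this fallback is logged.
    """
    if not lattice.reachable or lattice.reachable.keys() == {0}:
        if len(feasible.nodes) == 0:
            raise SearchError("empty lattice")
    nodes = lattice.nodes
    k_max = lattice.max_level()
    if len(feasible.nodes) > 0 and k_max == 0:
        raise SearchError("lattice contains no non-empty subsets")
    if k_max < len(nodes):
        logger.warning(
            "no complete generational ordering exists; reconstructing from "
            "%d of %d nodes and attaching the rest as isolated nodes",
            k_max,
            len(nodes),
        )
    level = lattice.masks_at_level(k_max)
    best_cum = max(lattice.reachable[m][0] for m in level)
    terminals = sorted(m for m in level if lattice.reachable[m][0] >= best_cum - TIE_TOL)

    networks: list[Network] = []
    seen: set[tuple] = set()
    for term in terminals:
        isolated = sorted(set(nodes) - set(lattice.names(term)))
        iso_score = sum(table.get(v, ()) for v in isolated)
        for ordering_idx in _orderings_from(lattice, term, max_tied):
            # _orderings_from already yields the reverse ordering: the node
            # removed last (a singleton start) comes first, parents-first.
            # per position, the tied best parent sets given the predecessors
            options: list[list[frozenset]] = []
            preds: set[str] = set()
            for i in ordering_idx:
                node = nodes[i]
                available = preds & set(feasible.reduced_pp[node])
                _, tied_sets = bp.best_for(node, available)
                options.append(tied_sets)
                preds.add(node)
            for combo in itertools.product(*options):
                parent_sets = {v: frozenset() for v in nodes}
                for pos, i in enumerate(ordering_idx):
                    parent_sets[nodes[i]] = combo[pos]
                key = tuple(sorted((v, tuple(sorted(ps))) for v, ps in parent_sets.items()))
                if key in seen:
                    continue
                seen.add(key)
                ordering = isolated + [nodes[i] for i in ordering_idx]
                net = Network(
                    nodes=list(nodes),
                    parent_sets=parent_sets,
                    total_score=lattice.reachable[term][0] + iso_score,
                    ordering=ordering,
                )
                networks.append(net)
                if len(networks) >= max_tied:
                    return networks
    return networks


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def _is_acyclic(parent_sets: Mapping[str, frozenset], nodes: Sequence[str]) -> bool:
    indeg = {v: len(parent_sets[v]) for v in nodes}
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for v, ps in parent_sets.items():
        for u in ps:
            children[u].append(v)
    stack = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for w in children[u]:
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(w)
    return seen == len(nodes)


def iter_dags(
    allowed: Mapping[str, Sequence[frozenset]], nodes: Sequence[str]
) -> Iterable[dict[str, frozenset]]:
    """Every acyclic assignment of one allowed parent set per node."""
    for combo in itertools.product(*(allowed[v] for v in nodes)):
        parent_sets = dict(zip(nodes, combo))
        if _is_acyclic(parent_sets, nodes):
            yield parent_sets


def exhaustive_oracle(
    feasible: FeasibleSet,
    table: LocalScoreTable,
    indegree: int,
    require_complete_ordering: bool = False,
) -> tuple[float, list[dict[str, frozenset]]]:
    """Enumerate all pp-consistent DAGs and return the optimum by direct search.

    With ``require_complete_ordering`` only DAGs realizable under a complete
    generational ordering of the whole feasible set are considered (the space
    the restricted dynamic program optimizes over).
    """
    nodes = feasible.nodes
    if len(nodes) > 5:
        raise SearchError("exhaustive oracle is limited to 5 nodes")
    allowed = {
        v: [
            frozenset(c)
            for size in range(0, min(indegree, len(feasible.reduced_pp[v])) + 1)
            for c in itertools.combinations(feasible.reduced_pp[v], size)
        ]
        for v in nodes
    }
    best = NEG_INF
    argmax: list[dict[str, frozenset]] = []
    for dag in iter_dags(allowed, nodes):
        if require_complete_ordering and not realizable_under_complete_ordering(
            dag, feasible
        ):
            continue
        score = sum(table.get(v, dag[v]) for v in nodes)
        if score > best + TIE_TOL:
            best = score
            argmax = [dag]
        elif score >= best - TIE_TOL:
            argmax.append(dag)
    return best, argmax


def realizable_under_complete_ordering(
    parent_sets: Mapping[str, frozenset], feasible: FeasibleSet
) -> bool:
    """Does some complete generational ordering realize this DAG?

    Searches for a permutation of the whole feasible set that is generational
    with respect to the possible-parent sets and in which every node's actual
    parents precede it.
    """
    nodes = feasible.nodes
    index = {v: i for i, v in enumerate(nodes)}
    pp_masks = _pp_masks(feasible)
    par_masks = []
    for v in nodes:
        m = 0
        for u in parent_sets.get(v, frozenset()):
            m |= 1 << index[u]
        par_masks.append(m)
    full = (1 << len(nodes)) - 1
    memo: dict[int, bool] = {}

    def extend(mask: int) -> bool:
        if mask == full:
            return True
        if mask in memo:
            return memo[mask]
        ok = False
        for i in range(len(nodes)):
            bit = 1 << i
            if mask & bit:
                continue
            if mask and not (pp_masks[i] & mask):
                continue
            if par_masks[i] & ~mask:
                continue
            if extend(mask | bit):
                ok = True
                break
        memo[mask] = ok
        return ok

    return extend(0)


def skeleton(parent_sets: Mapping[str, frozenset]) -> frozenset:
    """Undirected adjacencies of a DAG, as a set of unordered pairs."""
    return frozenset(
        frozenset((u, v)) for v, ps in parent_sets.items() for u in ps
    )


def v_structures(parent_sets: Mapping[str, frozenset]) -> frozenset:
    """Immoralities a -> b <- c with a, c non-adjacent."""
    adj = skeleton(parent_sets)
    out = set()
    for b, ps in parent_sets.items():
        for a, c in itertools.combinations(sorted(ps), 2):
            if frozenset((a, c)) not in adj:
                out.add((frozenset((a, c)), b))
    return frozenset(out)


def markov_equivalence_classes(
    dags: Sequence[Mapping[str, frozenset]]
) -> list[list[Mapping[str, frozenset]]]:
    """Group DAGs sharing a skeleton and v-structures (Markov equivalence)."""
    classes: dict[tuple, list] = {}
    for dag in dags:
        key = (skeleton(dag), v_structures(dag))
        classes.setdefault(key, []).append(dag)
    return list(classes.values())


def count_orderings(
    pp: Mapping[str, Sequence[str]] | int, mode: str = "orderings"
) -> int:
    """Count complete generational orderings, or weighted path structures.

    ``pp`` is either a possible-parent map or an integer p meaning the
    unconstrained map on p nodes.  ``orderings`` counts complete root-to-
    bottom lattice paths; ``path_structures`` weights each path by the product
    over its steps of ``2^(number of possible parents preceding the sink)``,
    which with no constraints totals ``p! * 2^(p choose 2)``.
    """
    if isinstance(pp, int):
        p = pp
        if p > 6:
            raise SearchError("unconstrained ordering counts are limited to p <= 6")
        names = [str(i) for i in range(p)]
        pp = {v: [u for u in names if u != v] for v in names}
    nodes = sorted(pp.keys())
    if len(nodes) > 20:
        raise SearchError("ordering counts are limited to 20 nodes")
    if mode not in ("orderings", "path_structures"):
        raise SearchError(f"unknown counting mode {mode!r}")
    index = {v: i for i, v in enumerate(nodes)}
    pp_masks = [0] * len(nodes)
    for v in nodes:
        for u in pp[v]:
            pp_masks[index[v]] |= 1 << index[u]
    full = (1 << len(nodes)) - 1
    counts: dict[int, int] = {0: 1}
    for _ in range(len(nodes)):
        nxt: dict[int, int] = {}
        for mask, c in counts.items():
            if mask == full:
                continue
            for i in range(len(nodes)):
                bit = 1 << i
                if mask & bit:
                    continue
                overlap = pp_masks[i] & mask
                if mask and not overlap:
                    continue
                weight = (1 << _popcount(overlap)) if mode == "path_structures" else 1
                nxt[mask | bit] = nxt.get(mask | bit, 0) + c * weight
        if not nxt:
            break
        counts = nxt
    return counts.get(full, 0)
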