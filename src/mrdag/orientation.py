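"""Step II: edge orientation under the principle of Mendelian randomization.

Orientation proceeds in three passes over the learned skeleton:

1. **Instrumental-variable constraint.**  Genotypes are randomized at meiosis,
   so an edge between a genotype and a phenotype always points to the
   phenotype; an edge between two genotypes stays undirected (causality
   between two genetic variants is not meaningful).
2. **V-structure identification.**  For every triplet X - Y - Z with X, Z
   non-adjacent, the decision rests on the conditional test X ⊥ Z | {Y}: if
   it rejects (conditional dependence), the triplet is the collider
   X -> Y <- Z.  Crucially, if that exact test was never run during the
   skeleton phase (e.g. the X-Z edge fell to a marginal test), it is run *on
   demand* here, consuming the next online-FDR threshold.  This avoids the
   classical sepset shortcut, which claims a v-structure whenever Y is absent
   from the separating set even when no conditional evidence exists.
3. **Iterative matching to the basic three-node models.**  Remaining
   undirected edges are oriented when exactly one direction is consistent
   with the recorded test results, never creating an untested collider or a
   directed cycle; genuinely ambiguous edges stay undirected.

A classic mode (:func:`orient_classic_cpdag`) reproduces the sepset-based
v-structure rule plus Meek propagation, for side-by-side comparison.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import GENOTYPE, PHENOTYPE, CausalGraph
from .independence import SufficientStat
from .online_fdr import FixedThreshold, LondState
from .skeleton import Skeleton, TestLedger, TestRecord, _run_test, learn_skeleton

#: The five basic three-node models over a genotype V1 and phenotypes T1, T2.
#: M4 represents the Markov-equivalence class of the two fully directed DAGs
#: that add T1 -> T2 or T2 -> T1 on top of M3; they cannot be told apart, so
#: the T1 - T2 edge stays undirected.
BASIC_MODELS: dict[str, tuple[tuple[str, str, str], ...]] = {
    "M0": (("V1", "T1", "->"),),
    "M1": (("V1", "T1", "->"), ("T1", "T2", "->")),
    "M2": (("V1", "T1", "->"), ("T2", "T1", "->")),
    "M3": (("V1", "T1", "->"), ("V1", "T2", "->")),
    "M4": (("V1", "T1", "->"), ("V1", "T2", "->"), ("T1", "T2", "--")),
}


class InferenceResult(NamedTuple):
    graph: CausalGraph
    skeleton: Skeleton
    ledger: TestLedger


# -- helpers ---------------------------------------------------------------


def _directed_view(g: CausalGraph) -> nx.DiGraph:
    """Digraph of the strictly directed edges (undirected pairs excluded)."""
    d = nx.DiGraph()
    d.add_nodes_from(g.labels)
    p = g.n_nodes
    for i in range(p):
        for j in range(p):
            if g.amat[i, j] and not g.amat[j, i]:
                d.add_edge(g.labels[i], g.labels[j])
    return d


def _would_cycle(g: CausalGraph, a: str, b: str) -> bool:
    """Would directing a -> b close a directed cycle?"""
    d = _directed_view(g)
    return nx.has_path(d, b, a)


def _set_directed(g: CausalGraph, a: str, b: str) -> None:
    i, j = g.index(a), g.index(b)
    g.amat[i, j], g.amat[j, i] = 1, 0


def _set_undirected(g: CausalGraph, a: str, b: str) -> None:
    i, j = g.index(a), g.index(b)
    g.amat[i, j] = g.amat[j, i] = 1


# -- step (1): Mendelian-randomization constraint ---------------------------


def orient_pmr(skeleton: Skeleton, kinds: Sequence[str] | None = None) -> CausalGraph:
    """Orient genotype-phenotype edges toward the phenotype.

    Genotype-genotype edges become (stay) undirected; phenotype-phenotype
    edges are left undirected for the later steps.  With no genotype nodes
    this is a no-op and orientation effectively starts at the v-structure
    step.
    """
    kinds = tuple(kinds) if kinds is not None else skeleton.kinds
    amat = skeleton.adj.astype(np.int8)
    g = CausalGraph(skeleton.labels, kinds, amat)
    p = g.n_nodes
    for i in range(p):
        for j in range(i + 1, p):
            if not skeleton.adj[i, j]:
                continue
            ki, kj = kinds[i], kinds[j]
            if ki == GENOTYPE and kj == PHENOTYPE:
                g.amat[i, j], g.amat[j, i] = 1, 0
            elif ki == PHENOTYPE and kj == GENOTYPE:
                g.amat[j, i], g.amat[i, j] = 1, 0
    return g


# -- step (2): v-structures with on-demand conditional test -----------------


def identify_v_structures(
    g: CausalGraph,
    skeleton: Skeleton,
    ledger: TestLedger,
    stat: SufficientStat,
    fdr,
) -> CausalGraph:
    """Orient colliders X -> Y <- Z supported by the test X ⊥ Z | {Y}.

    The ledger is consulted first; if the exact conditional test given {Y}
    was not performed during the skeleton search it is conducted now,
    consuming one online-FDR threshold.  Only a *rejection* (conditional
    dependence) orients the triplet; otherwise the edges are left as they
    are.  Conflicting orientation demands on an edge resolve back to the
    undirected state with a warning; edges fixed by the genotype constraint
    are never overridden.
    """
    g = g.copy()
    stat = stat.reorder(skeleton.labels)
    labels = skeleton.labels
    v_set: set[frozenset] = set()       # edges oriented by a v-structure here
    conflicted: set[frozenset] = set()  # edges with contradictory demands

    def demand(tail: str, head: str) -> bool:
        """Try to orient tail -> head; returns True if satisfied."""
        edge = frozenset((tail, head))
        if edge in conflicted:
            return False
        state = g.edge_state(tail, head)
        if state == "->":
            return True
        if state == "--":
            _set_directed(g, tail, head)
            v_set.add(edge)
            return True
        # state == "<-": directed out of the head
        if edge in v_set:
            warnings.warn(
                f"conflicting v-structure orientations for {tail}-{head}; "
                "leaving the edge undirected"
            )
            _set_undirected(g, tail, head)
            v_set.discard(edge)
            conflicted.add(edge)
        else:
            warnings.warn(
                f"v-structure claim {tail}->{head} contradicts the "
                "genotype-direction constraint; skipped"
            )
        return False

    for y in labels:
        nbrs = sorted(skeleton.neighbors(y))
        for x, z in combinations(nbrs, 2):
            if skeleton.adjacent(x, z):
                continue
            rec = ledger.get(x, z, (y,))
            if rec is None:
                i, j, k = labels.index(x), labels.index(z), labels.index(y)
                estimate, pval = _run_test(stat, i, j, (k,))
                threshold = fdr.next_threshold()
                rejected = fdr.record_result(pval, threshold)
                rec = TestRecord(x, z, (y,), estimate, pval, threshold, rejected)
                ledger.add(rec)
            if rec.rejected:
                demand(x, y)
                demand(z, y)
    return g


# -- step (3): iterative orientation against the basic models ---------------


def orient_remaining(
    g: CausalGraph, skeleton: Skeleton, ledger: TestLedger
) -> CausalGraph:
    """Orient leftover undirected edges consistent with the test evidence.

    Sweeps triplets with at least one directed edge and exactly one
    undirected edge, repeating until a full pass makes no change.  An
    undirected edge Y - Z is directed Y -> Z when some X -> Y exists with X, Z
    non-adjacent: among the basic models only the chain X -> Y -> Z matches
    the recorded absence of a v-structure at Y (step 2 already ran the
    conditional test), and orienting Z -> Y would create an untested
    collider.  A triplet with two directed edges X -> Y -> Z and an
    undirected X - Z closes to X -> Z to avoid a directed cycle.
    Orientations that would create a new untested collider or a directed
    cycle are skipped; the edge stays undirected, so the result may contain
    both directed and undirected edges.  Genotype-genotype edges are never
    oriented.
    """
    g = g.copy()
    labels = g.labels
    kinds = dict(zip(g.labels, g.kinds))

    def undirected_edges() -> list[tuple[str, str]]:
        out = []
        for a, b, state in g.edges():
            if state == "--" and not (
                kinds[a] == GENOTYPE and kinds[b] == GENOTYPE
            ):
                out.append(tuple(sorted((a, b))))
        return sorted(out)

    def parents(v: str) -> list[str]:
        i = g.index(v)
        return sorted(
            labels[k]
            for k in range(g.n_nodes)
            if g.amat[k, i] and not g.amat[i, k]
        )

    def creates_new_collider(tail: str, head: str) -> bool:
        for d in parents(head):
            if d != tail and not skeleton.adjacent(d, tail):
                return True
        return False

    def chain_demand(y: str, z: str) -> bool:
        """Some X -> Y with X, Z non-adjacent supports Y -> Z (chain rule)."""
        return any(not skeleton.adjacent(x, z) for x in parents(y) if x != z)

    def cycle_demand(y: str, z: str) -> bool:
        """A directed path Y -> b -> Z with Y - Z undirected forces Y -> Z."""
        i_y = g.index(y)
        for b in labels:
            if b in (y, z):
                continue
            if (
                g.amat[i_y, g.index(b)]
                and not g.amat[g.index(b), i_y]
                and g.amat[g.index(b), g.index(z)]
                and not g.amat[g.index(z), g.index(b)]
            ):
                return True
        return False

    changed = True
    while changed:
        changed = False
        for a, b in undirected_edges():
            fwd = chain_demand(a, b) or cycle_demand(a, b)
            back = chain_demand(b, a) or cycle_demand(b, a)
            if fwd == back:
                continue  # no demand, or ambiguous: leave undirected
            tail, head = (a, b) if fwd else (b, a)
            if kinds[head] == GENOTYPE:
                continue  # never point an edge at a genotype
            if creates_new_collider(tail, head) or _would_cycle(g, tail, head):
                continue
            _set_directed(g, tail, head)
            changed = True
    return g


# -- classic CPDAG mode -----------------------------------------------------


def orient_classic_cpdag(skeleton: Skeleton, sepsets=None) -> CausalGraph:
    """Sepset-based v-structures plus Meek propagation (no genotype constraint).

    For every X - Y - Z with X, Z non-adjacent, the triplet is declared a
    collider iff Y is absent from the recorded separating set of (X, Z).
    This faithfully reproduces the classical shortcut — and its documented
    failure mode: when the X - Z edge was removed by a test that never
    conditioned on Y, the absence of Y from the sepset carries no evidence,
    yet a v-structure is claimed anyway.  Meek rules then propagate
    orientations to the closure.
    """
    sepsets = skeleton.sepsets if sepsets is None else sepsets
    labels = skeleton.labels
    g = CausalGraph(labels, skeleton.kinds, skeleton.adj.astype(np.int8))
    oriented: set[frozenset] = set()
    conflicted: set[frozenset] = set()

    def demand(tail: str, head: str) -> None:
        edge = frozenset((tail, head))
        if edge in conflicted:
            return
        state = g.edge_state(tail, head)
        if state == "--":
            _set_directed(g, tail, head)
            oriented.add(edge)
        elif state == "<-":
            warnings.warn(
                f"conflicting v-structure orientations for {tail}-{head}; "
                "leaving the edge undirected"
            )
            _set_undirected(g, tail, head)
            oriented.discard(edge)
            conflicted.add(edge)

    for y in labels:
        for x, z in combinations(sorted(skeleton.neighbors(y)), 2):
            if skeleton.adjacent(x, z):
                continue
            sep = sepsets.get(frozenset((x, z)))
            if sep is None:
                continue  # pair never separated by a test: no information
            if y not in sep:
                demand(x, y)
                demand(z, y)

    _meek_closure(g)
    return g


def _meek_closure(g: CausalGraph) -> None:
    """Apply Meek rules R1-R3 to a partially directed graph, in place.

    R4 requires background-knowledge orientations to ever fire; starting from
    sepset v-structures alone, R1-R3 already reach the full closure.
    """
    labels = g.labels

    def directed(a: str, b: str) -> bool:
        return g.edge_state(a, b) == "->"

    def und(a: str, b: str) -> bool:
        return g.edge_state(a, b) == "--"

    changed = True
    while changed:
        changed = False
        for a, b in combinations(labels, 2):
            for x, y in ((a, b), (b, a)):
                if not und(x, y):
                    continue
                fire = False
                # R1: w -> x, x - y, w and y non-adjacent  =>  x -> y
                for w in labels:
                    if w not in (x, y) and directed(w, x) and not g.adjacent(w, y):
                        fire = True
                        break
                # R2: x -> w -> y and x - y  =>  x -> y
                if not fire:
                    for w in labels:
                        if w not in (x, y) and directed(x, w) and directed(w, y):
                            fire = True
                            break
                # R3: x - w1, x - w2, w1 -> y, w2 -> y, w1/w2 non-adjacent
                if not fire:
                    ws = [
                        w
                        for w in labels
                        if w not in (x, y) and und(x, w) and directed(w, y)
                    ]
                    for w1, w2 in combinations(ws, 2):
                        if not g.adjacent(w1, w2):
                            fire = True
                            break
                if fire and not _would_cycle(g, x, y):
                    _set_directed(g, x, y)
                    changed = True


# -- end-to-end -------------------------------------------------------------


def infer(
    data: pd.DataFrame | np.ndarray | None = None,
    *,
    stat: SufficientStat | None = None,
    labels: Sequence[str] | None = None,
    kinds: Sequence[str] | None = None,
    n_genotypes: int | None = None,
    alpha: float = 0.05,
    mode: str = "mr",
    corr: str = "pearson",
    fdr_method: str = "lond",
    data_kind: str = "gaussian",
    max_cond_size: int | None = None,
) -> InferenceResult:
    """Learn a causal graph end to end: skeleton search plus orientation.

    Either raw ``data`` (samples x variables; a DataFrame's columns provide
    the labels) or a precomputed ``stat`` may be given.  Node kinds come from
    ``kinds`` or positionally from ``n_genotypes`` (first columns are
    genotypes).  ``mode`` is ``"mr"`` (genotype constraint + on-demand
    v-structure tests + iterative orientation) or ``"classic"``
    (sepset-based CPDAG with Meek propagation).  ``fdr_method`` is ``"lond"``
    for online FDR control or ``"fixed"`` for a constant per-test level.
    The result is deterministic given the inputs and invariant to the column
    order of ``data``.
    """
    if stat is None:
        if data is None:
            raise ValueError("either data or stat must be provided")
        if isinstance(data, pd.DataFrame):
            labels = labels or tuple(str(c) for c in data.columns)
        elif labels is None:
            labels = tuple(f"X{i+1}" for i in range(np.asarray(data).shape[1]))
        if kinds is None:
            ng = n_genotypes or 0
            kinds = tuple(
                GENOTYPE if i < ng else PHENOTYPE for i in range(len(labels))
            )
        stat = SufficientStat.from_data(
            data, labels=labels, kinds=kinds, kind=data_kind, corr=corr
        )
    if mode not in ("mr", "classic"):
        raise ValueError(f"unknown inference mode {mode!r}")
    if fdr_method == "lond":
        fdr = LondState(alpha=alpha)
    elif fdr_method == "fixed":
        fdr = FixedThreshold(alpha=alpha)
    else:
        raise ValueError(f"unknown fdr method {fdr_method!r}")

    skel, ledger = learn_skeleton(stat, fdr, max_cond_size=max_cond_size)
    if mode == "classic":
        graph = orient_classic_cpdag(skel)
    else:
        graph = orient_pmr(skel)
        graph = identify_v_structures(graph, skel, ledger, stat, fdr)
        graph = orient_remaining(graph, skel, ledger)
    return InferenceResult(graph, skel, ledger)
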