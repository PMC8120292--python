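"""Graph comparison metrics, node-ordering stability, and module clustering.

Edges are compared as unordered adjacencies with an orientation *state*
(directed one way, directed the other way, or undirected).  An edge recovered
with the wrong state earns partial credit (weight 0.5 by default); a missing
or spurious adjacency earns none.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import networkx as nx

from .graph import GENOTYPE, CausalGraph, GraphError, canonical_form


def _states(g: CausalGraph, ignore_vv_direction: bool = False) -> dict[frozenset, str]:
    """Map unordered adjacent pairs to 'a->b', 'b->a' (lexicographic a < b)
    or '--'."""
    kinds = dict(zip(g.labels, g.kinds))
    out: dict[frozenset, str] = {}
    for a, b, state in g.edges():
        x, y = sorted((a, b))
        if state == "--" or (
            ignore_vv_direction
            and kinds[a] == GENOTYPE
            and kinds[b] == GENOTYPE
        ):
            out[frozenset((a, b))] = "--"
        else:
            out[frozenset((a, b))] = f"{a}->{b}"
    return out


def _check_labels(truth: CausalGraph, inferred: CausalGraph) -> None:
    if sorted(truth.labels) != sorted(inferred.labels):
        raise GraphError("graphs must share the same label set")


def recall_precision(
    truth: CausalGraph,
    inferred: CausalGraph,
    w: float = 0.5,
    ignore_vv_direction: bool = False,
) -> tuple[float, float]:
    """Weighted edge recall and precision of an inferred graph.

    Each true edge earns credit 1 if recovered with the same orientation
    state, ``w`` if recovered with a different state, 0 if absent.  Recall
    divides the total credit by the number of true edges; precision divides
    the same total by the number of inferred edges (0 for an empty inferred
    graph, by convention, so sweeps stay total).
    """
    _check_labels(truth, inferred)
    ts = _states(truth, ignore_vv_direction)
    xs = _states(inferred, ignore_vv_direction)
    credit = 0.0
    for pair, state in ts.items():
        if pair in xs:
            credit += 1.0 if xs[pair] == state else w
    recall = credit / len(ts) if ts else (1.0 if not xs else 0.0)
    precision = credit / len(xs) if xs else 0.0
    return recall, precision


def ashd(truth: CausalGraph, inferred: CausalGraph) -> float:
    """Adjusted structural Hamming distance between two mixed graphs.

    Summed over unordered node pairs: 1.0 when an adjacency exists in one
    graph but not the other, 0.5 when both graphs have the adjacency but with
    different orientation states, 0 otherwise.
    """
    _check_labels(truth, inferred)
    ts = _states(truth)
    xs = _states(inferred)
    d = 0.0
    for pair in set(ts) | set(xs):
        if pair not in ts or pair not in xs:
            d += 1.0
        elif ts[pair] != xs[pair]:
            d += 0.5
    return d


def stability_count(
    data: pd.DataFrame,
    n_perm: int,
    rng: np.random.Generator,
    *,
    kinds=None,
    **infer_kwargs,
) -> int:
    """Number of distinct graphs inferred across random column permutations.

    The same dataset is re-presented ``n_perm`` times with its columns (and
    the matching node kinds) shuffled; each copy is run through
    :func:`~mrdag.orientation.infer` and the distinct canonical graph keys
    are counted.  A value of 1 means the inference is invariant to node
    ordering on this dataset.
    """
    from .orientation import infer

    if n_perm < 1:
        raise ValueError("need at least one permutation")
    kinds = tuple(kinds) if kinds is not None else None
    keys = set()
    p = data.shape[1]
    for _ in range(n_perm):
        perm = rng.permutation(p)
        permuted = data.iloc[:, perm]
        pk = tuple(kinds[i] for i in perm) if kinds is not None else None
        res = infer(permuted, kinds=pk, **infer_kwargs)
        keys.add(canonical_form(res.graph))
    return len(keys)


def node_distances(g: CausalGraph) -> np.ndarray:
    """Pairwise shortest-path edge counts, ignoring edge orientation.

    Disconnected pairs receive the number of nodes as a finite sentinel
    distance (one more than any achievable path length).
    """
    p = g.n_nodes
    u = nx.Graph()
    u.add_nodes_from(g.labels)
    for a, b, _ in g.edges():
        u.add_edge(a, b)
    D = np.full((p, p), float(p))
    np.fill_diagonal(D, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(u):
        i = g.index(src)
        for dst, d in lengths.items():
            D[i, g.index(dst)] = float(d)
    return D


def cluster_modules(
    g: CausalGraph, min_size: int, linkage: str = "average"
) -> tuple[dict[str, int], np.ndarray]:
    """Cluster nodes into modules from the graph-distance dendrogram.

    Agglomerative clustering (``linkage``, average by default) is run on the
    pairwise shortest-path distances; the dendrogram is cut at the height
    that yields the largest number of clusters of at least ``min_size``
    nodes.  Nodes falling in smaller clusters are left unassigned (module 0).
    Returns (label -> module id, scipy linkage matrix).
    """
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    labels = g.labels
    p = g.n_nodes
    if p == 1:
        return {labels[0]: 1 if min_size <= 1 else 0}, np.empty((0, 4))
    D = node_distances(g)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    heights = np.concatenate([[0.0], Z[:, 2]])
    best = None
    for h in np.unique(heights):
        assign = hierarchy.fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(assign)
        good = [c for c in np.unique(assign) if sizes[c] >= min_size]
        n_assigned = int(sum(sizes[c] for c in good))
        score = (len(good), n_assigned)
        if best is None or score > best[0]:
            best = (score, assign, set(good))
    _, assign, good = best
    modules: dict[str, int] = {}
    next_id = 1
    seen: dict[int, int] = {}
    for lab, c in zip(labels, assign):
        if c in good:
            if c not in seen:
                seen[c] = next_id
                next_id += 1
            modules[lab] = seen[c]
        else:
            modules[lab] = 0
    return modules, Z
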