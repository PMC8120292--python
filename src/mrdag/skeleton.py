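"""Step I: order-independent level-wise skeleton search.

Starting from a complete undirected graph, the search tests each adjacent
pair for marginal independence (level 0), then conditional independence given
one node, two nodes, and so on.  A non-rejected test removes the edge, records
the separating set, and the edge is never tested again in this step.  Every
test consumes one online-FDR threshold, and all enumeration (pairs, subsets)
follows the canonical lexicographic label order so the entire procedure — and
the threshold stream with it — is invariant to input column order.

Adjacency sets used for conditioning are frozen at the start of each level
(the "stable" variant), so edge removals within a level cannot influence which
tests other pairs receive.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

from .independence import (
    SufficientStat,
    fisher_z_pvalue,
    g_square_test,
    partial_correlation,
)


@dataclasses.dataclass(frozen=True)
class TestRecord:
    """One independence test: pair, conditioning set, estimate, decision."""

    a: str
    b: str
    S: tuple[str, ...]
    estimate: float
    p: float
    threshold: float
    rejected: bool

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))


class TestLedger:
    """Ordered record of every independence test performed.

    The ledger is the source of truth for edge orientation: the v-structure
    step consults it before running any new test, and the iterative
    orientation step reads separation evidence from it.
    """

    def __init__(self) -> None:
        self._records: list[TestRecord] = []
        self._by_key: dict[tuple[frozenset, frozenset], TestRecord] = {}

    def add(self, rec: TestRecord) -> None:
        key = (rec.pair, frozenset(rec.S))
        if key in self._by_key:
            raise ValueError(f"duplicate test for {sorted(rec.pair)} | {rec.S}")
        self._records.append(rec)
        self._by_key[key] = rec

    def get(self, a: str, b: str, S: Sequence[str]) -> TestRecord | None:
        return self._by_key.get((frozenset((a, b)), frozenset(S)))

    def records(self) -> tuple[TestRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TestRecord]:
        return iter(self._records)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("a\tb\tsize\tS\testimate\tp\tthreshold\trejected\n")
            for r in self._records:
                fh.write(
                    f"{r.a}\t{r.b}\t{len(r.S)}\t{','.join(r.S)}\t"
                    f"{r.estimate:.10g}\t{r.p:.10g}\t{r.threshold:.10g}\t"
                    f"{int(r.rejected)}\n"
                )


@dataclasses.dataclass
class Skeleton:
    """Undirected skeleton plus separation sets.

    ``sepsets`` maps an unordered label pair to the conditioning set of the
    non-rejected test that removed the edge; it is defined exactly for the
    non-adjacent pairs that were tested.
    """

    labels: tuple[str, ...]
    kinds: tuple[str, ...]
    adj: np.ndarray
    sepsets: dict[frozenset, tuple[str, ...]]

    def adjacent(self, a: str, b: str) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return bool(self.adj[i, j])

    def neighbors(self, a: str) -> tuple[str, ...]:
        i = self.labels.index(a)
        return tuple(self.labels[j] for j in np.flatnonzero(self.adj[i]))


def _run_test(stat: SufficientStat, i: int, j: int, S: tuple[int, ...]):
    """Dispatch one independence test; returns (estimate, p)."""
    if stat.kind == "discrete":
        p, g2, _ = g_square_test(stat.data, i, j, list(S))
        return g2, p
    rho = partial_correlation(stat.R, i, j, list(S))
    return rho, fisher_z_pvalue(rho, stat.n, len(S))


def learn_skeleton(
    stat: SufficientStat,
    fdr,
    max_cond_size: int | None = None,
    ledger: TestLedger | None = None,
) -> tuple[Skeleton, TestLedger]:
    """Level-wise stable skeleton search with online-FDR thresholds.

    ``fdr`` is any object with the ``next_threshold``/``record_result``
    protocol (:class:`~mrdag.online_fdr.LondState` or ``FixedThreshold``).
    The sufficient statistics are reordered into canonical label order before
    any test runs, so the output is identical for any column permutation of
    the same data.
    """
    order = sorted(stat.labels)
    stat = stat.reorder(order)
    labels = stat.labels
    p = len(labels)
    if p < 2:
        raise ValueError("skeleton search needs at least two nodes")
    ledger = ledger if ledger is not None else TestLedger()
    adj = np.ones((p, p), dtype=bool)
    np.fill_diagonal(adj, False)
    sepsets: dict[frozenset, tuple[str, ...]] = {}

    level = 0
    while True:
        frozen = adj.copy()
        for i in range(p):
            for j in range(i + 1, p):
                if not adj[i, j]:
                    continue
                nbrs = [k for k in np.flatnonzero(frozen[i]) if k != j]
                if len(nbrs) < level:
                    continue
                for S in combinations(nbrs, level):
                    try:
                        estimate, pval = _run_test(stat, i, j, S)
                    except Exception as exc:
                        raise type(exc)(
                            f"{exc} [pair ({labels[i]}, {labels[j]}) given "
                            f"{tuple(labels[k] for k in S)}]"
                        ) from exc
                    threshold = fdr.next_threshold()
                    rejected = fdr.record_result(pval, threshold)
                    ledger.add(
                        TestRecord(
                            labels[i],
                            labels[j],
                            tuple(labels[k] for k in S),
                            estimate,
                            pval,
                            threshold,
                            rejected,
                        )
                    )
                    if not rejected:
                        adj[i, j] = adj[j, i] = False
                        sepsets[frozenset((labels[i], labels[j]))] = tuple(
                            labels[k] for k in S
                        )
                        break
        level += 1
        if max_cond_size is not None and level > max_cond_size:
            break
        # continue only if some adjacent pair has enough neighbors to condition on
        more = any(
            adj[i, j] and np.count_nonzero(adj[i]) - 1 >= level
            for i in range(p)
            for j in range(i + 1, p)
        )
        if not more:
            break

    return Skeleton(labels, stat.kinds, adj, sepsets), ledger
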