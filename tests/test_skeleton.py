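"""Skeleton search: level-wise testing, sepsets, ledger, order independence."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from mrdag.independence import SufficientStat
from mrdag.online_fdr import FixedThreshold, LondState
from mrdag.simulate import SimulationSpec, basic_model, replicate_rng, simulate_dataset
from mrdag.skeleton import learn_skeleton
from .conftest import random_correlation
from .test_independence import recursive_partial_correlation


def reference_stable_skeleton(R, n, labels, alpha):
    """Independent oracle: a direct transcription of the stable level-wise
    search at a fixed per-test level, using the recursive partial-correlation
    formula instead of matrix inversion."""
    order = sorted(range(len(labels)), key=lambda k: labels[k])
    labels = [labels[k] for k in order]
    R = R[np.ix_(order, order)]
    p = len(labels)
    adj = {(i, j) for i in range(p) for j in range(p) if i != j}
    level = 0
    while True:
        frozen = dict()
        for i in range(p):
            frozen[i] = [k for k in range(p) if (i, k) in adj]
        for i in range(p):
            for j in range(i + 1, p):
                if (i, j) not in adj:
                    continue
                nbrs = [k for k in frozen[i] if k != j]
                if len(nbrs) < level:
                    continue
                for S in combinations(nbrs, level):
                    rho = recursive_partial_correlation(R, i, j, list(S))
                    z = np.sqrt(n - level - 3) * abs(np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15)))
                    pval = 2 * stats.norm.sf(z)
                    if pval > alpha:
                        adj.discard((i, j))
                        adj.discard((j, i))
                        break
        level += 1
        if not any(
            (i, j) in adj and sum((i, k) in adj for k in range(p)) - 1 >= level
            for i in range(p)
            for j in range(i + 1, p)
        ):
            break
    return {frozenset((labels[i], labels[j])) for i, j in adj if i < j}


def _edges(skel):
    p = len(skel.labels)
    return {
        frozenset((skel.labels[i], skel.labels[j]))
        for i in range(p)
        for j in range(i + 1, p)
        if skel.adj[i, j]
    }


def test_independent_nodes_yield_empty_skeleton(rng):
    """Mutually independent Gaussians give an empty skeleton with high
    probability (false positives are bounded by the online thresholds)."""
    empties = 0
    for _ in range(20):
        X = rng.normal(size=(1000, 3))
        stat = SufficientStat.from_data(X, labels=("A", "B", "C"))
        skel, ledger = learn_skeleton(stat, LondState(alpha=0.05))
        if not _edges(skel):
            empties += 1
            assert len(ledger) == 3  # only the marginal tests
    assert empties >= 16  # null edge rate is a few percent per dataset


def test_chain_skeleton_and_sepset():
    truth = basic_model("M1")
    data, _ = simulate_dataset(SimulationSpec(truth=truth, gamma=1.0), replicate_rng(5, 0))
    stat = SufficientStat.from_data(data, kinds=truth.kinds)
    skel, _ = learn_skeleton(stat, LondState(alpha=0.05))
    assert _edges(skel) == {frozenset({"V1", "T1"}), frozenset({"T1", "T2"})}
    assert skel.sepsets[frozenset({"V1", "T2"})] == ("T1",)


def test_matches_brute_force_reference_at_fixed_alpha(rng):
    """With a fixed per-test level, the skeleton (edge set) equals an
    independently coded stable search on random correlation structures."""
    for trial in range(8):
        p = int(rng.integers(3, 6))
        R = random_correlation(rng, p)
        labels = tuple(f"X{k+1}" for k in range(p))
        stat = SufficientStat(R, 500, labels, ("phenotype",) * p)
        skel, _ = learn_skeleton(stat, FixedThreshold(alpha=0.05))
        expected = reference_stable_skeleton(R, 500, list(labels), 0.05)
        assert _edges(skel) == expected


def test_ledger_audit_removed_edges_tested_once():
    truth = basic_model("M1")
    data, _ = simulate_dataset(SimulationSpec(truth=truth, gamma=0.5), replicate_rng(6, 0))
    stat = SufficientStat.from_data(data, kinds=truth.kinds)
    skel, ledger = learn_skeleton(stat, LondState(alpha=0.05))
    seen = set()
    for rec in ledger:
        key = (rec.pair, frozenset(rec.S))
        assert key not in seen
        seen.add(key)
    # each removed pair has exactly one non-rejected record, and no test of a
    # pair appears after its removal
    for pair, sep in skel.sepsets.items():
        recs = [r for r in ledger if r.pair == pair]
        non_rej = [r for r in recs if not r.rejected]
        assert len(non_rej) == 1
        assert frozenset(non_rej[0].S) == frozenset(sep)
        assert recs[-1] is non_rej[0]


def test_skeleton_invariant_under_column_permutation(rng):
    truth = basic_model("M2")
    data, _ = simulate_dataset(SimulationSpec(truth=truth, gamma=1.0), replicate_rng(8, 0))
    stat = SufficientStat.from_data(data, kinds=truth.kinds)
    skel, ledger = learn_skeleton(stat, LondState())
    for _ in range(5):
        perm = rng.permutation(data.shape[1])
        stat_p = SufficientStat.from_data(
            data.iloc[:, perm], kinds=tuple(truth.kinds[i] for i in perm)
        )
        skel_p, ledger_p = learn_skeleton(stat_p, LondState())
        assert skel_p.labels == skel.labels
        assert np.array_equal(skel_p.adj, skel.adj)
        assert skel_p.sepsets == skel.sepsets
        assert ledger_p.records() == ledger.records()


def test_max_cond_size_limits_levels(rng):
    p = 5
    R = random_correlation(rng, p)
    stat = SufficientStat(R, 500, tuple(f"X{k}" for k in range(p)), ("phenotype",) * p)
    _, ledger = learn_skeleton(stat, FixedThreshold(alpha=0.2), max_cond_size=0)
    assert all(len(r.S) == 0 for r in ledger)


def test_ledger_tsv_export(tmp_path):
    truth = basic_model("M1")
    data, _ = simulate_dataset(SimulationSpec(truth=truth, gamma=1.0), replicate_rng(5, 1))
    stat = SufficientStat.from_data(data, kinds=truth.kinds)
    _, ledger = learn_skeleton(stat, LondState())
    out = tmp_path / "ledger.tsv"
    ledger.to_tsv(out)
    lines = out.read_text().strip().split("\n")
    assert len(lines) == len(ledger) + 1
    assert lines[0].split("\t") == [
        "a", "b", "size", "S", "estimate", "p", "threshold", "rejected",
    ]
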