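"""Synthetic data generation from a known ground-truth causal graph.

Phenotype nodes follow linear-Gaussian structural equations: a parentless
phenotype is N(m_i, sigma_i^2); a node with parent set P is
N(gamma_0 + sum_{l in P} gamma_l X_l, sigma_j^2).  A parentless genotype node
is a biallelic SNP in Hardy-Weinberg equilibrium with alternative-allele
frequency q, so genotypes 0/1/2 occur with probabilities (1-q)^2, 2q(1-q),
q^2; a genotype node that acquires a parent (only possible when an undirected
genotype-genotype edge is given a direction) is generated from the
conditional normal like any other child.

Undirected edges in the truth are handled two ways: a phenotype-phenotype
edge is a per-sample 50:50 mixture of the two possible directions (each
sample's values come from one of the two fully directed versions of the
graph), while an undirected genotype-genotype edge receives one random
direction for the whole dataset.

Defaults (q = 0.45, gamma_0 = 0, m = 0, sigma = 1, n = 1000) are the study
conditions used throughout the replication experiments; the signal strength
gamma is the parameter swept (1.0 strong, 0.5 moderate, 0.2 weak).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import (
    GENOTYPE,
    PHENOTYPE,
    CausalGraph,
    GraphError,
    graph_from_edges,
)
from .orientation import BASIC_MODELS

_MAX_MIXTURE_EDGES = 4


@dataclasses.dataclass
class SimulationSpec:
    """Everything needed to simulate one dataset from a ground-truth graph."""

    truth: CausalGraph
    gamma: float | Mapping[tuple[str, str], float] = 1.0
    gamma0: float = 0.0
    mean: float = 0.0
    sigma: float = 1.0
    q: float = 0.45
    n: int = 1000
    seed: int | None = None
    n_outliers: int = 0
    outlier_magnitude: float = 10.0
    discretize_levels: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sample size must be at least 1")
        if not 0 <= self.q <= 1:
            raise ValueError("allele frequency q must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("noise sd must be positive")

    def coef(self, parent: str, child: str) -> float:
        if isinstance(self.gamma, Mapping):
            return float(self.gamma[(parent, child)])
        return float(self.gamma)


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for replicate ``rep``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def simulate_genotype(q: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. genotypes 0/1/2 under Hardy-Weinberg equilibrium."""
    if not 0 <= q <= 1:
        raise ValueError("allele frequency q must lie in [0, 1]")
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    return rng.choice(np.array([0.0, 1.0, 2.0]), size=n, p=probs)


def _generate_directed(
    spec: SimulationSpec,
    edges: Sequence[tuple[str, str]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one dataset from a fully directed version of the truth."""
    labels = spec.truth.labels
    kinds = dict(zip(labels, spec.truth.kinds))
    dag = nx.DiGraph()
    dag.add_nodes_from(labels)
    dag.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(dag):
        raise GraphError("directed part of the truth graph contains a cycle")
    X = np.empty((spec.n, len(labels)))
    col = {lab: k for k, lab in enumerate(labels)}
    for node in nx.lexicographical_topological_sort(dag):
        parents = sorted(dag.predecessors(node))
        if not parents:
            if kinds[node] == GENOTYPE:
                X[:, col[node]] = simulate_genotype(spec.q, spec.n, rng)
            else:
                X[:, col[node]] = rng.normal(spec.mean, spec.sigma, spec.n)
        else:
            mu = spec.gamma0 + sum(
                spec.coef(par, node) * X[:, col[par]] for par in parents
            )
            X[:, col[node]] = mu + rng.normal(0.0, spec.sigma, spec.n)
    return X


def simulate_dag_data(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate one samples x variables dataset from the ground truth.

    Undirected genotype-genotype edges get one random direction per edge;
    each undirected phenotype-phenotype edge is a per-sample 50:50 mixture of
    its two directions (all 2^k directed versions are generated and each
    sample picks one according to independent fair coin flips per edge).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    truth = spec.truth
    kinds = dict(zip(truth.labels, truth.kinds))
    directed: list[tuple[str, str]] = []
    mixture: list[tuple[str, str]] = []
    for a, b, state in truth.edges():
        if state == "->":
            directed.append((a, b))
        elif kinds[a] == GENOTYPE and kinds[b] == GENOTYPE:
            directed.append((a, b) if rng.random() < 0.5 else (b, a))
        elif kinds[a] != kinds[b]:
            # an undirected variant-phenotype edge can only mean variant -> phenotype
            directed.append((a, b) if kinds[a] == GENOTYPE else (b, a))
        else:
            mixture.append((a, b))
    k = len(mixture)
    if k > _MAX_MIXTURE_EDGES:
        raise GraphError(
            f"too many undirected phenotype edges for mixture simulation ({k})"
        )
    if k == 0:
        X = _generate_directed(spec, directed, rng)
    else:
        versions = []
        for mask in range(2**k):
            extra = [
                (a, b) if not (mask >> e) & 1 else (b, a)
                for e, (a, b) in enumerate(mixture)
            ]
            versions.append(_generate_directed(spec, directed + extra, rng))
        flips = rng.integers(0, 2, size=(spec.n, k))
        choice = (flips * (2 ** np.arange(k))).sum(axis=1)
        X = np.empty_like(versions[0])
        for mask in range(2**k):
            rows = choice == mask
            X[rows] = versions[mask][rows]
    return pd.DataFrame(X, columns=list(truth.labels))


def inject_outliers(
    data: pd.DataFrame,
    k: int,
    magnitude: float,
    rng: np.random.Generator,
    kinds: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Contaminate ``k`` uniformly chosen samples with gross phenotype outliers.

    The phenotype values of each chosen row are replaced by fresh draws
    centered ``magnitude`` column standard deviations above the column mean;
    genotype columns are left untouched.  Returns the contaminated copy and
    the sorted outlier row indices.
    """
    n = data.shape[0]
    if k > n:
        raise ValueError("cannot inject more outliers than samples")
    kinds = tuple(kinds) if kinds is not None else (PHENOTYPE,) * data.shape[1]
    rows = np.sort(rng.choice(n, size=k, replace=False))
    out = data.copy()
    if k:
        for col, kind in zip(data.columns, kinds):
            if kind == GENOTYPE:
                continue
            sd = float(data[col].std(ddof=1))
            loc = float(data[col].mean()) + magnitude * sd
            out.loc[out.index[rows], col] = rng.normal(loc, sd, size=k)
    return out, rows


def discretize(data: pd.DataFrame, levels: int) -> pd.DataFrame:
    """Quantile-bin every column into ``levels`` categories (0..levels-1).

    Binning is rank-based, so with all-distinct values the category counts
    differ by at most one.  A constant column collapses to a single category
    with a warning.
    """
    if levels < 2:
        raise ValueError("need at least 2 levels")
    n = data.shape[0]
    out = {}
    for col in data.columns:
        vals = data[col].to_numpy()
        if np.all(vals == vals[0]):
            warnings.warn(f"column {col!r} is constant; single category")
            out[col] = np.zeros(n, dtype=int)
            continue
        order = np.argsort(vals, kind="stable")
        cats = np.empty(n, dtype=int)
        cats[order] = np.arange(n) * levels // n
        out[col] = cats
    return pd.DataFrame(out, index=data.index)


def simulate_dataset(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a dataset and apply the spec's outlier/discretization policies.

    Returns (data, outlier_row_indices).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    data = simulate_dag_data(spec, rng)
    outliers = np.array([], dtype=int)
    if spec.n_outliers:
        data, outliers = inject_outliers(
            data, spec.n_outliers, spec.outlier_magnitude, rng, spec.truth.kinds
        )
    if spec.discretize_levels:
        data = discretize(data, spec.discretize_levels)
    return data, outliers


# -- graph catalog -----------------------------------------------------------


def basic_model(name: str) -> CausalGraph:
    """One of the five basic three-node models M0..M4 (genotype V1, phenotypes
    T1, T2)."""
    if name not in BASIC_MODELS:
        raise GraphError(f"unknown basic model {name!r}")
    return graph_from_edges(
        ("V1", "T1", "T2"), (GENOTYPE, PHENOTYPE, PHENOTYPE), BASIC_MODELS[name]
    )


def chain_model(n_phenotypes: int = 3) -> CausalGraph:
    """The chain V1 -> T1 -> ... -> Tk."""
    labels = ["V1"] + [f"T{i+1}" for i in range(n_phenotypes)]
    kinds = [GENOTYPE] + [PHENOTYPE] * n_phenotypes
    edges = [(labels[i], labels[i + 1], "->") for i in range(n_phenotypes)]
    return graph_from_edges(labels, kinds, edges)


def collider_chain_model() -> CausalGraph:
    """V1 -> T1 <- T2 -> T3: a collider followed by a chain."""
    return graph_from_edges(
        ("V1", "T1", "T2", "T3"),
        (GENOTYPE, PHENOTYPE, PHENOTYPE, PHENOTYPE),
        (("V1", "T1", "->"), ("T2", "T1", "->"), ("T2", "T3", "->")),
    )


def complex_network() -> CausalGraph:
    """Synthetic 22-node network: 14 genetic variants and 8 phenotypes.

    A synthetic stand-in assembled from four groups of nodes, each containing
    undirected variant-variant edges, variant -> phenotype edges (including
    collider patterns T_i -> T_j <- V_k) and phenotype chains, so that the
    network exhibits the chain and v-structure motifs of the basic models and
    clusters into four modules of at least five nodes.
    """
    variants = [f"V{i+1}" for i in range(14)]
    phenos = [f"T{i+1}" for i in range(8)]
    labels = variants + phenos
    kinds = [GENOTYPE] * 14 + [PHENOTYPE] * 8
    edges = [
        # group 1: V1, V2, V3, T1, T2 (chain V2->T1->T2, collider T1->T2<-V3)
        ("V1", "V2", "--"),
        ("V2", "T1", "->"),
        ("V3", "T2", "->"),
        ("T1", "T2", "->"),
        # group 2: V4, V5, V6, T3, T4 (chain V6->T3->T4, collider T3->T4<-V5)
        ("V4", "V5", "--"),
        ("V5", "T4", "->"),
        ("V6", "T3", "->"),
        ("T3", "T4", "->"),
        # group 3: V7, V8, V9, V10, T5, T6 (chain V8->T5->T6, collider T5->T6<-V10)
        ("V7", "V8", "--"),
        ("V9", "V10", "--"),
        ("V8", "T5", "->"),
        ("V10", "T6", "->"),
        ("T5", "T6", "->"),
        # group 4: V11, V12, V13, V14, T7, T8 (mirror of group 3)
        ("V11", "V12", "--"),
        ("V13", "V14", "--"),
        ("V12", "T7", "->"),
        ("V14", "T8", "->"),
        ("T7", "T8", "->"),
    ]
    return graph_from_edges(labels, kinds, edges)


def outlier_demo_network() -> CausalGraph:
    """Synthetic 4-node truth for the outlier-robustness experiment.

    A chain V1 -> T1 -> T2 plus an unrelated phenotype T3.  Gross outliers
    shift every phenotype in the same direction, so with plain Pearson
    correlation they fabricate associations between T3 and the chain (extra
    edges); robust correlation downweights the outliers and recovers the
    truth.
    """
    return graph_from_edges(
        ("V1", "T1", "T2", "T3"),
        (GENOTYPE, PHENOTYPE, PHENOTYPE, PHENOTYPE),
        (("V1", "T1", "->"), ("T1", "T2", "->")),
    )
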