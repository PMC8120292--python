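# Methods

## Model and assumptions

`mrdag` learns a mixed causal graph (directed + undirected edges) over
genotype and phenotype nodes from individual-level data, assuming causal
sufficiency (all confounders observed), linear-Gaussian dependence among
continuous variables (so conditional independence is equivalent to zero
partial correlation), and faithfulness (every conditional independence in the
data reflects d-separation in the truth). Genetic variants are treated as
instruments under the principle of Mendelian randomization: meiosis
randomizes alleles, so a variant–phenotype edge can only point toward the
phenotype, and variant–variant edges carry no causal direction. Undirected
and bidirected edges are a single state (`A[i,j] = A[j,i] = 1`): a
Markov-equivalence ambiguity, not two distinct claims.

The inference is the standard two-step constraint-based scheme — stable
level-wise skeleton search, then orientation — with three deliberate
departures from classical PC implementations:

1. **Online FDR (LOND).** The number of independence tests is unknown in
   advance, so each test t receives the threshold α_t = β_t(D(t−1) + 1).
   The spending sequence defaults to β_t = α·C/(t ln² max(t, 2)) with C
   normalizing the sum to α over the first 10⁶ tests; it is an argument of
   `LondState`, and a fixed per-test level (`FixedThreshold`) is available
   for comparison runs. Under a fully null stream the expected
   false-discovery proportion is bounded by α (verified by simulation in the
   test suite).
2. **On-demand collider tests.** A triplet X − Y − Z (X, Z non-adjacent) is
   oriented as a collider only on the evidence of the test X ⟂ Z | {Y}. When
   Step I removed the X–Z edge by some other test, that conditional test is
   run at orientation time rather than inferred from the separating set. The
   conditioning set is exactly {Y}; larger supersets are not consulted. The
   `classic` mode keeps the sepset shortcut (plus Meek propagation) precisely
   so that its false-collider behavior can be reproduced and measured.
3. **Canonical order.** Pairs, conditioning subsets, and triplets are
   enumerated in lexicographic label order, and the sufficient statistics are
   reordered canonically before any test runs. The threshold stream, the
   ledger, the skeleton, and the final graph are therefore bit-identical
   under any permutation of input columns. (This also makes the classic mode
   order-invariant, which the classical implementations it mimics are not.)

Remaining undirected edges are oriented by iterative matching against the
five basic three-node models: chain propagation (X → Y, Y − Z, X and Z
non-adjacent ⇒ Y → Z, since Z → Y would be an untested collider) and cycle
closure (X → W → Z with X − Z ⇒ X → Z), skipping any orientation that would
create a new collider or a directed cycle, until a fixed point. Conflicting
collider demands on one edge revert it to undirected with a warning; the
constraint that no edge points into a genotype is never overridden. Edges
with no uniquely consistent direction stay undirected, so the output may mix
directed and undirected edges.

Meek rules R1–R3 are applied in classic mode; the fourth rule can only fire
when orientations originate from background knowledge, which classic mode
does not use, so R1–R3 already give the full closure there.

## Independence tests

* **Fisher z** (continuous): statistic √(n − |S| − 3)·|atanh ρ̂| against a
  standard normal, two-sided. Partial correlations come from the precision
  matrix of the correlation submatrix on {i, j} ∪ S; a singular submatrix
  raises a collinearity error with pair/set context. |ρ̂| = 1 returns p = 0
  with a warning rather than an error so simulation sweeps do not abort.
  The test requires n − |S| − 3 ≥ 1.
* **G²** (categorical): 2 Σ O ln(O/E) summed over the strata defined by the
  joint levels of S, with df = (L_i − 1)(L_j − 1) Π_k L_k (level counts from
  the full data); zero-count cells contribute nothing, empty strata are
  skipped, df ≤ 0 returns p = 1 with a warning.
* **Robust correlation**: iteratively reweighted location/scatter with
  Tukey-biweight weights w = (1 − d²/c²)² on squared Mahalanobis distances,
  c² the 0.999 χ²_p quantile, iterated to tolerance 1e-6 (max 100
  iterations). Weights live in [0, 1] and gross outliers get ≈ 0. When
  genotype columns are present, reweighting applies to the phenotype block
  only; genotype–anything correlations stay plain Pearson (genotypes are
  bounded counts, not elliptically distributed). Any affine-equivariant
  weight-producing scatter estimator would serve; this one is simple,
  deterministic, and meets the stated weight behavior.

## Simulator

Data are generated from a ground-truth graph in topological order:
parentless phenotypes ~ N(m, σ²); a node with parents P gets
N(γ₀ + Σ_{l∈P} γ_l X_l, σ²); parentless genotypes are Hardy–Weinberg draws
from ((1−q)², 2q(1−q), q²). Defaults: q = 0.45, γ₀ = 0, m = 0, σ = 1,
n = 1000 — the study conditions of all replication experiments; the shared
effect size γ is swept over {1.0, 0.5, 0.2} (strong/moderate/weak).

Undirected edges in the truth are handled two ways. A variant–variant edge
gets one random direction per dataset (the directed child is then generated
from the conditional normal — only *parentless* genotypes are multinomial).
A phenotype–phenotype undirected edge is a per-sample 50:50 mixture: both
directed completions of the graph are generated and each sample picks one
according to independent fair coin flips (at most 4 such edges, i.e. 16
completions). Outlier injection replaces the phenotype values of k uniformly
chosen rows (default magnitude: draws centered 10 column-sd above the column
mean; the count, not the mechanism, is the primitive quantity — 10 outliers
in n = 1000 for the robustness experiment). Discretization is rank-based
quantile binning, so category counts differ by at most 1 when values are
distinct.

**Reference graphs.** The catalog provides the five basic models M0–M4, the
4-node chain and collider-chain used for stability counting, a synthetic
22-node network (14 variants, 8 phenotypes in four groups of ≥ 5 nodes, each
combining undirected variant pairs, a chain V → T_a → T_b and a collider
T_a → T_b ← V′), and a synthetic 4-node outlier-demonstration truth
(V1 → T1 → T2 plus an unrelated phenotype T3). The two larger graphs are
reconstructions built to exhibit the structural features the replication
experiments require — module structure, chain/collider motifs, undirected
variant pairs, a phenotype whose associations exist only through
contamination — not copies of any external dataset.

Two structural pitfalls were deliberately avoided in the 22-node graph and
are worth knowing about as general phenomena. With all edge coefficients
equal to γ = 1, (a) two correlated variants sharing a child make the
variant–variant partial correlation given that child *exactly* zero (an
unfaithful parameterization: the skeleton search then correctly-by-its-lights
deletes a true edge), and (b) the triangle V → T_a, V → T_b, T_a → T_b makes
the V–T_a partial correlation given T_b vanish the same way. Equal-coefficient
simulations of such motifs are not a fair test of any constraint-based
learner.

## What the simulations do and do not show

The generator produces exactly the world the model assumes: linear effects,
Gaussian noise, no hidden confounding, no linkage disequilibrium between
variants, independent samples. Passing the replication suite shows the
algorithm recovers what is recoverable under those assumptions (including
the designed failure modes: weak-signal collider misses, classic-mode false
colliders, Markov-equivalent ambiguity); it does not certify performance on
real expression data, where nonlinearity, hidden confounders, correlated
variants, and non-Gaussian noise all violate the premises. Conditioning on a
*discretized* mediator retains residual dependence when binning is coarse —
with 2–3 levels and n ≥ 1000 the G² search keeps a chain's endpoint edge;
four or more levels condition finely enough.

## Numerical and design choices

* Conditioning sets are drawn from the neighborhood of the lexicographically
  smaller endpoint only; subsets are enumerated in canonical combinatorial
  order; the maximum conditioning-set size is configurable (unlimited by
  default).
* Weighted recall/precision: a true edge recovered with the wrong
  orientation state — wrong direction, or directed vs undirected in either
  combination — earns weight w (default 0.5); undirected matching undirected
  earns full credit. Precision of an empty inferred graph is defined as 0 so
  sweep aggregation stays total. An `ignore_vv_direction` flag treats any
  variant–variant edge as undirected in both graphs before scoring, for
  comparisons against methods that orient such edges.
* aSHD: 1.0 per presence/absence mismatch, 0.5 per orientation-state
  mismatch on a shared adjacency.
* Module clustering: shortest-path distances ignoring orientation, with the
  node count as a finite sentinel for disconnected pairs; average-linkage
  agglomeration (configurable); the dendrogram is cut at the height
  maximizing the number of clusters of at least `min_size` nodes (ties break
  toward assigning more nodes), smaller clusters are left unassigned
  (module 0).
* Replicate r of a sweep uses an RNG seeded from (master seed, r), so any
  replicate is reproducible in isolation; sweeps parallelize only across
  replicates, never inside one inference, which would scramble the online
  threshold stream.
* Problem sizes in the test suite and acceptance script — 200 replicates for
  the three-node models (500 for the weak-signal classic case), 100 for the
  22-node network, 20 datasets × 20 permutations for stability, 50 for the
  outlier experiment — give Monte-Carlo standard errors well inside the
  tolerances being checked while keeping a full run to a few minutes.

## Known limitations

* No mixed continuous–discrete tests; a dataset is analyzed as all-Gaussian
  or all-categorical.
* The robust estimator assumes the phenotype block is elliptically
  distributed apart from contamination; it needs n ≥ p + 2.
* Large dense graphs make the sequential test count — and with it the LOND
  threshold decay — grow quickly; inference becomes conservative, retaining
  only strongly supported edges.
* The classic mode reproduces the sepset decision rule of pcalg-style PC but
  not its order sensitivity (the canonical pipeline removes it), so
  node-order instability of classical implementations is out of scope.
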