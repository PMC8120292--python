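# mrdag

Constraint-based causal graph learning for genomic data that mixes genetic
variants (genotypes) with molecular phenotypes such as gene expression.

## The problem

Gene regulatory relationships can be represented as a causal graph: an edge
X → Y says X regulates Y. Constraint-based structure learners of the PC
family infer such graphs from observational data by testing marginal and
conditional independence between pairs of variables, but generic
implementations suffer from three well-known problems:

1. they control only the per-test type-I error, not the overall error rate
   over the (unknown, data-dependent) number of tests performed;
2. they decide v-structures (colliders X → Y ← Z) from the *separating set*
   alone, claiming a collider whenever Y is absent from it — even when the
   X–Z edge was removed by a test that never conditioned on Y, so no
   conditional evidence exists either way;
3. their output can depend on the order in which variables appear in the
   input file.

`mrdag` addresses all three, and additionally exploits the **principle of
Mendelian randomization (PMR)**: alleles are randomized at meiosis, so a
genetic variant acts as a natural instrument and an edge between a variant V
and a phenotype T can only point V → T, while an edge between two variants is
left undirected.

## The algorithm

**Step I — skeleton.** Starting from the complete graph, test each adjacent
pair (i, j) for independence given conditioning sets S of size 0, 1, 2, …
drawn from the current neighborhood (adjacencies frozen within each level, as
in stable PC). Continuous data use the Fisher z test of the (partial)
correlation, with statistic √(n − |S| − 3)·|atanh ρ̂|; categorical data use
the G² likelihood-ratio test. A non-rejected test removes the edge and
records S as the pair's separating set.

Each test t receives its own significance threshold from the **LOND** rule
(significance Levels based On the Number of Discoveries), controlling the
overall false discovery rate online:

    α_t = β_t · (D(t−1) + 1),   Σ_t β_t = α,

where D(t−1) counts rejections so far and β_t ∝ 1 / (t ln² t) by default
(target FDR α = 0.05).

**Step II — orientation.**
1. Direct every variant–phenotype edge toward the phenotype; leave
   variant–variant edges undirected (PMR).
2. For every triplet X − Y − Z with X, Z non-adjacent, decide the collider
   X → Y ← Z from the test X ⟂ Z | {Y}. If Step I never ran that exact test,
   **run it now** (consuming the next LOND threshold) instead of guessing
   from the separating set.
3. Iteratively orient remaining undirected edges when exactly one direction
   is consistent with the recorded tests (chain propagation, cycle
   avoidance), never creating an untested collider. Markov-equivalent
   ambiguities — e.g. V → T1, V → T2 with T1 − T2, whose two completions are
   indistinguishable — stay undirected.

All enumeration (pairs, subsets, triplets) follows the lexicographic label
order, so the inferred graph is **invariant to the column order** of the
input. A `classic` mode implements the sepset-based CPDAG rule plus Meek
propagation for side-by-side comparison, faithfully including its
false-collider artifact.

The package also ships a simulator (linear-Gaussian structural equations;
Hardy–Weinberg genotypes with P(V=0,1,2) = ((1−q)², 2q(1−q), q²); 50:50
per-sample mixtures for undirected phenotype edges; outlier injection;
quantile discretization), evaluation metrics (weighted recall/precision with
0.5 credit for wrongly oriented edges, adjusted structural Hamming distance),
a robust correlation estimator that downweights outlying samples, node-order
stability counting, and distance-based module clustering.

## Worked example

Simulate one dataset (n = 1000) from the chain V1 → T1 → T2 (V1 a variant
with allele frequency 0.45, unit-variance noise, effect size γ = 1), infer
the graph, and compare it with the truth:

```
$ mrdag simulate --truth M1 --gamma 1.0 --n 1000 --reps 1 --seed 3 --out demo
$ mrdag infer --input demo/data_0000.tsv --n-genotypes 1 \
      --output demo/inferred.tsv --ledger demo/ledger.tsv
2 edges, 6 tests -> demo/inferred.tsv
$ mrdag eval --truth demo/truth.tsv --inferred demo/inferred.tsv
recall	precision	ashd
1.0000	1.0000	0.00
```

The ledger records every test with its online threshold — note the edge
T2–V1 surviving the marginal test (row 3) and falling to the conditional
test given T1 (last row), which records {T1} as the separating set:

```
a	b	size	S	estimate	p	threshold	rejected
T1	T2	0		0.735	1.6e-193	0.0253	1
T1	V1	0		0.551	3.2e-85	0.0253	1
T2	V1	0		0.431	6.5e-48	0.0101	1
T1	T2	1	V1	0.661	7.9e-139	0.0063	1
T1	V1	1	T2	0.383	3.9e-37	0.0047	1
T2	V1	1	T1	0.045	0.153	0.0038	0
```

A replicate sweep reports mean (sd) weighted recall and precision per signal
strength:

```
$ mrdag sweep --model M1 --gammas 1.0,0.5,0.2 --reps 50 --n 1000 --seed 7
gamma	recall_mean	recall_sd	precision_mean	precision_sd
1.0	1.0000	0.0000	1.0000	0.0000
0.5	1.0000	0.0000	1.0000	0.0000
0.2	0.9700	0.1485	0.9800	0.0990
```

Recovery is essentially perfect at strong and moderate signal and degrades
gracefully at weak signal, where the faint conditional dependencies fall
below the online thresholds.

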