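# Methods

## Problem and model

`lac` addresses associative classification of entities described by
binary features — typically compounds described by MACCS/MDL fingerprint
bits or by dichotomized bioassay readouts — where features differ in
importance but no feature weights are supplied with the data. The
pipeline has four stages: (1) derive per-feature weights by link analysis
of the class-split bipartite compound–feature graph; (2) mine frequent
itemsets under the adjusted weighted support; (3) turn frequent itemsets
into class association rules; (4) rank and prune them into a CBA rule
list that classifies by first match.

## Link-based feature weighting

A labeled dataset is an undirected bipartite graph: an edge joins
transaction *t* and feature *f* iff *f* ∈ *t*. Features act as
authorities, transactions as hubs: a good feature occurs in many good
transactions and vice versa. The graph splits into an active subsystem
(transactions of the chosen positive class, incidence `L_a`) and an
inactive one (`L_b`). Authority scores are the fixed point of

    x ∝ c_a · A_a(x) + c_b · A_b(x),    (c_a, c_b) from the class factor β,

iterated from the uniform vector with L1 renormalization per step until
the L1 change is below `tol` (default 1e-8) or `max_iter` (1000) steps.

Three authority operators are available per subsystem (with `L` the
subsystem incidence, `D_out` its transaction-degree diagonal and `D_in`
its feature-degree diagonal, pseudo-inverted at zero degree):

| variant    | A(x)                                              | character |
|------------|---------------------------------------------------|-----------|
| `hits`     | `Lᵀ L x`                                          | raw mutual reinforcement; dominated by the largest community |
| `pagerank` | `α · D_in⁻¹ Lᵀ D_out⁻¹ L x̂ + (1−α) · u`          | fully normalized two-step random walk with uniform teleport `u` over supported features; `x̂` is the L1-normalized input and the zero vector maps to zero |
| `unified`  | `D_in^{-1/2} Lᵀ D_out⁻¹ L D_in^{-1/2} x`          | symmetric normalization interpolating between the two; **default** |

For the `unified` variant the mixing coefficients are `√β` and `√(1−β)`,
matching its square-root degree scaling; the other variants use `β` and
`1−β` directly. β defaults to 0.9: any β > 0.5 promotes features whose
connections are predominantly active, and 0.9 weights the active system
strongly while still letting the inactive system damp features common to
both classes.

Numerical conventions: features with zero in-degree receive weight
exactly 0 (they carry no link evidence); transactions with empty itemsets
are dropped with a logged count; the converged vector is rescaled to
**mean one** by default so that weighted supports share the scale of
classical supports (L1 normalization is available). The iteration is
fully deterministic. Hub scores are exposed (`hub_scores`) for
diagnostics but never become item weights.

Known degeneracy: the fully normalized `pagerank` operator
`D_in⁻¹ Lᵀ D_out⁻¹ L` has the constant vector as an exact fixed point
whenever all subsystem in-degrees are positive (it is a similarity
transform of the SALSA column-stochastic matrix, whose stationary vector
is in-degree proportional), so that variant returns near-uniform weights
on well-connected graphs. This is a known property of full normalization
in link analysis, and is why `unified` — which retains degree contrast —
is the default.

Baselines: `frequency_weights` (weight ∝ occurrence count, mean-one) and
`uniform_weights` (all 1), the latter reducing the whole pipeline to
classical CBA.

## Weighted association rule mining

Itemset weight is the arithmetic mean of member weights; weighted support
`WS` multiplies it by classical support; transaction weight is the sum of
member weights; adjusted weighted support `AWS` is the transaction-weight
mass of supporting transactions over total mass. Mean-for-itemsets and
sum-for-transactions are the unique simple combination reproducing the
bundled worked example's support table.

`WS` is not monotone under inclusion, so the Apriori miner refuses to
prune with it (`support_mode="weighted"` raises; an exhaustive
`enumerate_frequent_itemsets` scan serves small universes instead). `AWS`
is monotone, so level-wise mining is exact; this is verified against a
powerset-enumeration oracle on universes up to 12 items.

Mining details: candidates of size k join frequent (k−1)-sets sharing a
(k−2)-prefix under the dataset's canonical item order (tie-free and
deterministic); an itemset must occur in at least one transaction to be
frequent, so a threshold of 0 yields exactly the supported itemsets;
defaults are `max_len` 4 (counting the antecedent only, not the class
consequent) and a cumulative candidate budget of 200 000, exceeded
budgets truncating deeper levels with a logged warning rather than
aborting.

Two cells of the conventional printed version of the worked example's
support table are internally inconsistent with these definitions (the WS
of {83,84} and the AWS of {83}); every other cell reproduces exactly, and
the package's own table is the computed one. The WS of {81,83,84}
computes to 16/45 ≈ 0.3556, conventionally printed as 0.35 (truncated).

## Class association rules and the classifier

Class labels are modeled as virtual items `class:<label>` appended to
each transaction before mining, weighted with the mean plain-item weight
(1 under mean-one), so rule support is simply `AWS(X ∪ {c})` from the
same engine and all transaction weights shift by the same constant.
Augmented mining runs one level deeper than `max_len` so maximal
antecedents still pair with their class marker. Confidence is
`AWS(X ∪ {c}) / AWS(X)`, the transaction-weight analogue of conditional
probability; with uniform weights it is not numerically identical to the
count ratio (each matching transaction is weighted by its size + 1) but
coincides in all equal-size constructions and reduces to classical CBA
behavior.

Ranking is by confidence, then support, then generation order (earlier =
shorter-or-equal antecedent). Pruning is CBA database coverage (M1): a
ranked rule is kept iff it correctly classifies at least one uncovered
training row; all rows it matches become covered; after each kept rule
the majority class of the uncovered remainder and the running training
error are recorded, and the kept list is truncated at the error-minimal
prefix (earliest on ties), with that stage's majority default appended.
Majority ties break toward the globally more frequent class, then class
order. Pessimistic-error pruning (an optional CBA refinement) is not
implemented. Prediction is first match, falling through to the default
class.

## Evaluation protocol

`cross_validate` partitions rows into k seeded folds (default 10),
stratified by class by default — stratification stabilizes small minority
classes; plain random folds are available. Weights, miner and classifier
are fit on each training split only; `weights_on="full"` exists as an
explicit opt-in for computing weights once on all rows (a deliberate
leakage trade-off some workflows accept). Accuracy is correct/total on
the held-out fold. `compare_weights` reports Pearson and Spearman
(average-rank ties) agreement of two weight vectors plus a per-item rank
table; zero-variance input yields NaN with `defined=False`.

## Synthetic data

The generator emulates sparse binary fingerprint data: each transaction
draws a class (balance 0.5 by default), includes each of `n_items`
(default 20) background items independently (probability 0.1 by default,
reflecting the sparsity of structural-key fingerprints), then inserts
planted antecedents per class with a given penetrance. A separate helper
inserts a single item at different rates in positive and negative rows to
construct class-skew test pairs. Defaults of 200 transactions keep
10-fold evaluation meaningful at desk scale. One seeded stream with a
documented draw order (class, background vector, planted rules, in that
order per transaction) makes regeneration bit-stable.

What the generator does **not** emulate: correlated fingerprint bits
beyond planted co-occurrence, realistic bit marginal distributions,
class-dependent background structure, or label noise. Passing tests on
this data demonstrate correctness of the algorithms under their stated
assumptions, not predictive performance on real chemical datasets; real
fingerprint or bioassay data is consumed through the `itemlist`/
`bitstring` readers.

## Problem sizes used in the test and acceptance runs

The worked example is 6 transactions × 5 items (exact arithmetic). Oracle
equivalences use random instances of ≤ 12 items / ≤ 15 transactions
(mining) and ≤ 8 × 8 incidence (eigendecomposition). Property suites use
1 000 monotonicity draws and 300–500-row synthetic datasets; recovery
tests use 100–500 rows. These sizes are chosen so that the independent
brute-force oracles remain exact and the whole suite runs in seconds.

## Known limitations

- The `pagerank` variant degeneracy described above.
- HITS (β = 1, `hits`) inherits classic HITS instability: the principal
  eigenvector can be dominated by the largest dense block.
- `AWS` of rare-but-heavy itemsets depends on overall transaction mass,
  so minsup thresholds are not directly comparable across weighting
  schemes with different normalizations; mean-one normalization mitigates
  this.
- The exhaustive WS scan is exponential in the number of observed items
  and intended only for small universes.
- Multi-class data is supported (one-vs-rest in the graph split; any
  number of class labels in rules), but the class factor machinery is
  designed around a binary active/inactive split.
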