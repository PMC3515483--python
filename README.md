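# lac — link-based associative classification

`lac` builds interpretable rule-list classifiers from binary-feature
datasets — chemical fingerprints (MACCS/MDL public keys), discretized
bioassay panels, or any transaction data — while weighting features by
**link analysis** instead of treating them as equally important.

Classical associative classification (CBA) mines rules `X → c` whose
antecedent `X` is an itemset and whose consequent is a class label, ranks
them by confidence/support, and classifies by first match. It ignores
that some fingerprint bits matter far more than others. Weighted
association rule mining fixes that, but needs a weight per feature — and
most datasets ship none. `lac` derives the weights from the dataset
itself: the data is a bipartite graph (compounds ↔ features), features
are *authorities* and compounds are *hubs* in the HITS sense, and a
power iteration over a HITS/PageRank-style operator family yields a
nonnegative authority score per feature. The graph is split into an
"active" and an "inactive" subsystem by class label and the two are mixed
with a class factor β (default 0.9), so features connected mostly to
active compounds are promoted.

## The statistics at the core

For an itemset *is* over transactions *T* with item weights *w*:

- itemset weight  `W(is) = mean_{i∈is} w_i`
- weighted support  `WS(is) = W(is) · |{t ⊇ is}| / |T|`
- transaction weight  `tw(t) = Σ_{i∈t} w_i`
- **adjusted weighted support**  `AWS(is) = Σ_{t ⊇ is} tw(t) / Σ_{t∈T} tw(t)`

`WS` violates the downward closure property (a superset can be frequent
while its subset is not), which breaks Apriori pruning; `AWS` is monotone
under inclusion, so level-wise mining stays exact. Rule confidence is the
AWS ratio `AWS(X ∪ {c}) / AWS(X)`; rules are ranked and pruned by the CBA
database-coverage procedure with a default class.

## Worked example

The bundled six-compound fingerprint example (`lac.fixture_table1()`):
compounds C1–C6 over bits 81–85 with weights
{81: 0.8, 82: 1, 83: 0.8, 84: 1.6, 85: 1}.

```python
from lac import fixture_table1, MiningConfig, mine_frequent_itemsets, itemset_stats

ds, w = fixture_table1()
for s in ({"81"}, {"81", "83"}, {"81", "83", "84"}):
    st = itemset_stats(s, ds, w)
    print(sorted(s), round(st.classical_support, 2),
          round(st.weighted_support, 2), round(st.adjusted_weighted_support, 2))
```

prints

```
['81'] 0.67 0.53 0.75
['81', '83'] 0.33 0.27 0.44
['81', '83', '84'] 0.33 0.36 0.44
```

At a support threshold of 0.3 this exhibits the closure failure of plain
weighted support: `{81,83}` is infrequent under WS (0.27 < 0.3) while its
superset `{81,83,84}` is frequent (0.36) — so subset pruning would wrongly
discard it — whereas under AWS all three sets sit at 0.44 ≥ 0.3 and
Apriori mining is sound (`mine_frequent_itemsets(ds, w,
MiningConfig(minsup=0.3))` returns all of them).

On synthetic data with planted rules the full pipeline looks like:

```python
from lac import synthetic as syn
from lac import MiningConfig, cross_validate, compare_weights, weights_for_scheme, frequency_weights

cfg = syn.SynthConfig(n_transactions=300, n_items=12, seed=7, background_item_prob=0.15,
                      planted_rules=(syn.PlantedRule(frozenset({"f1", "f2"}), "pos", 0.9),
                                     syn.PlantedRule(frozenset({"f5"}), "neg", 0.8)))
ds = syn.generate(cfg)
report = cross_validate(ds, k=10, seed=1, scheme="link",
                        mining_config=MiningConfig(minsup=0.1, minconf=0.6))
print(round(report.mean_accuracy, 3))                     # 0.92
cmp = compare_weights(weights_for_scheme(ds, "link"), frequency_weights(ds))
print(round(cmp.pearson, 3))                              # 0.947
```

The planted items `f1`/`f2` end up with link weights ≈ 1.78/1.75 versus
≈ 0.82 for background items, the 10-fold cross-validated accuracy is
0.92, and the link weights correlate strongly with plain occurrence
frequency while promoting class-informative bits.

## Command line

Every operation is also a `lac` subcommand (thin shells over the library):

```
lac synth   --n 300 --items 12 --plant "f1;f2->pos:0.9" --seed 7 --output data.csv
lac weights --input data.csv --scheme link --beta 0.9 --output weights.tsv
lac mine    --input data.csv --weights weights.tsv --minsup 0.1 --output itemsets.tsv
lac train   --input data.csv --scheme link --minsup 0.1 --minconf 0.6 --model-out model.txt
lac predict --model model.txt --input data.csv --output predictions.tsv
lac cv      --input data.csv --scheme link --k 10 --seed 1 --report report.txt
```

Defaults mirror the standard settings (β = 0.9, max rule length 4,
candidate budget 200 000); a flat key=value `--config` file can supply
any of them.

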