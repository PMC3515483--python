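"""Class association rules and the CBA-style rule-list classifier.

Class labels are modeled as *virtual items*: each labeled transaction is
augmented with a marker item ``class:<label>`` before mining, so a rule's
support is simply the adjusted weighted support of ``X ∪ {class marker}``
and one mining engine serves both plain itemsets and rules.  Virtual class
items carry the mean item weight (1 under mean-one normalization) so they
shift every transaction's weight by the same amount and do not distort the
relative transaction weights.

The classifier follows the classic CBA construction:

1. every frequent ``(X, c)`` pair with support >= minsup and confidence
   >= minconf becomes a candidate rule;
2. rules are ranked by confidence, then support, then generation order;
3. database-coverage pruning (M1): walking the ranked list, a rule is kept
   iff it correctly classifies at least one still-uncovered training row,
   and all rows it matches become covered;
4. the kept list is truncated at the prefix minimizing total training
   errors, with the majority class of the then-uncovered rows appended as
   the default class.

Prediction is first-match: the highest-precedence rule whose antecedent is
contained in the query itemset fires; otherwise the default class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .dataset_io import Transaction, TransactionDataset
from .linkrank import ItemWeights
from .warm import MiningConfig, WeightedItemsetStats, mine_frequent_itemsets

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_ITEM_PREFIX",
    "ClassAssociationRule",
    "RuleClassifier",
    "class_item",
    "augment_with_class_items",
    "generate_cars",
    "mine_cars",
    "rank_rules",
    "build_classifier",
    "predict",
    "train_classifier",
    "save_model",
    "load_model",
]

CLASS_ITEM_PREFIX = "class:"


def class_item(label: str) -> str:
    return CLASS_ITEM_PREFIX + label


@dataclass(frozen=True)
class ClassAssociationRule:
    """``antecedent -> consequent`` with support, confidence and birth order.

    ``support`` is the adjusted weighted support of antecedent ∪ class
    marker on the augmented dataset; ``confidence`` the AWS ratio
    ``AWS(X ∪ {c}) / AWS(X)``; ``gen_id`` the discovery index used as the
    final ranking tie-break (earlier = shorter-or-equal antecedent).
    """

    antecedent: frozenset[str]
    consequent: str
    support: float
    confidence: float
    gen_id: int

    def matches(self, itemset: frozenset[str]) -> bool:
        return self.antecedent <= itemset


@dataclass(frozen=True)
class RuleClassifier:
    """Precedence-ordered rule list plus a default class."""

    rules: tuple[ClassAssociationRule, ...]
    default_class: str
    training_accuracy: float

    def predict(self, itemset: Iterable[str]) -> str:
        return predict(self, itemset)


# ---------------------------------------------------------------------------
# rule generation
# ---------------------------------------------------------------------------


def augment_with_class_items(
    dataset: TransactionDataset, weights: ItemWeights
) -> tuple[TransactionDataset, ItemWeights]:
    """Append ``class:<label>`` marker items to every labeled transaction.

    Marker items are appended at the end of the item universe and weighted
    with the mean plain-item weight, so under mean-one normalized weights
    they carry weight 1.
    """
    if not dataset.is_labeled:
        raise ValueError("rule generation requires a fully labeled dataset")
    markers = tuple(class_item(c) for c in dataset.classes)
    clash = set(markers) & set(dataset.items)
    if clash:
        raise ValueError(f"item universe already contains class markers: {sorted(clash)}")
    aug = TransactionDataset(
        items=dataset.items + markers,
        classes=dataset.classes,
        transactions=tuple(
            Transaction(t.id, t.items | {class_item(t.label)}, t.label)
            for t in dataset.transactions
        ),
    )
    plain = [weights[i] for i in dataset.items]
    marker_w = sum(plain) / len(plain) if plain else 1.0
    aug_weights = ItemWeights(
        {**{i: weights[i] for i in dataset.items}, **{m: marker_w for m in markers}},
        normalization=None,
        provenance=weights.provenance,
        meta=dict(weights.meta),
    )
    return aug, aug_weights


def generate_cars(
    frequent: Sequence[WeightedItemsetStats],
    dataset: TransactionDataset,
    weights: ItemWeights,
    config: MiningConfig,
) -> list[ClassAssociationRule]:
    """Turn frequent itemsets over the class-augmented universe into rules.

    ``frequent`` must come from mining the augmented dataset (see
    :func:`augment_with_class_items`).  Every itemset holding exactly one
    class marker and a nonempty antecedent of at most ``max_len`` plain
    items yields a candidate rule; its confidence is the ratio of the
    itemset's AWS to its antecedent's AWS, i.e. the transaction-weight
    mass of matching rows of class c over the mass of all matching rows.
    Rules with confidence >= minconf survive, stamped with gen_id in
    discovery order.
    """
    if not dataset.is_labeled:
        raise ValueError("rule generation requires a fully labeled dataset")
    aws_of = {st.itemset: st.adjusted_weighted_support for st in frequent}
    markers = {class_item(c): c for c in dataset.classes}
    rules: list[ClassAssociationRule] = []
    gen_id = 0
    for st in frequent:
        found = [i for i in st.itemset if i in markers]
        if len(found) != 1:
            continue
        marker = found[0]
        antecedent = st.itemset - {marker}
        if not antecedent or len(antecedent) > config.max_len:
            continue
        ante_aws = aws_of.get(antecedent)
        if ante_aws is None:
            # AWS is monotone, so a frequent rule itemset implies a frequent
            # antecedent unless the candidate budget truncated that level.
            continue
        confidence = st.adjusted_weighted_support / ante_aws if ante_aws > 0 else 0.0
        if confidence >= config.minconf:
            rules.append(
                ClassAssociationRule(
                    antecedent=antecedent,
                    consequent=markers[marker],
                    support=st.adjusted_weighted_support,
                    confidence=confidence,
                    gen_id=gen_id,
                )
            )
            gen_id += 1
    return rules


def mine_cars(
    dataset: TransactionDataset,
    weights: ItemWeights,
    config: MiningConfig = MiningConfig(),
) -> list[ClassAssociationRule]:
    """Mine class association rules in one call: augment, mine, generate.

    The augmented mining depth is ``max_len + 1`` so antecedents of up to
    ``max_len`` items still fit together with the class marker.
    """
    aug, aug_weights = augment_with_class_items(dataset, weights)
    aug_config = replace(config, max_len=config.max_len + 1)
    frequent = mine_frequent_itemsets(aug, aug_weights, aug_config)
    return generate_cars(frequent, dataset, weights, config)


# ---------------------------------------------------------------------------
# ranking, pruning, prediction
# ---------------------------------------------------------------------------


def rank_rules(rules: Iterable[ClassAssociationRule]) -> list[ClassAssociationRule]:
    """CBA precedence: confidence desc, support desc, then earliest gen_id."""
    return sorted(rules, key=lambda r: (-r.confidence, -r.support, r.gen_id))


def _majority(
    labels: Iterable[str], class_order: Sequence[str], global_counts: Counter
) -> str:
    counts = Counter(labels)
    if not counts:
        counts = global_counts
    best = max(counts.values())
    tied = [c for c, v in counts.items() if v == best]
    if len(tied) == 1:
        return tied[0]
    # break toward the globally more frequent class, then class order
    return max(tied, key=lambda c: (global_counts[c], -class_order.index(c)))


def build_classifier(
    rules: Sequence[ClassAssociationRule], dataset: TransactionDataset
) -> RuleClassifier:
    """Database-coverage (M1) pruning of a ranked rule list.

    ``rules`` must already be in precedence order.  See the module
    docstring for the construction.
    """
    if not dataset.is_labeled:
        raise ValueError("classifier construction requires a fully labeled dataset")
    labels = [t.label for t in dataset.transactions]
    global_counts = Counter(labels)
    n = len(labels)

    uncovered = set(range(n))
    kept: list[ClassAssociationRule] = []
    rule_errors = 0
    # candidate truncation points: (n_rules_kept, default_class, total_errors),
    # recorded after each kept rule per the CBA coverage walk
    stages: list[tuple[int, str, int]] = []
    for rule in rules:
        matched = [i for i in uncovered if rule.matches(dataset.transactions[i].items)]
        if not any(labels[i] == rule.consequent for i in matched):
            continue
        kept.append(rule)
        uncovered.difference_update(matched)
        rule_errors += sum(1 for i in matched if labels[i] != rule.consequent)
        default = _majority((labels[i] for i in uncovered), dataset.classes, global_counts)
        default_errors = sum(1 for i in uncovered if labels[i] != default)
        stages.append((len(kept), default, rule_errors + default_errors))
        if not uncovered:
            break

    if not stages:  # nothing kept: majority-default classifier
        default0 = _majority(labels, dataset.classes, global_counts)
        stages = [(0, default0, sum(1 for l in labels if l != default0))]
    best_k, best_default, _ = min(stages, key=lambda s: (s[2], s[0]))
    clf = RuleClassifier(tuple(kept[:best_k]), best_default, training_accuracy=0.0)
    correct = sum(
        1 for t in dataset.transactions if predict(clf, t.items) == t.label
    )
    return replace(clf, training_accuracy=correct / n if n else 1.0)


def predict(classifier: RuleClassifier, itemset: Iterable[str]) -> str:
    """First-match classification: highest-precedence matching rule wins."""
    s = frozenset(itemset)
    for rule in classifier.rules:
        if rule.matches(s):
            return rule.consequent
    return classifier.default_class


def train_classifier(
    dataset: TransactionDataset,
    weights: ItemWeights,
    config: MiningConfig = MiningConfig(),
) -> RuleClassifier:
    """Full pipeline on a labeled dataset: mine CARs, rank, prune."""
    ranked = rank_rules(mine_cars(dataset, weights, config))
    return build_classifier(ranked, dataset)


# ---------------------------------------------------------------------------
# model persistence (structured text)
# ---------------------------------------------------------------------------


def save_model(classifier: RuleClassifier, path) -> None:
    """Write the ordered rule list + default class as a small text file."""
    with open(path, "w") as fh:
        fh.write("#lac-model\tv1\n")
        fh.write(f"default\t{classifier.default_class}\n")
        fh.write(f"training_accuracy\t{classifier.training_accuracy!r}\n")
        for r in classifier.rules:
            ante = ";".join(sorted(r.antecedent))
            fh.write(
                f"rule\t{ante}\t{r.consequent}\t{r.support!r}\t{r.confidence!r}\t{r.gen_id}\n"
            )


def load_model(path) -> RuleClassifier:
    default: Optional[str] = None
    accuracy = 0.0
    rules: list[ClassAssociationRule] = []
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != "#lac-model\tv1":
            raise ValueError(f"{path}: not a lac model file")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "default":
                default = fields[1]
            elif fields[0] == "training_accuracy":
                accuracy = float(fields[1])
            elif fields[0] == "rule":
                _, ante, cls, sup, conf, gid = fields
                rules.append(
                    ClassAssociationRule(
                        antecedent=frozenset(s for s in ante.split(";") if s),
                        consequent=cls,
                        support=float(sup),
                        confidence=float(conf),
                        gen_id=int(gid),
                    )
                )
    if default is None:
        raise ValueError(f"{path}: model file has no default class")
    return RuleClassifier(tuple(rules), default, accuracy)
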