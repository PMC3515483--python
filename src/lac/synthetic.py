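"""Seeded generators for class-labeled transaction datasets.

Two controlled structures cover the properties the pipeline is supposed to
detect:

* *planted rules* — an antecedent itemset inserted into transactions of a
  given class with a given penetrance, on top of independent background
  item noise.  A planted deterministic rule (penetrance 1, no background)
  must be recovered by the full pipeline with confidence 1.
* *class-skewed items* — an item appearing at different rates in positive
  and negative transactions, the situation in which link weighting with a
  class factor above 0.5 should promote the active-skewed item over a
  matched inactive-skewed one.

All randomness flows through one ``numpy`` generator seeded from the
config, with a fixed draw order (per transaction: class, then background
vector, then planted rules in listed order), so regeneration is bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import Transaction, TransactionDataset

__all__ = [
    "PlantedRule",
    "SynthConfig",
    "generate",
    "add_class_skewed_item",
    "generate_class_skewed_feature",
]

POSITIVE, NEGATIVE = "pos", "neg"


@dataclass(frozen=True)
class PlantedRule:
    """Insert ``antecedent`` into transactions of ``label`` w.p. ``penetrance``."""

    antecedent: frozenset[str]
    label: str
    penetrance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")


@dataclass(frozen=True)
class SynthConfig:
    """Shape of a synthetic dataset.

    n_transactions : number of rows (default 200, comfortably above the
        10 folds of the standard evaluation protocol).
    n_items : background item universe size ``f1 … fN`` (default 20, the
        scale of a fingerprint fragment while keeping exhaustive oracles
        cheap).
    class_balance : probability of the positive class (default 0.5).
    planted_rules : rules inserted on top of the background noise.
    background_item_prob : independent inclusion probability of each
        background item (default 0.1, sparse transactions as in
        fingerprint data).
    seed : generator seed.
    """

    n_transactions: int = 200
    n_items: int = 20
    class_balance: float = 0.5
    planted_rules: tuple[PlantedRule, ...] = ()
    background_item_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transactions < 0 or self.n_items < 0:
            raise ValueError("sizes must be nonnegative")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if not 0.0 <= self.background_item_prob <= 1.0:
            raise ValueError("background_item_prob must be in [0, 1]")
        universe = {f"f{i}" for i in range(1, self.n_items + 1)}
        for rule in self.planted_rules:
            if not rule.antecedent <= universe:
                raise ValueError(
                    f"planted antecedent {sorted(rule.antecedent)} outside universe"
                )
            if rule.label not in (POSITIVE, NEGATIVE):
                raise ValueError(f"planted rule label must be {POSITIVE!r} or {NEGATIVE!r}")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(f"f{i}" for i in range(1, self.n_items + 1))


def generate(config: SynthConfig) -> TransactionDataset:
    """Draw a labeled dataset per ``config`` (reproducible given the seed)."""
    rng = np.random.default_rng(config.seed)
    items = config.items
    transactions = []
    for t in range(config.n_transactions):
        label = POSITIVE if rng.random() < config.class_balance else NEGATIVE
        mask = rng.random(config.n_items) < config.background_item_prob
        itemset = {f for f, m in zip(items, mask) if m}
        for rule in config.planted_rules:
            if rule.label == label and rng.random() < rule.penetrance:
                itemset |= rule.antecedent
        transactions.append(Transaction(f"t{t + 1}", frozenset(itemset), label))
    return TransactionDataset(items, (POSITIVE, NEGATIVE), tuple(transactions))


def add_class_skewed_item(
    dataset: TransactionDataset,
    item: str,
    active_rate: float,
    inactive_rate: float,
    seed: int,
    positive_class: str = POSITIVE,
) -> TransactionDataset:
    """Insert ``item`` with class-dependent rates into an existing dataset.

    The item appears with probability ``active_rate`` in transactions of
    ``positive_class`` and ``inactive_rate`` elsewhere.  Composable:
    inserting two matched items with swapped rates (different seeds)
    builds the paired construction used to test class-factor promotion.
    """
    for rate in (active_rate, inactive_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    if item in dataset.items:
        raise ValueError(f"item {item!r} already in the universe")
    rng = np.random.default_rng(seed)
    transactions = []
    for t in dataset.transactions:
        rate = active_rate if t.label == positive_class else inactive_rate
        itemset = t.items | {item} if rng.random() < rate else t.items
        transactions.append(Transaction(t.id, itemset, t.label))
    return TransactionDataset(dataset.items + (item,), dataset.classes, tuple(transactions))


def generate_class_skewed_feature(
    config: SynthConfig,
    item: str,
    active_rate: float,
    inactive_rate: float,
) -> TransactionDataset:
    """Background dataset from ``config`` plus one class-skewed item.

    The skewed item's draws use a seed offset from ``config.seed`` so the
    background is identical to :func:`generate`'s output for the same
    config.
    """
    return add_class_skewed_item(
        generate(config), item, active_rate, inactive_rate, seed=config.seed + 1
    )
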