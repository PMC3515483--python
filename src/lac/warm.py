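"""Weighted association rule mining with the adjusted weighted support.

Definitions, for an itemset ``is`` over a dataset ``T`` with per-item
weights ``w``:

* itemset weight        ``W(is) = mean_{i in is} w_i``
* classical support     ``sup(is) = |{t : is ⊆ t}| / |T|``
* weighted support      ``WS(is) = W(is) · sup(is)``
* transaction weight    ``tw(t)  = Σ_{i in t} w_i``
* adjusted weighted support
                        ``AWS(is) = Σ_{t ⊇ is} tw(t) / Σ_{t in T} tw(t)``

``WS`` violates the downward closure property (DCP): a superset can gain
weight and pass a threshold its subsets fail, which makes level-wise
(Apriori) pruning unsound.  ``AWS`` is monotone under inclusion — every
transaction containing a superset contains the subset — so DCP holds and
Apriori mining is exact.  :func:`mine_frequent_itemsets` therefore refuses
``support_mode="weighted"``; use :func:`enumerate_frequent_itemsets` (an
exhaustive scan) for small universes when WS-frequent sets are wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .dataset_io import TransactionDataset
from .linkrank import ItemWeights

logger = logging.getLogger(__name__)

__all__ = [
    "MiningConfig",
    "WeightedItemsetStats",
    "itemset_weight",
    "classical_support",
    "weighted_support",
    "transaction_weight",
    "adjusted_weighted_support",
    "itemset_stats",
    "mine_frequent_itemsets",
    "enumerate_frequent_itemsets",
]

_SUPPORT_MODES = ("classical", "weighted", "adjusted")


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and budgets of the miner.

    minsup, minconf : support / confidence thresholds in [0, 1].
    max_len : maximum antecedent length (default 4).
    max_candidates : cumulative candidate-itemset budget across all Apriori
        levels (default 200 000); exceeding it truncates deeper levels
        rather than aborting.
    support_mode : which support the frequency test uses — ``adjusted``
        (default), ``classical``, or ``weighted`` (exhaustive scan only).
    """

    minsup: float = 0.2
    minconf: float = 0.7
    max_len: int = 4
    max_candidates: int = 200_000
    support_mode: str = "adjusted"

    def __post_init__(self) -> None:
        if not 0.0 <= self.minsup <= 1.0:
            raise ValueError("minsup must be in [0, 1]")
        if not 0.0 <= self.minconf <= 1.0:
            raise ValueError("minconf must be in [0, 1]")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")
        if self.support_mode not in _SUPPORT_MODES:
            raise ValueError(f"support_mode must be one of {_SUPPORT_MODES}")


@dataclass(frozen=True)
class WeightedItemsetStats:
    """All three support flavors of one itemset."""

    itemset: frozenset[str]
    itemset_weight: float
    classical_support: float
    weighted_support: float
    adjusted_weighted_support: float

    def support(self, mode: str) -> float:
        if mode == "classical":
            return self.classical_support
        if mode == "weighted":
            return self.weighted_support
        if mode == "adjusted":
            return self.adjusted_weighted_support
        raise ValueError(f"unknown support mode {mode!r}")


# ---------------------------------------------------------------------------
# point measures
# ---------------------------------------------------------------------------


def itemset_weight(itemset: Iterable[str], weights: ItemWeights) -> float:
    """Arithmetic mean of the member item weights; itemset must be nonempty."""
    items = list(itemset)
    if not items:
        raise ValueError("itemset weight of the empty set is undefined")
    try:
        return sum(weights[i] for i in items) / len(items)
    except KeyError as exc:
        raise ValueError(f"item {exc.args[0]!r} has no weight") from None


def classical_support(itemset: Iterable[str], dataset: TransactionDataset) -> float:
    """Fraction of transactions containing the itemset (1 for the empty set)."""
    if dataset.n_transactions == 0:
        raise ValueError("support over an empty dataset is undefined")
    s = frozenset(itemset)
    count = sum(1 for t in dataset.transactions if s <= t.items)
    return count / dataset.n_transactions


def weighted_support(
    itemset: Iterable[str], dataset: TransactionDataset, weights: ItemWeights
) -> float:
    """``W(is) × sup(is)``.  Not monotone under inclusion."""
    s = frozenset(itemset)
    return itemset_weight(s, weights) * classical_support(s, dataset)


def transaction_weight(t: Iterable[str], weights: ItemWeights) -> float:
    """Sum of the weights of the items in ``t``; empty transaction -> 0."""
    try:
        return sum(weights[i] for i in t)
    except KeyError as exc:
        raise ValueError(f"item {exc.args[0]!r} has no weight") from None


def adjusted_weighted_support(
    itemset: Iterable[str], dataset: TransactionDataset, weights: ItemWeights
) -> float:
    """Transaction-weight mass of supporting transactions over total mass.

    Monotone under itemset inclusion, hence safe for Apriori pruning.
    ``AWS(∅) = 1`` by convention.
    """
    if dataset.n_transactions == 0:
        raise ValueError("support over an empty dataset is undefined")
    s = frozenset(itemset)
    total = 0.0
    supporting = 0.0
    for t in dataset.transactions:
        tw = transaction_weight(t.items, weights)
        total += tw
        if s <= t.items:
            supporting += tw
    if total <= 0.0:
        raise ValueError("all transaction weights are zero; AWS undefined")
    return supporting / total


def itemset_stats(
    itemset: Iterable[str], dataset: TransactionDataset, weights: ItemWeights
) -> WeightedItemsetStats:
    """Compute all support flavors of one itemset."""
    s = frozenset(itemset)
    return WeightedItemsetStats(
        itemset=s,
        itemset_weight=itemset_weight(s, weights),
        classical_support=classical_support(s, dataset),
        weighted_support=weighted_support(s, dataset, weights),
        adjusted_weighted_support=adjusted_weighted_support(s, dataset, weights),
    )


# ---------------------------------------------------------------------------
# mining
# ---------------------------------------------------------------------------


class _Context:
    """Precomputed per-dataset structures: tid-sets and transaction weights."""

    def __init__(self, dataset: TransactionDataset, weights: ItemWeights):
        self.order = list(dataset.items)
        self.n = dataset.n_transactions
        if self.n == 0:
            raise ValueError("cannot mine an empty dataset")
        self.tw = np.array(
            [transaction_weight(t.items, weights) for t in dataset.transactions]
        )
        self.total_tw = float(self.tw.sum())
        if self.total_tw <= 0:
            raise ValueError("all transaction weights are zero; AWS undefined")
        self.tids: dict[str, frozenset[int]] = {f: frozenset() for f in self.order}
        occurrences: dict[str, set[int]] = {f: set() for f in self.order}
        for idx, t in enumerate(dataset.transactions):
            for f in t.items:
                occurrences[f].add(idx)
        self.tids = {f: frozenset(v) for f, v in occurrences.items()}
        self.weights = weights

    def stats(self, items: tuple[str, ...], tidset: frozenset[int]) -> WeightedItemsetStats:
        s = frozenset(items)
        w = itemset_weight(s, self.weights)
        sup = len(tidset) / self.n
        aws = float(sum(self.tw[i] for i in tidset)) / self.total_tw
        return WeightedItemsetStats(s, w, sup, w * sup, aws)


def mine_frequent_itemsets(
    dataset: TransactionDataset,
    weights: ItemWeights,
    config: MiningConfig = MiningConfig(),
) -> list[WeightedItemsetStats]:
    """Level-wise (Apriori) mining of frequent itemsets.

    Candidates of size k are joins of frequent (k-1)-itemsets sharing a
    (k-2)-prefix under the dataset's canonical item order, kept only when
    all (k-1)-subsets are frequent.  An itemset is frequent when it occurs
    in at least one transaction and its support (``support_mode``) reaches
    ``minsup``.  Mining stops at ``max_len`` or when the cumulative
    candidate count exceeds ``max_candidates`` (truncation is logged).
    Output is sorted by (size, item order).

    ``support_mode="weighted"`` is refused: WS is not monotone under
    inclusion, so subset-based pruning would silently drop frequent
    supersets of infrequent sets.  Use :func:`enumerate_frequent_itemsets`.
    """
    if config.support_mode == "weighted":
        raise ValueError(
            "weighted support violates the downward closure property; "
            "level-wise pruning would be unsound.  Use "
            "enumerate_frequent_itemsets() for an exhaustive WS scan."
        )
    ctx = _Context(dataset, weights)
    pos = {f: i for i, f in enumerate(ctx.order)}

    results: list[WeightedItemsetStats] = []
    # level 1
    candidates_seen = len(ctx.order)
    frequent: dict[tuple[str, ...], frozenset[int]] = {}
    for f in ctx.order:
        tids = ctx.tids[f]
        if not tids:
            continue
        st = ctx.stats((f,), tids)
        if st.support(config.support_mode) >= config.minsup:
            frequent[(f,)] = tids
            results.append(st)

    truncated = False
    current = dict(frequent)
    k = 2
    while current and k <= config.max_len and not truncated:
        frequent_keys = set(current)
        keys = sorted(current, key=lambda t: [pos[i] for i in t])
        nxt: dict[tuple[str, ...], frozenset[int]] = {}
        for a_idx in range(len(keys)):
            if truncated:
                break
            for b_idx in range(a_idx + 1, len(keys)):
                a, b = keys[a_idx], keys[b_idx]
                if a[:-1] != b[:-1]:
                    break  # keys sorted, shared-prefix block exhausted
                cand = a + (b[-1],)
                if candidates_seen >= config.max_candidates:
                    logger.warning(
                        "candidate budget %d exhausted at level %d; deeper "
                        "levels truncated",
                        config.max_candidates,
                        k,
                    )
                    truncated = True
                    break
                candidates_seen += 1
                if any(
                    cand[:j] + cand[j + 1 :] not in frequent_keys
                    for j in range(len(cand))
                ):
                    continue
                tids = current[a] & current[b]
                if not tids:
                    continue
                st = ctx.stats(cand, tids)
                if st.support(config.support_mode) >= config.minsup:
                    nxt[cand] = tids
                    results.append(st)
        current = nxt
        k += 1

    results.sort(key=lambda st: (len(st.itemset), sorted(pos[i] for i in st.itemset)))
    return results


def enumerate_frequent_itemsets(
    dataset: TransactionDataset,
    weights: ItemWeights,
    config: MiningConfig = MiningConfig(),
) -> list[WeightedItemsetStats]:
    """Exhaustive frequent-itemset scan over all itemsets up to ``max_len``.

    Sound for every support mode (including the non-monotone ``weighted``)
    but exponential in the number of observed items; intended for small
    universes and as the oracle the Apriori miner is checked against.
    """
    ctx = _Context(dataset, weights)
    pos = {f: i for i, f in enumerate(ctx.order)}
    observed = [f for f in ctx.order if ctx.tids[f]]
    results: list[WeightedItemsetStats] = []
    for size in range(1, min(config.max_len, len(observed)) + 1):
        for combo in combinations(observed, size):
            tids = ctx.tids[combo[0]]
            for f in combo[1:]:
                tids = tids & ctx.tids[f]
                if not tids:
                    break
            if not tids:
                continue
            st = ctx.stats(combo, tids)
            if st.support(config.support_mode) >= config.minsup:
                results.append(st)
    results.sort(key=lambda st: (len(st.itemset), sorted(pos[i] for i in st.itemset)))
    return results
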