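"""Model assessment: k-fold cross-validation and weight-vector comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cba_classifier import predict, train_classifier
from .dataset_io import TransactionDataset
from .linkrank import (
    ItemWeights,
    LinkWeightConfig,
    build_bipartite,
    compute_link_weights,
    frequency_weights,
    uniform_weights,
)
from .warm import MiningConfig

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "WeightComparison",
    "kfold_indices",
    "weights_for_scheme",
    "cross_validate",
    "compare_weights",
]


@dataclass(frozen=True)
class EvalReport:
    """Per-fold and mean accuracy of a cross-validated pipeline."""

    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    config_snapshot: Mapping[str, object]
    seed: int

    @property
    def k(self) -> int:
        return len(self.fold_accuracies)


@dataclass(frozen=True)
class WeightComparison:
    """Pearson/Spearman agreement of two weight vectors plus a rank table.

    ``defined`` is False when either vector has zero variance, in which
    case both correlations are NaN.
    """

    pearson: float
    spearman: float
    defined: bool
    rank_table: pd.DataFrame = field(repr=False)


def kfold_indices(
    dataset: TransactionDataset,
    k: int,
    seed: int,
    stratified: bool = True,
) -> list[np.ndarray]:
    """Seeded partition of row indices into k disjoint covering folds.

    Stratified (default): within each class, shuffled indices are dealt
    round-robin across folds, so class proportions are stable even for
    small minority classes.  Plain: a global shuffle split into k chunks.
    """
    n = dataset.n_transactions
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available transactions")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratified and dataset.classes:
        labels = dataset.labels()
        offset = 0
        for cls in dataset.classes:
            idx = np.array([i for i, l in enumerate(labels) if l == cls], dtype=int)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                folds[(offset + j) % k].append(int(i))
            offset += len(idx)
    else:
        idx = rng.permutation(n)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def weights_for_scheme(
    dataset: TransactionDataset,
    scheme: str,
    positive_class: Optional[str] = None,
    link_config: Optional[LinkWeightConfig] = None,
) -> ItemWeights:
    """Compute item weights by scheme name: ``link | frequency | uniform``."""
    if scheme == "uniform":
        return uniform_weights(dataset)
    if scheme == "frequency":
        return frequency_weights(dataset)
    if scheme == "link":
        if positive_class is None:
            if not dataset.classes:
                raise ValueError("link weighting requires a labeled dataset")
            positive_class = dataset.classes[0]
        graph = build_bipartite(dataset, positive_class)
        return compute_link_weights(graph, link_config or LinkWeightConfig())
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def cross_validate(
    dataset: TransactionDataset,
    k: int = 10,
    seed: int = 0,
    scheme: str = "link",
    positive_class: Optional[str] = None,
    link_config: Optional[LinkWeightConfig] = None,
    mining_config: Optional[MiningConfig] = None,
    stratified: bool = True,
    weights_on: str = "train",
) -> EvalReport:
    """k-fold cross-validated accuracy of the full pipeline.

    For each fold, item weights, the miner and the classifier are fit on
    the training split only, and accuracy (correct / total) is measured on
    the held-out fold.  ``weights_on="full"`` instead computes the weight
    vector once on the entire dataset before splitting — an explicit
    leakage trade-off some workflows accept for stability; the default is
    strictly leakage-free.
    """
    if not dataset.is_labeled:
        raise ValueError("cross-validation requires a fully labeled dataset")
    if weights_on not in ("train", "full"):
        raise ValueError("weights_on must be 'train' or 'full'")
    mining_config = mining_config or MiningConfig()
    link_config = link_config or LinkWeightConfig()
    folds = kfold_indices(dataset, k, seed, stratified)
    full_weights = (
        weights_for_scheme(dataset, scheme, positive_class, link_config)
        if weights_on == "full"
        else None
    )
    accuracies = []
    for held_out in folds:
        test_set = set(held_out.tolist())
        train_idx = [i for i in range(dataset.n_transactions) if i not in test_set]
        train = dataset.subset(train_idx)
        if full_weights is not None:
            w = full_weights
        else:
            w = weights_for_scheme(train, scheme, positive_class, link_config)
        clf = train_classifier(train, w, mining_config)
        correct = sum(
            1
            for i in held_out
            if predict(clf, dataset.transactions[i].items)
            == dataset.transactions[i].label
        )
        accuracies.append(correct / len(held_out))
    snapshot = {
        "k": k,
        "scheme": scheme,
        "positive_class": positive_class,
        "stratified": stratified,
        "weights_on": weights_on,
        "link_config": vars(link_config).copy() if hasattr(link_config, "__dict__") else str(link_config),
        "mining_config": {
            "minsup": mining_config.minsup,
            "minconf": mining_config.minconf,
            "max_len": mining_config.max_len,
            "max_candidates": mining_config.max_candidates,
            "support_mode": mining_config.support_mode,
        },
    }
    return EvalReport(
        fold_accuracies=tuple(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        config_snapshot=snapshot,
        seed=seed,
    )


def compare_weights(w1: ItemWeights, w2: ItemWeights) -> WeightComparison:
    """Pearson and Spearman agreement of two weight vectors.

    Ranks use average-rank ties, ascending (larger weight = larger rank,
    i.e. more important).  Vectors must share the same item universe.
    """
    universe = w1.item_universe
    if set(universe) != set(w2.item_universe):
        raise ValueError("weight vectors cover different item universes")
    a = w1.as_array(universe)
    b = w2.as_array(universe)
    table = pd.DataFrame(
        {
            "item": universe,
            "weight_1": a,
            "weight_2": b,
            "rank_1": sps.rankdata(a),
            "rank_2": sps.rankdata(b),
        }
    )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return WeightComparison(float("nan"), float("nan"), False, table)
    pearson = float(sps.pearsonr(a, b).statistic)
    spearman = float(sps.spearmanr(a, b).statistic)
    return WeightComparison(pearson, spearman, True, table)
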