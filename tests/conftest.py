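import numpy as np
import pytest

from lac import dataset_io, synthetic
from lac.dataset_io import from_records


@pytest.fixture(scope="session")
def table1():
    """The six-compound worked example and its item weights."""
    return dataset_io.fixture_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_dataset(rng, n_items=8, n_transactions=12, labeled=False, item_prob=0.4):
    """Small random dataset with no empty transactions."""
    items = [f"f{i}" for i in range(1, n_items + 1)]
    records = []
    for t in range(n_transactions):
        mask = rng.random(n_items) < item_prob
        if not mask.any():
            mask[rng.integers(n_items)] = True
        itemset = [f for f, m in zip(items, mask) if m]
        label = ("pos" if rng.random() < 0.5 else "neg") if labeled else None
        records.append((f"t{t+1}", itemset, label))
    classes = ["pos", "neg"] if labeled else []
    return from_records(records, items=items, classes=classes)


def random_weights(rng, dataset, low=0.1, high=2.0):
    from lac.linkrank import ItemWeights

    vals = rng.uniform(low, high, size=len(dataset.items))
    return ItemWeights(dict(zip(dataset.items, vals)))
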