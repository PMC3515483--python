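"""Transaction dataset model and plain-text I/O.

A *transaction dataset* is the canonical input of associative
classification: each row is an entity (typically a chemical compound),
carrying a set of binary items (MACCS/MDL public-key fingerprint bits,
discretized bioassay readouts such as ``"MCF7 inactive"``) and an optional
class label (active/inactive, positive/negative).

Two text dialects are supported:

* ``itemlist`` — CSV with header ``id,class,items``; the ``items`` field is
  a semicolon-separated list of item names; ``class`` may be empty.
* ``bitstring`` — TSV with header ``id<TAB>class<TAB>bits:<N>``; each row
  carries a fixed-width 0/1 string of length N; set positions become items
  named by their bit index (``"0"`` … ``"N-1"``).

Items are opaque strings throughout, so numeric fingerprint bits and named
bioassay readouts are handled uniformly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, NamedTuple, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .linkrank import ItemWeights

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "Transaction",
    "TransactionDataset",
    "WeightedItem",
    "from_records",
    "load_transactions",
    "write_transactions",
    "read_weights",
    "write_weights",
    "read_rules",
    "write_rules",
    "fixture_table1",
]


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


class Transaction(NamedTuple):
    """One entity: an identifier, its itemset, and an optional class label."""

    id: str
    items: frozenset[str]
    label: Optional[str]


class WeightedItem(NamedTuple):
    """An item paired with its nonnegative significance weight."""

    item: str
    weight: float


@dataclass(frozen=True)
class TransactionDataset:
    """An immutable collection of transactions over a fixed item universe.

    Parameters
    ----------
    items
        The ordered item universe.  The tuple order is the canonical total
        order used everywhere downstream (candidate generation, output
        sorting), so two datasets with the same universe in the same order
        produce bit-identical mining results.
    classes
        Ordered class universe; empty for unlabeled data.
    transactions
        The rows.  Every transaction's itemset must be a subset of the
        universe; ids must be unique; a labeled transaction requires a
        nonempty class universe.
    """

    items: tuple[str, ...]
    classes: tuple[str, ...]
    transactions: tuple[Transaction, ...]

    def __post_init__(self) -> None:
        universe = set(self.items)
        if len(universe) != len(self.items):
            raise ValueError("duplicate items in universe")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class labels")
        seen_ids: set[str] = set()
        class_set = set(self.classes)
        for t in self.transactions:
            if t.id in seen_ids:
                raise ValueError(f"duplicate transaction id {t.id!r}")
            seen_ids.add(t.id)
            extra = t.items - universe
            if extra:
                raise ValueError(
                    f"transaction {t.id!r} contains items outside the "
                    f"universe: {sorted(extra)}"
                )
            if t.label is not None and t.label not in class_set:
                raise ValueError(
                    f"transaction {t.id!r} has unknown class {t.label!r}"
                )

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    @property
    def is_labeled(self) -> bool:
        """True when every transaction carries a class label."""
        return bool(self.classes) and all(
            t.label is not None for t in self.transactions
        )

    def item_index(self) -> dict[str, int]:
        """Map item -> position in the canonical universe order."""
        return {f: i for i, f in enumerate(self.items)}

    def subset(self, indices: Sequence[int]) -> "TransactionDataset":
        """A new dataset with the selected rows and the same universes."""
        return TransactionDataset(
            items=self.items,
            classes=self.classes,
            transactions=tuple(self.transactions[i] for i in indices),
        )

    def labels(self) -> tuple[Optional[str], ...]:
        return tuple(t.label for t in self.transactions)


def from_records(
    records: Iterable[tuple[str, Iterable[str], Optional[str]]],
    items: Optional[Sequence[str]] = None,
    classes: Optional[Sequence[str]] = None,
) -> TransactionDataset:
    """Build a dataset from ``(id, items, label)`` triples.

    When ``items``/``classes`` are omitted the universes are the sorted
    union of what is observed.
    """
    transactions = tuple(
        Transaction(str(tid), frozenset(map(str, its)), lab)
        for tid, its, lab in records
    )
    if items is None:
        items = sorted(set().union(*(t.items for t in transactions)) if transactions else set())
    if classes is None:
        classes = sorted({t.label for t in transactions if t.label is not None})
    return TransactionDataset(tuple(items), tuple(classes), transactions)


# ---------------------------------------------------------------------------
# transaction readers / writers
# ---------------------------------------------------------------------------

_ITEMLIST_HEADER = ["id", "class", "items"]


def load_transactions(path: str | Path, format: str = "itemlist") -> TransactionDataset:
    """Read a transaction dataset from ``path`` in the named dialect.

    Raises :class:`ParseError` (naming the offending line) on malformed
    rows, and on bitstring rows whose width disagrees with the header.
    """
    path = Path(path)
    if format == "itemlist":
        return _load_itemlist(path)
    if format == "bitstring":
        return _load_bitstring(path)
    raise ValueError(f"unknown format {format!r}; expected 'itemlist' or 'bitstring'")


def _load_itemlist(path: Path) -> TransactionDataset:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header 'id,class,items'")
        if [h.strip() for h in header] != _ITEMLIST_HEADER:
            raise ParseError(f"{path}:1: bad header {header!r}, expected 'id,class,items'")
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            tid, label, items_field = row
            items = [s.strip() for s in items_field.split(";") if s.strip()]
            records.append((tid.strip(), items, label.strip() or None))
    return from_records(records)


def _load_bitstring(path: Path) -> TransactionDataset:
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file, expected header 'id\\tclass\\tbits:<N>'")
        parts = header.rstrip("\n").split("\t")
        if len(parts) != 3 or parts[0] != "id" or parts[1] != "class" or not parts[2].startswith("bits:"):
            raise ParseError(f"{path}:1: bad header {header!r}")
        try:
            width = int(parts[2][len("bits:"):])
        except ValueError:
            raise ParseError(f"{path}:1: bad bit width in header {parts[2]!r}")
        records = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = line.split("\t")
            if len(row) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            tid, label, bits = row
            if len(bits) != width or set(bits) - {"0", "1"}:
                raise ParseError(
                    f"{path}:{lineno}: bits field must be {width} characters of 0/1"
                )
            items = [str(i) for i, b in enumerate(bits) if b == "1"]
            records.append((tid, items, label or None))
    universe = tuple(str(i) for i in range(width))
    return from_records(records, items=universe)


def write_transactions(
    dataset: TransactionDataset, path: str | Path, format: str = "itemlist"
) -> None:
    """Write ``dataset`` so that :func:`load_transactions` round-trips it."""
    path = Path(path)
    order = dataset.item_index()
    if format == "itemlist":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_ITEMLIST_HEADER)
            for t in dataset.transactions:
                items = ";".join(sorted(t.items, key=order.__getitem__))
                writer.writerow([t.id, t.label or "", items])
    elif format == "bitstring":
        width = len(dataset.items)
        with open(path, "w") as fh:
            fh.write(f"id\tclass\tbits:{width}\n")
            for t in dataset.transactions:
                bits = "".join("1" if f in t.items else "0" for f in dataset.items)
                fh.write(f"{t.id}\t{t.label or ''}\t{bits}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# weights and rules TSV
# ---------------------------------------------------------------------------


def write_weights(weights: "ItemWeights", path: str | Path) -> None:
    """Two-column TSV ``item<TAB>weight`` at full precision (repr round-trip)."""
    with open(path, "w") as fh:
        fh.write("item\tweight\n")
        for item in weights.item_universe:
            fh.write(f"{item}\t{float(weights[item])!r}\n")


def read_weights(path: str | Path) -> "ItemWeights":
    from .linkrank import ItemWeights

    values: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["item", "weight"]:
            raise ParseError(f"{path}:1: bad header {header!r}, expected 'item\\tweight'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = line.split("\t")
            if len(row) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            try:
                values[row[0]] = float(row[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad weight {row[1]!r}")
    return ItemWeights(values, normalization=None, provenance="user")


def write_rules(rules: Sequence, path: str | Path) -> None:
    """Rule TSV: ``antecedent<TAB>class<TAB>support<TAB>confidence<TAB>rank``.

    The antecedent is written as a sorted semicolon-joined item list; rank
    is the rule's position in the given sequence (precedence order).
    """
    with open(path, "w") as fh:
        fh.write("antecedent\tclass\tsupport\tconfidence\trank\n")
        for rank, rule in enumerate(rules, start=1):
            ante = ";".join(sorted(rule.antecedent))
            fh.write(f"{ante}\t{rule.consequent}\t{rule.support!r}\t{rule.confidence!r}\t{rank}\n")


def read_rules(path: str | Path) -> list:
    from .cba_classifier import ClassAssociationRule

    rules = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["antecedent", "class", "support", "confidence", "rank"]:
            raise ParseError(f"{path}:1: bad rules header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = line.split("\t")
            if len(row) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields")
            ante, cls, sup, conf, rank = row
            rules.append(
                ClassAssociationRule(
                    antecedent=frozenset(s for s in ante.split(";") if s),
                    consequent=cls,
                    support=float(sup),
                    confidence=float(conf),
                    gen_id=int(rank) - 1,
                )
            )
    return rules


# ---------------------------------------------------------------------------
# bundled worked example
# ---------------------------------------------------------------------------


def fixture_table1() -> tuple[TransactionDataset, "ItemWeights"]:
    """The six-compound MDL-key worked example with its item weights.

    Six compounds C1–C6 over fingerprint bits 81–85, plus a weight vector
    for the bits.  This tiny dataset is the standard illustration of why
    plain weighted support breaks the downward closure property while the
    adjusted weighted support preserves it; it is used throughout the test
    suite as a hand-checkable reference.
    """
    from .linkrank import ItemWeights

    rows = [
        ("C1", ["81", "82", "83", "84"]),
        ("C2", ["82", "84"]),
        ("C3", ["81", "84"]),
        ("C4", ["81", "82", "84", "85"]),
        ("C5", ["81", "82", "83", "84", "85"]),
        ("C6", ["82", "83", "85"]),
    ]
    dataset = from_records(
        [(cid, items, None) for cid, items in rows],
        items=["81", "82", "83", "84", "85"],
        classes=[],
    )
    weights = ItemWeights(
        {"81": 0.8, "82": 1.0, "83": 0.8, "84": 1.6, "85": 1.0},
        normalization=None,
        provenance="user",
    )
    return dataset, weights
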