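"""Link-based feature weighting on the bipartite compound-feature graph.

A labeled transaction dataset is a bipartite graph: compounds on one side,
features on the other, with an edge wherever a compound contains a feature.
Features play the role of *authorities* and compounds of *hubs* in the
HITS sense — an important feature occurs in many important compounds, and
an important compound contains many important features.  Because compounds
carry class labels, the graph splits into an "active" (positive) subsystem
and an "inactive" (negative) subsystem, and the two are mixed by a class
factor ``beta``: with ``beta > 0.5`` the active system dominates, so
features that connect mostly to active compounds are promoted.

Three operator variants are exposed:

* ``hits`` — classic mutual reinforcement, authority operator ``LᵀL``;
* ``pagerank`` — degree-normalized random walk
  ``D_in⁻¹ Lᵀ D_out⁻¹ L`` with damped uniform teleport;
* ``unified`` (default) — the symmetric normalization
  ``D_in^{-1/2} Lᵀ D_out⁻¹ L D_in^{-1/2}`` that interpolates between the
  two, combining HITS' mutual reinforcement with PageRank's link-weight
  normalization.  Under this variant the class mixing coefficients enter
  as ``√beta`` and ``√(1-beta)``, consistent with the square-root degree
  scaling.

The converged authority vector, rescaled to mean one, becomes the item
weight vector consumed by weighted association rule mining.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import scipy.sparse as sp

from .dataset_io import TransactionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ItemWeights",
    "LinkWeightConfig",
    "BipartiteGraph",
    "build_bipartite",
    "authority_operator",
    "hub_scores",
    "compute_link_weights",
    "frequency_weights",
    "uniform_weights",
]

_VARIANTS = ("hits", "pagerank", "unified")


@dataclass(frozen=True)
class ItemWeights:
    """Nonnegative per-item weights with normalization/provenance metadata.

    ``normalization`` is ``"mean_one"`` (mean weight 1, the default output
    scale so weighted supports are comparable to classical supports),
    ``"l1"`` (weights sum to 1), or ``None`` for raw/user-supplied values.
    ``provenance`` records how the vector was produced: ``"link"``,
    ``"frequency"``, ``"uniform"`` or ``"user"``.
    """

    weights: Mapping[str, float]
    normalization: Optional[str] = None
    provenance: str = "user"
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, w in self.weights.items():
            if not (w >= 0.0):
                raise ValueError(f"negative or NaN weight for item {item!r}: {w}")
        if self.weights:
            vals = np.fromiter(self.weights.values(), dtype=float)
            if self.normalization == "mean_one" and abs(vals.mean() - 1.0) > 1e-6:
                raise ValueError("normalization declared mean_one but mean != 1")
            if self.normalization == "l1" and abs(vals.sum() - 1.0) > 1e-6:
                raise ValueError("normalization declared l1 but sum != 1")

    @property
    def item_universe(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def __getitem__(self, item: str) -> float:
        return self.weights[item]

    def __contains__(self, item: str) -> bool:
        return item in self.weights

    def __len__(self) -> int:
        return len(self.weights)

    def as_array(self, order: tuple[str, ...]) -> np.ndarray:
        return np.array([self.weights[i] for i in order], dtype=float)

    def rescaled(self, normalization: str) -> "ItemWeights":
        """Return a copy rescaled to ``mean_one`` or ``l1``."""
        vals = np.fromiter(self.weights.values(), dtype=float)
        total = vals.sum()
        if total <= 0:
            raise ValueError("cannot rescale an all-zero weight vector")
        if normalization == "mean_one":
            factor = len(vals) / total
        elif normalization == "l1":
            factor = 1.0 / total
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        return ItemWeights(
            {k: v * factor for k, v in self.weights.items()},
            normalization=normalization,
            provenance=self.provenance,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class LinkWeightConfig:
    """Knobs of the link-weighting recursion.

    beta : class factor in [0, 1]; weight of the active subsystem in the
        mixed recursion.  Values above 0.5 promote features that connect
        preferentially to active compounds.  Default 0.9.
    variant : ``hits`` | ``pagerank`` | ``unified`` (default).
    damping : PageRank link-follow probability alpha in (0, 1]; only the
        ``pagerank`` variant teleports.  Default 0.85.
    tol : L1 convergence tolerance of the power iteration.
    max_iter : iteration cap; non-convergence is logged, not fatal.
    normalize_mean_to_one : rescale the converged authority vector to mean
        one (else L1).
    """

    beta: float = 0.9
    variant: str = "unified"
    damping: float = 0.85
    tol: float = 1e-8
    max_iter: int = 1000
    normalize_mean_to_one: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class BipartiteGraph:
    """Class-split incidence of a labeled dataset.

    ``L_a`` stacks the rows of positive-class (active) transactions,
    ``L_b`` the rest; columns follow ``items``.  Transactions with empty
    itemsets are dropped before operator construction (they have no links,
    and the inverse out-degree scaling would be undefined).
    """

    items: tuple[str, ...]
    L_a: sp.csr_matrix
    L_b: sp.csr_matrix
    ids_a: tuple[str, ...]
    ids_b: tuple[str, ...]

    @property
    def d_in(self) -> np.ndarray:
        """Per-item in-degree: column sums over both subsystems."""
        return (
            np.asarray(self.L_a.sum(axis=0)).ravel()
            + np.asarray(self.L_b.sum(axis=0)).ravel()
        )

    @property
    def d_out(self) -> np.ndarray:
        """Per-transaction out-degree (row sums), active rows first."""
        return np.concatenate(
            [
                np.asarray(self.L_a.sum(axis=1)).ravel(),
                np.asarray(self.L_b.sum(axis=1)).ravel(),
            ]
        )

    def incidence(self, system: str) -> sp.csr_matrix:
        if system == "a":
            return self.L_a
        if system == "b":
            return self.L_b
        raise ValueError("system must be 'a' or 'b'")


def build_bipartite(
    dataset: TransactionDataset, positive_class: str
) -> BipartiteGraph:
    """Split ``dataset`` into active/inactive incidence matrices.

    Transactions labeled ``positive_class`` populate the active system;
    all other labels go to the inactive system.
    """
    if not dataset.classes:
        raise ValueError("dataset has no class labels; cannot build class-split graph")
    if positive_class not in dataset.classes:
        raise ValueError(
            f"unknown class {positive_class!r}; dataset classes are {dataset.classes}"
        )
    index = dataset.item_index()
    n = len(dataset.items)

    def incidence(rows: list) -> sp.csr_matrix:
        mat = sp.lil_matrix((len(rows), n), dtype=float)
        for r, t in enumerate(rows):
            for f in t.items:
                mat[r, index[f]] = 1.0
        return mat.tocsr()

    active, inactive = [], []
    dropped = 0
    for t in dataset.transactions:
        if not t.items:
            dropped += 1
            continue
        (active if t.label == positive_class else inactive).append(t)
    if dropped:
        logger.warning("dropped %d transactions with empty itemsets", dropped)
    return BipartiteGraph(
        items=dataset.items,
        L_a=incidence(active),
        L_b=incidence(inactive),
        ids_a=tuple(t.id for t in active),
        ids_b=tuple(t.id for t in inactive),
    )


def _inv(vec: np.ndarray, power: float = 1.0) -> np.ndarray:
    """Pseudo-inverse of a nonnegative degree vector: 0 stays 0."""
    out = np.zeros_like(vec, dtype=float)
    nz = vec > 0
    out[nz] = vec[nz] ** (-power)
    return out


def authority_operator(
    graph: BipartiteGraph, system: str, config: LinkWeightConfig
) -> Callable[[np.ndarray], np.ndarray]:
    """The authority (feature-score) operator of one subsystem.

    With ``L`` the subsystem incidence and ``D_in``/``D_out`` its item and
    transaction degree diagonals (pseudo-inverted at zero degree):

    * ``hits``:     ``A(x) = Lᵀ L x``
    * ``unified``:  ``A(x) = D_in^{-1/2} Lᵀ D_out⁻¹ L D_in^{-1/2} x``
    * ``pagerank``: ``A(x) = α · D_in⁻¹ Lᵀ D_out⁻¹ L x̂ + (1-α) · u``
      where ``x̂`` is the L1-normalized input (zero input maps to zero, so
      no teleport mass is injected at zero mass) and ``u`` is uniform over
      items with nonzero in-degree in the subsystem.

    All variants map nonnegative vectors to nonnegative vectors.
    """
    L = graph.incidence(system)
    if L.shape[0] == 0:
        raise ValueError(f"system {system!r} has no transactions")
    d_out = np.asarray(L.sum(axis=1)).ravel()
    d_in = np.asarray(L.sum(axis=0)).ravel()
    inv_out = _inv(d_out)

    if config.variant == "hits":

        def op(x: np.ndarray) -> np.ndarray:
            return L.T @ (L @ np.asarray(x, dtype=float))

    elif config.variant == "unified":
        inv_sqrt_in = _inv(d_in, power=0.5)

        def op(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return inv_sqrt_in * (L.T @ (inv_out * (L @ (inv_sqrt_in * x))))

    else:  # pagerank
        inv_in = _inv(d_in)
        alpha = config.damping
        support = d_in > 0
        teleport = support / support.sum() if support.any() else np.zeros_like(d_in)

        def op(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            mass = x.sum()
            if mass <= 0:
                return np.zeros_like(x)
            xhat = x / mass
            walk = inv_in * (L.T @ (inv_out * (L @ xhat)))
            return alpha * walk + (1.0 - alpha) * teleport

    return op


def hub_scores(
    graph: BipartiteGraph, system: str, authority: np.ndarray, config: LinkWeightConfig
) -> np.ndarray:
    """Hub (compound) scores induced by an authority vector, for diagnostics.

    The dual of the authority operator: each transaction's score aggregates
    the authority of the features it contains, normalized per variant.
    Returned in the row order of the subsystem's incidence.
    """
    L = graph.incidence(system)
    x = np.asarray(authority, dtype=float)
    if config.variant == "hits":
        y = L @ x
    elif config.variant == "unified":
        d_in = np.asarray(L.sum(axis=0)).ravel()
        d_out = np.asarray(L.sum(axis=1)).ravel()
        y = _inv(d_out, 0.5) * (L @ (_inv(d_in, 0.5) * x))
    else:
        d_in = np.asarray(L.sum(axis=0)).ravel()
        y = L @ (_inv(d_in) * x)
    total = y.sum()
    return y / total if total > 0 else y


def compute_link_weights(
    graph: BipartiteGraph, config: LinkWeightConfig = LinkWeightConfig()
) -> ItemWeights:
    """Power-iterate the class-mixed authority recursion to a weight vector.

    Starting from the uniform distribution, iterate

        ``x ∝ c_a · A_a(x) + c_b · A_b(x)``

    with L1 renormalization each step, where ``(c_a, c_b)`` are
    ``(beta, 1-beta)`` — replaced by their square roots for the
    ``unified`` variant, whose operator carries square-root degree
    scalings.  Stops when the L1 change drops below ``tol`` or after
    ``max_iter`` steps (logged; ``meta["converged"]`` records which).
    Items absent from the data keep weight exactly 0; the result is
    rescaled to mean one by default.
    """
    n = len(graph.items)
    d_in_total = graph.d_in
    if n == 0 or not np.any(d_in_total > 0):
        raise ValueError("graph has no item with nonzero in-degree")

    if config.variant == "unified":
        c_a, c_b = math.sqrt(config.beta), math.sqrt(1.0 - config.beta)
    else:
        c_a, c_b = config.beta, 1.0 - config.beta
    op_a = authority_operator(graph, "a", config) if graph.L_a.shape[0] else None
    op_b = authority_operator(graph, "b", config) if graph.L_b.shape[0] else None

    x = np.full(n, 1.0 / n)
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        y = np.zeros(n)
        if op_a is not None and c_a > 0:
            y += c_a * op_a(x)
        if op_b is not None and c_b > 0:
            y += c_b * op_b(x)
        total = y.sum()
        if total <= 0:
            x = y
            converged = True
            break
        y /= total
        delta = np.abs(y - x).sum()
        x = y
        if delta < config.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "link-weight power iteration did not converge in %d steps", config.max_iter
        )
    x = np.where(d_in_total > 0, x, 0.0)
    total = x.sum()
    meta = {
        "converged": converged,
        "iterations": iterations,
        "beta": config.beta,
        "variant": config.variant,
    }
    if total <= 0:
        logger.warning("all link weights are zero (degenerate mixing)")
        return ItemWeights(
            dict(zip(graph.items, x.tolist())), normalization=None, provenance="link", meta=meta
        )
    if config.normalize_mean_to_one:
        x = x * (n / total)
        norm = "mean_one"
    else:
        x = x / total
        norm = "l1"
    return ItemWeights(
        dict(zip(graph.items, x.tolist())), normalization=norm, provenance="link", meta=meta
    )


def frequency_weights(dataset: TransactionDataset) -> ItemWeights:
    """Occurrence-count weights, rescaled to mean one.

    The natural unweighted baseline: an item's weight is proportional to
    the number of transactions containing it.
    """
    counts = np.zeros(len(dataset.items))
    index = dataset.item_index()
    for t in dataset.transactions:
        for f in t.items:
            counts[index[f]] += 1.0
    total = counts.sum()
    if total <= 0:
        return ItemWeights(
            dict(zip(dataset.items, counts.tolist())), normalization=None, provenance="frequency"
        )
    counts *= len(counts) / total
    return ItemWeights(
        dict(zip(dataset.items, counts.tolist())), normalization="mean_one", provenance="frequency"
    )


def uniform_weights(dataset: TransactionDataset) -> ItemWeights:
    """All weights exactly 1: reduces the weighted pipeline to classical CBA."""
    return ItemWeights(
        {f: 1.0 for f in dataset.items}, normalization="mean_one", provenance="uniform"
    )
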