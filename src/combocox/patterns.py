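"""Itemsets over a binary item matrix and weighted-support mining.

An *itemset* is a conjunction of items (binarized features); its indicator
vector marks the samples carrying every member item.  The path engine scores
an itemset ``t`` by its weighted support

    c(t) = sum_i w_i x_{t,i}

where the per-sample weights ``w_i`` are the martingale-residual-form
gradient weights of the Cox partial likelihood at the current fit, so that
``c(t)`` is exactly the derivative of the unpenalized loss with respect to a
candidate coefficient for ``t``.  Finding all itemsets with ``|c(t)|`` above
a threshold is then a weighted frequent-itemset problem.

Because the weights are signed, plain weighted support is not anti-monotone;
the depth-first search prunes instead with the positive-part bound
``sum_i max(w_i, 0) x_{t,i}``, which can only shrink along any superset
branch and therefore never discards a qualifying itemset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .survival import CoxPartialLikelihood, SurvivalDataset

#: relative tolerance used when comparing weighted supports for argmax
#: tie-breaking; ties are resolved toward fewer items, then lexicographically.
_TIE_RTOL = 1e-12


@dataclass
class Itemset:
    """A sorted tuple of item indices with its sample indicator vector."""

    items: tuple[int, ...]
    indicator: np.ndarray
    support: int = 0
    value: float | None = None  # achieved weighted support, when mined

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise InputError("an itemset must contain at least one item")
        if len(set(self.items)) != len(self.items):
            raise InputError("itemset items must be duplicate-free")
        self.items = tuple(sorted(int(i) for i in self.items))
        self.indicator = np.asarray(self.indicator).astype(bool)
        self.support = int(self.indicator.sum())

    @classmethod
    def from_items(cls, items, matrix: np.ndarray) -> "Itemset":
        items = tuple(sorted(int(i) for i in items))
        ind = np.all(matrix[:, list(items)].astype(bool), axis=1)
        return cls(items=items, indicator=ind)

    def name(self, item_names: list[str]) -> str:
        return " * ".join(item_names[i] for i in self.items)

    def __eq__(self, other) -> bool:
        return isinstance(other, Itemset) and self.items == other.items

    def __hash__(self) -> int:
        return hash(self.items)

    def __repr__(self) -> str:
        return f"Itemset{self.items} (support={self.support})"


@dataclass
class MiningProblem:
    """A weighted-support threshold query over the itemset lattice."""

    weights: np.ndarray
    threshold: float
    max_order: int = 3
    closed_only: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise InputError("weights must be finite")
        if self.threshold <= 0:
            raise InputError("threshold must be positive")
        if self.max_order < 1:
            raise InputError("max_order must be >= 1")


class ItemLattice:
    """Shared DFS scaffolding: items ordered by descending support.

    Items are visited in descending-support order (stable by original index),
    the standard heuristic that maximizes early pruning; itemsets are emitted
    with original item indices, sorted.
    """

    def __init__(self, items_matrix: np.ndarray):
        items_matrix = np.asarray(items_matrix)
        if items_matrix.ndim != 2 or items_matrix.shape[1] == 0:
            raise InputError("item matrix must be non-empty and 2-D")
        self.n, self.m = items_matrix.shape
        self.cols = items_matrix.astype(bool)
        counts = self.cols.sum(axis=0)
        self.order = np.lexsort((np.arange(self.m), -counts))
        self.supports = [np.flatnonzero(self.cols[:, j]) for j in self.order]
        # float view in visiting order: one row-sliced matmul per DFS node
        # scores every extension at once
        self.colsf = self.cols[:, self.order].astype(float)

    def original(self, positions: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(sorted(int(self.order[p]) for p in positions))


def _mine_one_side(lattice: ItemLattice, w: np.ndarray, threshold: float,
                   max_order: int) -> list[tuple[tuple[int, ...], np.ndarray, float]]:
    """All itemsets with sum(w[support]) >= threshold (positive side only)."""
    w_pos = np.maximum(w, 0.0)
    out: list[tuple[tuple[int, ...], np.ndarray, float]] = []

    def recurse(start: int, prefix: tuple[int, ...], supp: np.ndarray) -> None:
        if start >= lattice.m:
            return
        sub = lattice.colsf[supp, start:]
        vals = w[supp] @ sub
        # positive-part bound: no itemset on a branch (including its root)
        # can exceed it
        bounds = w_pos[supp] @ sub
        for idx in np.flatnonzero(bounds >= threshold):
            pos = start + idx
            new_supp = supp[sub[:, idx] > 0]
            items = prefix + (pos,)
            if vals[idx] >= threshold:
                out.append((items, new_supp, float(vals[idx])))
            if len(items) < max_order:
                recurse(pos + 1, items, new_supp)

    recurse(0, (), np.arange(lattice.n))
    return out


def _closure(lattice: ItemLattice, supp: np.ndarray) -> frozenset[int]:
    """All original item indices present in every supporting sample."""
    present = lattice.cols[supp].all(axis=0)
    return frozenset(np.flatnonzero(present).tolist())


def mine_threshold_itemsets(
    data: "SurvivalDataset | np.ndarray | ItemLattice", problem: MiningProblem
) -> list[Itemset]:
    """Exactly the itemsets with ``|c(t)| >= threshold``, by pruned DFS.

    The negative side is found by rerunning with negated weights.  Each
    returned :class:`Itemset` carries its achieved (signed) weighted support
    in ``value``.  Results are sorted by (order, items) for determinism.
    """
    if isinstance(data, ItemLattice):
        lattice = data
    else:
        matrix = data.items if isinstance(data, SurvivalDataset) else np.asarray(data)
        lattice = ItemLattice(matrix)
    if len(problem.weights) != lattice.n:
        raise InputError("weights length must equal the number of samples")

    found: list[Itemset] = []
    for sign in (+1.0, -1.0):
        hits = _mine_one_side(lattice, sign * problem.weights,
                              problem.threshold, problem.max_order)
        for positions, supp, val in hits:
            items = lattice.original(positions)
            if problem.closed_only and frozenset(items) != _closure(lattice, supp):
                continue
            ind = np.zeros(lattice.n, dtype=bool)
            ind[supp] = True
            found.append(Itemset(items=items, indicator=ind, value=sign * val))
    found.sort(key=lambda t: (len(t.items), t.items))
    return found


def max_weighted_support(
    matrix: np.ndarray, weights: np.ndarray, max_order: int
) -> tuple[float, tuple[int, ...]]:
    """Maximize ``sum_i w_i x_{t,i}`` over itemsets of length <= max_order.

    Branch-and-bound twin of the threshold miner.  Ties within floating-point
    noise are broken toward fewer items, then lexicographically smaller
    original indices.  Returns ``(best value, best itemset indices)``.
    """
    w = np.asarray(weights, dtype=float)
    lattice = ItemLattice(matrix)
    w_pos = np.maximum(w, 0.0)
    scale = np.abs(w).sum() + 1.0
    tol = _TIE_RTOL * scale
    best_val = -np.inf
    best_items: tuple[int, ...] | None = None

    def recurse(start: int, prefix: tuple[int, ...], supp: np.ndarray) -> None:
        nonlocal best_val, best_items
        if start >= lattice.m:
            return
        sub = lattice.colsf[supp, start:]
        vals = w[supp] @ sub
        bounds = w_pos[supp] @ sub
        sizes = sub.sum(axis=0)
        for idx in range(sub.shape[1]):
            if sizes[idx] == 0 or bounds[idx] < best_val - tol:
                continue
            pos = start + idx
            val = vals[idx]
            items = prefix + (pos,)
            orig = lattice.original(items)
            if val > best_val + tol:
                best_val, best_items = val, orig
            elif val >= best_val - tol and best_items is not None:
                if (len(orig), orig) < (len(best_items), best_items):
                    best_val = max(best_val, val)
                    best_items = orig
            if len(items) < max_order:
                recurse(pos + 1, items, supp[sub[:, idx] > 0])

    recurse(0, (), np.arange(lattice.n))
    if best_items is None:
        raise InputError("item matrix has no non-empty itemsets")
    return float(best_val), best_items


def canonicalize(itemsets: list[Itemset]) -> list[Itemset]:
    """Deduplicate itemsets sharing an identical indicator vector.

    Indistinguishable covariates make the penalized problem non-unique; among
    each indicator-equivalence class the itemset with fewest items (ties:
    lexicographically smallest) survives.  Input order of survivors is kept.
    """
    seen: dict[bytes, Itemset] = {}
    order: list[bytes] = []
    for t in itemsets:
        key = np.packbits(t.indicator).tobytes()
        cur = seen.get(key)
        if cur is None:
            seen[key] = t
            order.append(key)
        elif (len(t.items), t.items) < (len(cur.items), cur.items):
            seen[key] = t
    return [seen[k] for k in order]


def compute_activation_weights(
    beta_active: np.ndarray,
    active_itemsets: list[Itemset],
    data: SurvivalDataset,
    ties: str = "breslow",
    lam: float | None = None,
    tol: float = 1e-6,
) -> np.ndarray:
    """Per-sample weights ``w`` such that ``c(t) = sum_i w_i x_{t,i}``.

    ``c(t)`` is the gradient of the (unpenalized) Cox log partial likelihood
    with respect to a candidate coefficient for itemset ``t``, evaluated at
    the current active-set optimum: each sample's event indicator minus its
    accumulated share of risk-set mass under the current model.

    When ``lam`` is given, the KKT equalities ``c(t) = sign(beta_t) * lam``
    are verified on the active set; a violation beyond ``tol`` signals a
    stale (non-optimal) state via :class:`InputError`.
    """
    beta_active = np.asarray(beta_active, dtype=float)
    if len(beta_active) != len(active_itemsets):
        raise InputError("beta_active and active_itemsets lengths differ")
    pl = CoxPartialLikelihood(data.time, data.event, ties)
    if active_itemsets:
        X = np.column_stack([t.indicator.astype(float) for t in active_itemsets])
        eta = X @ beta_active
    else:
        eta = np.zeros(data.n_samples)
    w = pl.weights(eta)
    if lam is not None:
        for b, t in zip(beta_active, active_itemsets):
            c = float(w @ t.indicator)
            if b != 0 and abs(c - np.sign(b) * lam) > tol:
                raise InputError(
                    f"stale state: active itemset {t.items} has c(t)={c:.6g} "
                    f"but sign(beta)*lambda={np.sign(b) * lam:.6g}"
                )
    return w
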