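"""Dichotomization of continuous features into over-/under-expression items.

Each continuous feature (e.g. a gene's expression across samples) is turned
into up to two binary items: ``up.<name>`` flags samples whose value lies
above ``mu + theta * sigma`` and ``dn.<name>`` flags values below
``mu - theta * sigma``, where ``mu`` and ``sigma`` are the feature's mean and
standard deviation and ``theta`` (default 1.5) controls how extreme a value
must be to count as dys-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError


@dataclass
class BinarizationSpec:
    """Parameters of the mu +- theta*sigma thresholding rule.

    Parameters
    ----------
    theta : float
        Threshold multiplier on the standard deviation (> 0).
    normalize : bool
        Z-score each feature before thresholding.  The rule itself is affine
        invariant, so this only matters when ``mu``/``sigma`` are later frozen
        and applied to new samples.
    emit_up, emit_dn : bool
        Which side(s) to emit.
    ddof : int
        Delta degrees of freedom for the standard deviation: 1 (sample, the
        default, conventional in expression preprocessing) or 0 (population).
    strict : bool
        Use strict inequalities at the cutoffs (default), matching
        "above"/"below".
    min_item_count : int
        Item columns carried by fewer samples than this are dropped (0 keeps
        everything).  A pattern matching one sample trivially overfits.
    """

    theta: float = 1.5
    normalize: bool = False
    emit_up: bool = True
    emit_dn: bool = True
    ddof: int = 1
    strict: bool = True
    min_item_count: int = 2

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise InputError("theta must be positive")
        if self.ddof not in (0, 1):
            raise InputError("ddof must be 0 or 1")


def _validate_numeric(expr: pd.DataFrame) -> np.ndarray:
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for j, col in enumerate(expr.columns):
            coerced = pd.to_numeric(expr[col], errors="coerce")
            orig_na = expr[col].isna()
            bad = coerced.isna() & ~orig_na
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise InputError(
                    f"non-numeric value {expr.iloc[i, j]!r} at row "
                    f"{expr.index[i]!r}, column {col!r}"
                )
        values = expr.apply(pd.to_numeric).to_numpy()
    if np.isnan(values).any():
        i, j = map(int, next(zip(*np.nonzero(np.isnan(values)))))
        raise InputError(
            f"missing value at row {expr.index[i]!r}, column {expr.columns[j]!r}"
        )
    return values.astype(float)


def binarize_matrix(
    expr: pd.DataFrame, spec: BinarizationSpec | None = None
) -> pd.DataFrame:
    """Convert a samples x features numeric matrix into a 0/1 item matrix.

    Parameters
    ----------
    expr : DataFrame
        Rows are samples (index = sample IDs), columns are features.
    spec : BinarizationSpec, optional
        Thresholding parameters; defaults to ``BinarizationSpec()``.

    Returns
    -------
    DataFrame
        0/1 matrix with the same index and columns named ``up.<feature>`` /
        ``dn.<feature>``.  Constant features (sigma = 0) yield no items; item
        columns below ``spec.min_item_count`` positives are dropped.
    """
    if spec is None:
        spec = BinarizationSpec()
    if expr.shape[0] < 2:
        raise InputError("binarization needs at least 2 samples per feature")
    values = _validate_numeric(expr)
    if spec.normalize:
        mu0 = values.mean(axis=0)
        sd0 = values.std(axis=0, ddof=spec.ddof)
        safe = np.where(sd0 > 0, sd0, 1.0)
        values = (values - mu0) / safe

    mu = values.mean(axis=0)
    sigma = values.std(axis=0, ddof=spec.ddof)

    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(expr.columns):
        if sigma[j] == 0:
            continue
        hi = mu[j] + spec.theta * sigma[j]
        lo = mu[j] - spec.theta * sigma[j]
        if spec.emit_up:
            up = values[:, j] > hi if spec.strict else values[:, j] >= hi
            cols[f"up.{name}"] = up.astype(np.uint8)
        if spec.emit_dn:
            dn = values[:, j] < lo if spec.strict else values[:, j] <= lo
            cols[f"dn.{name}"] = dn.astype(np.uint8)

    out = pd.DataFrame(cols, index=expr.index, dtype=np.uint8)
    if spec.min_item_count > 0 and out.shape[1] > 0:
        keep = out.sum(axis=0) >= spec.min_item_count
        out = out.loc[:, keep]
    return out
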