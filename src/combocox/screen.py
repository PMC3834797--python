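"""Resampling screen turning path traces into ranked interaction candidates.

A single regularization path run on all the data is prone to overfitting:
a pattern may enter the model on the strength of a handful of samples.  The
screen therefore sets aside a held-out test fraction once, then repeatedly
(default 100 times) re-runs the path follower on random subsamples (default
95%) of the training data.  From each run it keeps the multi-item itemsets
that appear anywhere on the path *and* beat the linear model of their
constituent single items in a nested likelihood-ratio test; candidates that
recur in at least ``min_occurrences`` iterations are ranked by training-set
logrank p-value, flagged for Bonferroni significance, and finally evaluated
on the untouched test subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ComboCoxError, DegenerateDataError, FittingError, InputError
from .path import PathConfig, follow_path
from .patterns import Itemset
from .survival import SurvivalDataset, fit_cox, likelihood_ratio_test, logrank_test


@dataclass
class ScreenConfig:
    """Protocol parameters of the resampling screen.

    Defaults follow the standard protocol: 100 iterations on 95% subsamples
    of the training data after a 25% test split, keeping combinations that
    pass the LR test at 0.05 and recur in at least 4 iterations.
    """

    n_iterations: int = 100
    subsample_fraction: float = 0.95
    lr_alpha: float = 0.05
    min_occurrences: int = 4
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction <= 1):
            raise InputError("subsample_fraction must be in (0, 1]")
        if self.min_occurrences < 1:
            raise InputError("min_occurrences must be >= 1")
        if not (0 <= self.test_fraction < 1):
            raise InputError("test_fraction must be in [0, 1)")
        if self.n_iterations < 1:
            raise InputError("n_iterations must be >= 1")


@dataclass
class CandidateInteraction:
    """A recurring itemset with its screening statistics."""

    itemset: Itemset
    occurrences: int
    lr_pvalue: float            # best (smallest) LR-test p across iterations
    logrank_pvalue: float       # training subset
    test_logrank_pvalue: float  # held-out subset
    bonferroni_significant: bool = False


@dataclass
class IterationLog:
    """What one subsample run contributed (serializable for resume)."""

    index: int
    skipped: bool = False
    n_events: int = 0
    kept: list[tuple[tuple[int, ...], float]] = field(default_factory=list)


@dataclass
class ScreenRun:
    """Full outcome of :func:`run_screen`."""

    candidates: list[CandidateInteraction]
    iteration_logs: list[IterationLog]
    m_bonferroni: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    config: ScreenConfig


def bonferroni(pvalues, m: int) -> np.ndarray:
    """Family-wise significance flags: ``p <= 0.05 / m`` (non-strict at the
    boundary, by documented convention)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if m < len(pvalues):
        raise InputError("correction factor m must be >= the number of tests")
    if m < 1:
        raise InputError("correction factor m must be >= 1")
    return pvalues <= 0.05 / m


def _safe_logrank(time, event, group) -> float:
    """Logrank p-value with degenerate groupings reported as 1.0."""
    group = np.asarray(group)
    if group.all() or not group.any():
        return 1.0
    try:
        return logrank_test(time, event, group.astype(int))[1]
    except (DegenerateDataError, InputError):
        return 1.0


def screen_split(n_samples: int, config: ScreenConfig) -> tuple[np.ndarray, np.ndarray]:
    """One-time train/test split; the test subset never touches selection."""
    ss = np.random.SeedSequence([config.seed, 0x5517])
    rng = np.random.default_rng(ss)
    n_test = int(round(config.test_fraction * n_samples))
    perm = rng.permutation(n_samples)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return train_idx, test_idx


def _iteration_rng(config: ScreenConfig, index: int) -> np.random.Generator:
    # per-iteration streams keyed by (seed, index): iteration i is
    # reproducible in isolation, which makes interrupted runs resumable
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1 + index]))


def screen_iteration(
    data: SurvivalDataset,
    train_idx: np.ndarray,
    config: ScreenConfig,
    path_config: PathConfig,
    index: int,
) -> IterationLog:
    """One subsample run: path trace, then the nested LR filter.

    For every multi-item itemset appearing in any path state, the full model
    {constituent single items + itemset indicator} is compared against the
    nested model {constituent single items} by an unpenalized likelihood-ratio
    test with 1 df on the iteration's subsample; only significantly improved
    combinations are kept.
    """
    rng = _iteration_rng(config, index)
    k = int(round(config.subsample_fraction * len(train_idx)))
    k = max(k, 1)
    sub = np.sort(rng.choice(train_idx, size=k, replace=False))
    subdata = data.subset(sub)
    log = IterationLog(index=index, n_events=subdata.n_events)
    if subdata.n_events == 0:
        log.skipped = True
        return log
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        trace = follow_path(subdata, path_config)
        for t in trace.all_itemsets(min_order=2):
            singles = np.column_stack(
                [subdata.items[:, j].astype(float) for j in t.items]
            )
            full_X = np.column_stack([singles, t.indicator.astype(float)])
            try:
                reduced = fit_cox(singles, subdata.time, subdata.event,
                                  ties=path_config.ties)
                full = fit_cox(full_X, subdata.time, subdata.event,
                               ties=path_config.ties)
                p = likelihood_ratio_test(full, reduced, df=1)
            except (ComboCoxError, np.linalg.LinAlgError):
                continue
            if p <= config.lr_alpha:
                log.kept.append((t.items, float(p)))
    return log


def aggregate_screen(
    data: SurvivalDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    logs: list[IterationLog],
    config: ScreenConfig,
) -> tuple[list[CandidateInteraction], int]:
    """Pool iteration outputs into the final ranked candidate list.

    An itemset counts once per iteration it appears in.  The Bonferroni
    correction factor ``m`` is the number of distinct candidates reaching
    aggregation (before the occurrence filter), mirroring how the family of
    hypotheses is larger than the reported list.
    """
    occurrences: dict[tuple[int, ...], int] = {}
    best_lr: dict[tuple[int, ...], float] = {}
    for log in logs:
        seen_here = set()
        for items, p in log.kept:
            if items in seen_here:
                continue
            seen_here.add(items)
            occurrences[items] = occurrences.get(items, 0) + 1
            best_lr[items] = min(best_lr.get(items, 1.0), p)
    m = len(occurrences)
    survivors = [k for k, c in occurrences.items() if c >= config.min_occurrences]
    candidates = []
    for items in survivors:
        itemset = Itemset.from_items(items, data.items)
        ind = itemset.indicator
        p_train = _safe_logrank(
            data.time[train_idx], data.event[train_idx], ind[train_idx]
        )
        if len(test_idx):
            p_test = _safe_logrank(
                data.time[test_idx], data.event[test_idx], ind[test_idx]
            )
        else:
            p_test = np.nan
        candidates.append(
            CandidateInteraction(
                itemset=itemset,
                occurrences=occurrences[items],
                lr_pvalue=best_lr[items],
                logrank_pvalue=p_train,
                test_logrank_pvalue=p_test,
            )
        )
    if candidates:
        flags = bonferroni([c.logrank_pvalue for c in candidates], max(m, 1))
        for c, f in zip(candidates, flags):
            c.bonferroni_significant = bool(f)
    candidates.sort(
        key=lambda c: (c.logrank_pvalue, -c.occurrences, c.itemset.items)
    )
    return candidates, m


def run_screen(
    data: SurvivalDataset,
    config: ScreenConfig | None = None,
    path_config: PathConfig | None = None,
) -> ScreenRun:
    """The full resampling screen (split, iterate, filter, aggregate, rank)."""
    config = config or ScreenConfig()
    path_config = path_config or PathConfig()
    train_idx, test_idx = screen_split(data.n_samples, config)
    logs = [
        screen_iteration(data, train_idx, config, path_config, i)
        for i in range(config.n_iterations)
    ]
    candidates, m = aggregate_screen(data, train_idx, test_idx, logs, config)
    return ScreenRun(
        candidates=candidates,
        iteration_logs=logs,
        m_bonferroni=m,
        train_indices=train_idx,
        test_indices=test_idx,
        config=config,
    )


def stability_report(
    logs: list[IterationLog], min_occurrences: int
) -> pd.DataFrame:
    """Size and churn of the would-be final list after each iteration prefix.

    Because a candidate can fall back below the occurrence threshold only by
    never recurring, the prefix list is not guaranteed monotone; adds and
    drops are recorded separately so a stability plot can show both.
    """
    counts: dict[tuple[int, ...], int] = {}
    prev: set[tuple[int, ...]] = set()
    rows = []
    for log in logs:
        for items in {k for k, _ in log.kept}:
            counts[items] = counts.get(items, 0) + 1
        current = {k for k, c in counts.items() if c >= min_occurrences}
        rows.append(
            {
                "iteration": log.index + 1,
                "list_size": len(current),
                "n_added": len(current - prev),
                "n_dropped": len(prev - current),
            }
        )
        prev = current
    return pd.DataFrame(rows)
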