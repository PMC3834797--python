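"""Model/Results front end.

Two estimator objects wrap the functional layers in the style of
statsmodels: you build a model from data, call ``fit()``, and get a results
object carrying estimates, diagnostics and a ``summary()`` table.

* :class:`PatternCoxPath` — the L1-penalized Cox regularization path over
  itemset covariates; its results hold the full trace of active sets and
  coefficients as the penalty decreases.
* :class:`InteractionScreen` — the resampling screen; its results hold the
  ranked candidate-interaction table and the stability curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binarize import BinarizationSpec, binarize_matrix
from .exceptions import InputError
from .path import PathConfig, PathTrace, follow_path
from .screen import ScreenConfig, ScreenRun, run_screen, stability_report
from .survival import SurvivalDataset


def _dataset_from_frames(
    items_df: pd.DataFrame, survival_df: pd.DataFrame
) -> SurvivalDataset:
    shared = [sid for sid in items_df.index if sid in set(survival_df.index)]
    if not shared:
        raise InputError("no shared sample IDs between items and survival")
    items_df = items_df.loc[shared]
    survival_df = survival_df.loc[shared]
    cols = {c.lower(): c for c in survival_df.columns}
    if "time" not in cols or "event" not in cols:
        raise InputError("survival frame needs 'time' and 'event' columns")
    return SurvivalDataset(
        items=items_df.to_numpy(),
        time=survival_df[cols["time"]].to_numpy(dtype=float),
        event=survival_df[cols["event"]].to_numpy(),
        item_names=[str(c) for c in items_df.columns],
        sample_ids=[str(s) for s in items_df.index],
    )


class PatternCoxPath:
    """L1-penalized Cox model over the lattice of itemset covariates.

    Parameters
    ----------
    data : SurvivalDataset
        Binarized items plus survival outcomes.
    max_order : int
        Largest itemset size searched (default 3; reported interactions in
        expression data are rarely larger).
    ties : {"breslow", "efron"}
        Tie correction of the partial likelihood.
    """

    def __init__(self, data: SurvivalDataset, max_order: int = 3,
                 ties: str = "breslow"):
        self.data = data
        self.max_order = max_order
        self.ties = ties

    @classmethod
    def from_dataframe(cls, items_df: pd.DataFrame, survival_df: pd.DataFrame,
                       **kwargs) -> "PatternCoxPath":
        """Build from a 0/1 items frame and a survival frame (joined on index)."""
        return cls(_dataset_from_frames(items_df, survival_df), **kwargs)

    @classmethod
    def from_expression(cls, expr_df: pd.DataFrame, survival_df: pd.DataFrame,
                        theta: float = 1.5,
                        binarization: BinarizationSpec | None = None,
                        **kwargs) -> "PatternCoxPath":
        """Binarize a continuous expression frame, then build the model."""
        spec = binarization or BinarizationSpec(theta=theta)
        items_df = binarize_matrix(expr_df, spec)
        return cls(_dataset_from_frames(items_df, survival_df), **kwargs)

    def fit(self, max_active: int = 50, lambda_min_ratio: float = 0.01,
            max_events: int = 200, **kwargs) -> "PatternCoxPathResults":
        config = PathConfig(
            max_order=self.max_order, ties=self.ties, max_active=max_active,
            lambda_min_ratio=lambda_min_ratio, max_events=max_events, **kwargs,
        )
        trace = follow_path(self.data, config)
        return PatternCoxPathResults(self, trace, config)


class PatternCoxPathResults:
    """The fitted regularization path: states, events and summaries."""

    def __init__(self, model: PatternCoxPath, trace: PathTrace,
                 config: PathConfig):
        self.model = model
        self.trace = trace
        self.config = config

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([s.lam for s in self.trace.states])

    @property
    def lambda_max(self) -> float:
        return self.trace.lambda_max

    def coefficients_at(self, lam: float) -> pd.Series:
        """Active coefficients at the recorded state covering ``lam``."""
        state = self.trace.state_at(lam)
        names = self.model.data.item_names
        return pd.Series(
            state.beta_active,
            index=[t.name(names) for t in state.active],
            name=f"beta@lambda={state.lam:.6g}",
        )

    def summary(self) -> pd.DataFrame:
        """One row per path event: lambda, action, itemset, active-set size."""
        names = self.model.data.item_names
        sizes = {}
        size = 0
        for e in self.trace.events:
            size += 1 if e.action == "add" else -1
            sizes[id(e)] = size
        return pd.DataFrame(
            [
                {
                    "lambda": e.lam,
                    "action": e.action,
                    "itemset": e.itemset.name(names),
                    "order": len(e.itemset.items),
                    "support": e.itemset.support,
                    "active_size": sizes[id(e)],
                }
                for e in self.trace.events
            ]
        )

    def plot_path(self, ax=None):
        """Coefficient trajectories against lambda (one line per itemset)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = self.model.data.item_names
        series: dict[tuple, tuple[list, list]] = {}
        for s in self.trace.states:
            present = {t.items: b for t, b in zip(s.active, s.beta_active)}
            for key in set(series) | set(present):
                xs, ys = series.setdefault(key, ([], []))
                xs.append(s.lam)
                ys.append(present.get(key, 0.0))
        for key, (xs, ys) in sorted(series.items()):
            label = " * ".join(names[i] for i in key)
            ax.plot(xs, ys, label=label)
        ax.set_xlabel(r"$\lambda$")
        ax.set_ylabel("coefficient")
        ax.invert_xaxis()
        if len(series) <= 12:
            ax.legend(fontsize="small")
        return ax


class InteractionScreen:
    """Resampling screen for survival-associated itemset interactions."""

    def __init__(self, data: SurvivalDataset,
                 config: ScreenConfig | None = None,
                 path_config: PathConfig | None = None):
        self.data = data
        self.config = config or ScreenConfig()
        self.path_config = path_config or PathConfig()

    @classmethod
    def from_dataframe(cls, items_df: pd.DataFrame, survival_df: pd.DataFrame,
                       **kwargs) -> "InteractionScreen":
        return cls(_dataset_from_frames(items_df, survival_df), **kwargs)

    def fit(self, seed: int | None = None) -> "ScreenResults":
        config = self.config
        if seed is not None:
            config = ScreenConfig(**{**config.__dict__, "seed": seed})
        run = run_screen(self.data, config, self.path_config)
        return ScreenResults(self, run)


class ScreenResults:
    """Ranked candidate interactions plus stability diagnostics."""

    def __init__(self, model: InteractionScreen, run: ScreenRun):
        self.model = model
        self.run = run

    @property
    def candidates(self):
        return self.run.candidates

    @property
    def m_bonferroni(self) -> int:
        return self.run.m_bonferroni

    def summary(self) -> pd.DataFrame:
        from .io import screen_results_frame

        return screen_results_frame(self.run.candidates,
                                    self.model.data.item_names)

    def stability(self) -> pd.DataFrame:
        return stability_report(self.run.iteration_logs,
                                self.run.config.min_occurrences)

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)
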