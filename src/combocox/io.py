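"""Reading and writing the package's tabular formats.

Schemas (all TSV or CSV, dialect auto-detected from the header line):

* expression matrix — header row of feature names, first column sample IDs;
* survival table — columns ``time`` and ``event`` (case-insensitive), first
  column sample IDs;
* item matrix — like the expression matrix but 0/1 with ``up.``/``dn.``
  prefixed column names;
* path trace — a JSON document plus a flat events table (one row per event:
  lambda, action, itemset, coefficient snapshot as a JSON string);
* screen results — the candidate table with combination names joined by
  `` * ``.

All joins are by sample ID, never by position.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binarize import BinarizationSpec, binarize_matrix
from .exceptions import InputError
from .path import PathTrace
from .screen import CandidateInteraction, IterationLog
from .survival import SurvivalDataset

logger = logging.getLogger("combocox")

SCREEN_COLUMNS = [
    "Gene combination",
    "LR test P-value",
    "Logrank P-value",
    "No. of occurrences",
    "Test logrank P-value",
]


@dataclass
class RunConfig:
    """Resolved inputs and settings of one command-line run."""

    expression: str | None = None
    survival: str | None = None
    items: str | None = None
    out_dir: str = "."
    seed: int = 0
    delimiter: str | None = None
    binarization: BinarizationSpec = field(default_factory=BinarizationSpec)


def _sniff_sep(path: str | Path, override: str | None = None) -> str:
    if override:
        return override
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV with the first column as the sample-ID index."""
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate sample IDs in {path}: {dupes[:5]}")
    return df


def _find_column(df: pd.DataFrame, name: str, path) -> str:
    for col in df.columns:
        if col.lower() == name:
            return col
    raise InputError(f"survival table {path} is missing a {name!r} column")


def load_inputs(
    config: RunConfig,
) -> tuple[SurvivalDataset, pd.DataFrame | None]:
    """Load and join the input tables into a :class:`SurvivalDataset`.

    Either ``expression`` (binarized on the fly) or a pre-binarized ``items``
    table must be given, plus the ``survival`` table.  Samples are joined on
    ID; unmatched IDs on either side are dropped with a warning.
    """
    if config.survival is None:
        raise InputError("a survival table is required")
    if (config.expression is None) == (config.items is None):
        raise InputError("give exactly one of an expression or an items table")

    surv = read_table(config.survival, config.delimiter)
    tcol = _find_column(surv, "time", config.survival)
    ecol = _find_column(surv, "event", config.survival)

    expr = None
    if config.expression is not None:
        expr = read_table(config.expression, config.delimiter)
        items_df = binarize_matrix(expr, config.binarization)
    else:
        items_df = read_table(config.items, config.delimiter)
        bad = ~items_df.isin([0, 1]).all()
        if bad.any():
            raise InputError(
                f"items table has non-binary columns: {list(items_df.columns[bad])[:5]}"
            )

    shared = items_df.index.intersection(surv.index)
    n_drop = (len(items_df) - len(shared)) + (len(surv) - len(shared))
    if n_drop:
        msg = (
            f"dropped {len(items_df) - len(shared)} covariate and "
            f"{len(surv) - len(shared)} survival rows with unmatched sample IDs"
        )
        warnings.warn(msg, RuntimeWarning)
        logger.warning(msg)
    if len(shared) == 0:
        raise InputError("no sample IDs shared between covariates and survival")
    # preserve covariate row order
    shared = [sid for sid in items_df.index if sid in set(shared)]
    items_df = items_df.loc[shared]
    surv = surv.loc[shared]
    if expr is not None:
        expr = expr.loc[shared]

    dataset = SurvivalDataset(
        items=items_df.to_numpy(),
        time=surv[tcol].to_numpy(dtype=float),
        event=surv[ecol].to_numpy(),
        item_names=[str(c) for c in items_df.columns],
        sample_ids=list(items_df.index),
    )
    return dataset, expr


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_dataset(dataset: SurvivalDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the item matrix and survival table as TSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    items_path = out_dir / "items.tsv"
    surv_path = out_dir / "survival.tsv"
    pd.DataFrame(
        dataset.items, index=dataset.sample_ids, columns=dataset.item_names
    ).rename_axis("sample").to_csv(items_path, sep="\t")
    pd.DataFrame(
        {"time": dataset.time, "event": dataset.event}, index=dataset.sample_ids
    ).rename_axis("sample").to_csv(surv_path, sep="\t", float_format="%.17g")
    return {"items": items_path, "survival": surv_path}


def trace_to_dict(trace: PathTrace) -> dict:
    names = trace.item_names

    def render(items):
        return " * ".join(names[i] for i in items)

    return {
        "schema": "combocox/path-trace/1",
        "lambda_max": trace.lambda_max,
        "termination_reason": trace.termination_reason,
        "events": [
            {
                "lambda": e.lam,
                "action": e.action,
                "itemset": render(e.itemset.items),
                "items": list(e.itemset.items),
            }
            for e in trace.events
        ],
        "states": [
            {
                "lambda": s.lam,
                "log_partial_likelihood": s.loss,
                "active": [
                    {
                        "itemset": render(t.items),
                        "items": list(t.items),
                        "beta": float(b),
                        "support": t.support,
                    }
                    for t, b in zip(s.active, s.beta_active)
                ],
            }
            for s in trace.states
        ],
    }


def trace_events_frame(trace: PathTrace) -> pd.DataFrame:
    """One row per path event with the coefficient snapshot at that lambda."""
    names = trace.item_names
    rows = []
    for e in trace.events:
        snap_state = None
        for s in trace.states:
            if s.lam <= e.lam + 1e-15:
                snap_state = s
                break
        snapshot = (
            {t.name(names): float(b) for t, b in zip(snap_state.active,
                                                     snap_state.beta_active)}
            if snap_state is not None
            else {}
        )
        rows.append(
            {
                "lambda": e.lam,
                "action": e.action,
                "itemset": e.itemset.name(names),
                "coefficients": json.dumps(snapshot),
            }
        )
    return pd.DataFrame(rows, columns=["lambda", "action", "itemset", "coefficients"])


def screen_results_frame(
    candidates: list[CandidateInteraction], item_names: list[str]
) -> pd.DataFrame:
    """Candidate table in the conventional report layout."""
    rows = [
        {
            "Gene combination": c.itemset.name(item_names),
            "LR test P-value": c.lr_pvalue,
            "Logrank P-value": c.logrank_pvalue,
            "No. of occurrences": c.occurrences,
            "Test logrank P-value": c.test_logrank_pvalue,
            "Bonferroni significant": c.bonferroni_significant,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS + ["Bonferroni significant"])


def write_manifest(dest: str | Path, seed: int, **sections) -> None:
    """Record config, seed and package version next to every output."""
    doc = {"package": "combocox", "version": __version__, "seed": seed}
    for key, value in sections.items():
        if hasattr(value, "__dataclass_fields__"):
            value = asdict(value)
        doc[key] = value
    Path(dest).write_text(json.dumps(doc, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# -- iteration logs (screen resume) -----------------------------------------

def iteration_log_to_json(log: IterationLog) -> str:
    return json.dumps(
        {
            "index": log.index,
            "skipped": log.skipped,
            "n_events": log.n_events,
            "kept": [[list(items), p] for items, p in log.kept],
        }
    )


def iteration_log_from_json(line: str) -> IterationLog:
    doc = json.loads(line)
    return IterationLog(
        index=doc["index"],
        skipped=doc["skipped"],
        n_events=doc["n_events"],
        kept=[(tuple(items), float(p)) for items, p in doc["kept"]],
    )
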