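"""Across-run analyses of per-phase network metrics.

Inputs are long-format tables of per-run, per-phase, per-region averaged
metric scores (as produced by ``network_metrics.metrics_for_phase``), columns
``subject, run, metric, region, value``.  The analyses:

* top-10 ranking frequencies per metric across runs;
* per-region counts of runs where planning beats execution (and vice versa);
* the planning-vs-execution global-efficiency comparison per run number;
* Pearson correlation between global efficiency and a behavioral score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ValidationError

REQUIRED_COLS = {"subject", "run", "metric", "region", "value"}


def _check(df: pd.DataFrame) -> None:
    missing = REQUIRED_COLS - set(df.columns)
    if missing:
        raise ValidationError(f"metrics table is missing columns {sorted(missing)}")


def rank_top_regions(per_run: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Frequency of each region among the top-``top_n`` scores of each run.

    Ties break deterministically by region id (recorded in the ranking order).
    Returns columns ``metric, region, frequency``.
    """
    _check(per_run)
    rows = []
    for (metric, subject, run), grp in per_run.groupby(["metric", "subject", "run"]):
        grp = grp.sort_values(["value", "region"], ascending=[False, True], kind="mergesort")
        n = min(top_n, len(grp))
        if n < top_n:
            import warnings

            warnings.warn(
                f"only {n} regions available for top-{top_n} in {metric}/{subject}/run{run}",
                stacklevel=2,
            )
        rows.append(grp.head(n)[["metric", "region"]])
    tallies = (
        pd.concat(rows).groupby(["metric", "region"]).size().rename("frequency").reset_index()
    )
    return tallies


def difference_counts(planning: pd.DataFrame, execution: pd.DataFrame) -> pd.DataFrame:
    """Per (metric, region): counts of runs with planning > execution,
    execution > planning, and exact ties.  The three counts always sum to the
    number of matched runs."""
    _check(planning)
    _check(execution)
    keys = ["subject", "run", "metric", "region"]
    merged = planning.merge(execution, on=keys, suffixes=("_plan", "_exec"))
    if len(merged) != len(planning) or len(merged) != len(execution):
        raise ValidationError("planning and execution tables do not match run-for-run")
    diff = merged["value_plan"] - merged["value_exec"]
    merged = merged.assign(
        planning_higher=(diff > 0).astype(int),
        execution_higher=(diff < 0).astype(int),
        tie=(diff == 0).astype(int),
    )
    return (
        merged.groupby(["metric", "region"])[["planning_higher", "execution_higher", "tie"]]
        .sum()
        .reset_index()
    )


def global_efficiency_comparison(per_run: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Planning-vs-execution global-efficiency counts.

    ``per_run`` needs columns ``subject, run, phase, e_global``.  Returns a
    per-run-number table (columns ``run, planning, execution, tie``) plus an
    overall dict with counts across all runs.
    """
    need = {"subject", "run", "phase", "e_global"}
    if not need.issubset(per_run.columns):
        raise ValidationError(f"table needs columns {sorted(need)}")
    wide = per_run.pivot_table(
        index=["subject", "run"], columns="phase", values="e_global"
    ).reset_index()
    for ph in ("planning", "execution"):
        if ph not in wide.columns:
            raise ValidationError(f"missing phase {ph!r}")
    wide = wide.assign(
        planning_higher=(wide["planning"] > wide["execution"]).astype(int),
        execution_higher=(wide["execution"] > wide["planning"]).astype(int),
        tie=(wide["planning"] == wide["execution"]).astype(int),
    )
    table = (
        wide.groupby("run")[["planning_higher", "execution_higher", "tie"]]
        .sum()
        .reset_index()
        .rename(columns={"planning_higher": "planning", "execution_higher": "execution"})
    )
    overall = {
        "planning_higher": int(wide["planning_higher"].sum()),
        "execution_higher": int(wide["execution_higher"].sum()),
        "tie": int(wide["tie"].sum()),
        "n_runs": int(len(wide)),
    }
    return table, overall


def behavior_correlation(e_global: np.ndarray, extra_moves: np.ndarray) -> tuple[float, float]:
    """Pearson r (two-sided t-test p on n-2 df) between global efficiency and
    the behavioral error score."""
    x = np.asarray(e_global, dtype=float)
    y = np.asarray(extra_moves, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 matched observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
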