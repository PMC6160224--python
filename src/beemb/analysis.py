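"""Aggregation and statistics for experiment outputs.

Performance curves are averaged the way behavioural studies report them:
within-bee percent correct per block of trials, then mean and SEM over the
bee population. Hypothesis tests are 2x2 Pearson chi-square tests with
Yates continuity correction (the convention of the R ``chisq.test``
default for 2x2 tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable2x2", "block_performance", "chi_square_2x2",
           "learning_test", "vs_chance_test", "sufficiency_report"]

ALPHA = 0.01


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 test: rows are conditions, columns success/failure."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("grand total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def block_performance(records: pd.DataFrame,
                      block_size: int = 10) -> pd.DataFrame:
    """Per-block percent correct with SEM over bees.

    ``records`` needs columns ``bee_id``, ``trial_index`` (0-based within
    bee) and boolean ``correct``. Block b pools trials b*block_size ..
    (b+1)*block_size - 1 within each bee; the block mean is the average over
    bees of the within-bee percentage, and the SEM is over bees. Incomplete
    blocks are rejected.
    """
    if records.empty:
        raise ValueError("no trial records")
    df = records.copy()
    n_trials = df.groupby("bee_id")["trial_index"].count()
    if (n_trials % block_size).any() or n_trials.nunique() != 1:
        raise ValueError("each bee needs a whole number of complete blocks")
    df["block"] = df["trial_index"] // block_size
    per_bee = (df.groupby(["bee_id", "block"])["correct"]
                 .mean().mul(100.0).rename("percent_correct").reset_index())
    out = per_bee.groupby("block")["percent_correct"].agg(
        mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
    return out.reset_index()


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square with continuity correction on a 2x2 table.

    Raises ValueError when a marginal is zero (the statistic is undefined).
    Returns (statistic, p) with p from chi-square with 1 df.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square statistic undefined")
    res = stats.chi2_contingency(arr, correction=True)
    return float(res.statistic), float(res.pvalue)


def learning_test(first_correct: int, first_total: int,
                  last_correct: int, last_total: int) -> tuple[float, float]:
    """Test for learning: first-block vs last-block pooled correct counts."""
    table = ContingencyTable2x2(first_correct, first_total - first_correct,
                                last_correct, last_total - last_correct)
    return chi_square_2x2(table)


def vs_chance_test(successes: int, total: int,
                   chance: float = 0.5) -> tuple[float, float]:
    """Observed success/failure counts against an equal-split (or other
    fixed-probability) expectation table of the same size."""
    expected = int(round(total * chance))
    table = ContingencyTable2x2(successes, total - successes,
                                expected, total - expected)
    return chi_square_2x2(table)


def sufficiency_report(results: dict) -> pd.DataFrame:
    """Build the pathway-requirement table from lesioned runs.

    ``results`` maps (task, pathway) to a dict with keys ``successes``,
    ``total`` and optionally ``baseline_successes``/``baseline_total`` (used
    for acquisition tasks where "chance" is the naive response rate). A
    pathway earns Y for a task when, learning through that pathway alone,
    performance is significantly above chance (alpha = 0.01) in the correct
    direction.
    """
    tasks = sorted({t for t, _ in results}, key=str)
    pathways = sorted({p for _, p in results})
    rows = []
    for task in tasks:
        row = {"task": task}
        for pathway in pathways:
            cell = results.get((task, pathway))
            if cell is None:
                raise ValueError(f"missing lesion run for {task}/{pathway}")
            succ, total = cell["successes"], cell["total"]
            if "baseline_successes" in cell:
                b_s, b_t = cell["baseline_successes"], cell["baseline_total"]
                try:
                    _, p = learning_test(b_s, b_t, succ, total)
                except ValueError:  # e.g. nothing ever responds
                    p = 1.0
                above = succ / total > b_s / b_t
            else:
                try:
                    _, p = vs_chance_test(succ, total)
                except ValueError:
                    p = 1.0
                above = succ / total > 0.5
            row[pathway] = "Y" if (p < ALPHA and above) else "N"
        rows.append(row)
    return pd.DataFrame(rows).set_index("task")
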