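"""Validity reporting: quartile tables, Q4-Q1 contrasts, forest summaries.

Construct validity of a cohort-relative diet score is conventionally
shown as a table of baseline characteristics and food/nutrient intakes
by score quartile — continuous variables as mean (SD), categorical ones
as N [%] — together with top-versus-bottom quartile contrasts ("+8 g/d
of fiber", "-200 kcal/d of energy"). Criterion validity is shown as a
forest-style table of hazard ratios per outcome with Q1 as the 1.00
reference row.

Rounding of the headline contrasts is decimal half-up at the precision
chosen for each variable; the unrounded difference is always retained
alongside, because published contrasts are often loosely rounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "QuartileTable",
    "ContrastResult",
    "quartile_characteristics",
    "q4_vs_q1_contrast",
    "incidence_proportion",
    "forest_table",
]

QUARTILES = ["Q1", "Q2", "Q3", "Q4"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (0.5 always away from zero on magnitude)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class QuartileTable:
    """Per-quartile summaries: n, mean/SD for continuous, N/% for categorical."""

    n: pd.Series                      # quartile -> count
    continuous: pd.DataFrame          # MultiIndex (variable, stat in {mean, sd})
    categorical: pd.DataFrame         # MultiIndex (variable, level) x quartile

    def mean(self, variable: str, quartile: str) -> float:
        return float(self.continuous.loc[(variable, "mean"), quartile])

    def to_frame(self) -> pd.DataFrame:
        """Flat printable table with 'mean (sd)' / 'N [%]' formatted cells."""
        rows = {}
        rows["n"] = self.n.astype(int).astype(str)
        for var in self.continuous.index.get_level_values(0).unique():
            m = self.continuous.loc[(var, "mean")]
            s = self.continuous.loc[(var, "sd")]
            rows[var] = m.round(1).astype(str) + " (" + s.round(1).astype(str) + ")"
        for var, lev in self.categorical.index:
            n = self.categorical.loc[(var, lev)]
            tot = self.n.reindex(n.index)
            pct = (100 * n / tot).round(1)
            rows[f"{var}={lev}"] = (
                n.astype(int).astype(str) + " [" + pct.astype(str) + "]"
            )
        return pd.DataFrame(rows).T


def quartile_characteristics(
    cohort: pd.DataFrame,
    quartile: pd.Series,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> QuartileTable:
    """Summarize cohort variables within score quartiles.

    SD uses the n-1 denominator. Quartile levels with no members are
    omitted (a degenerate cohort can occupy a single quartile).
    """
    df = cohort.copy()
    df["_q"] = pd.Categorical(
        np.asarray(quartile.reindex(df.index) if hasattr(quartile, "reindex")
                   else quartile),
        categories=QUARTILES,
    )
    present = [q for q in QUARTILES if (df["_q"] == q).any()]
    df = df.loc[df["_q"].notna()]
    if continuous is None:
        continuous = [c for c in cohort.columns
                      if pd.api.types.is_numeric_dtype(cohort[c])]
    if categorical is None:
        categorical = [c for c in cohort.columns
                       if not pd.api.types.is_numeric_dtype(cohort[c])]
    counts = df.groupby("_q", observed=True).size().reindex(present)
    counts.name = "n"

    cont_rows = {}
    for var in continuous:
        grp = df.groupby("_q", observed=True)[var]
        cont_rows[(var, "mean")] = grp.mean().reindex(present)
        cont_rows[(var, "sd")] = grp.std(ddof=1).reindex(present)
    cont = (pd.DataFrame(cont_rows).T if cont_rows
            else pd.DataFrame(columns=present))
    if cont_rows:
        cont.index = pd.MultiIndex.from_tuples(cont.index,
                                               names=["variable", "stat"])

    cat_rows = {}
    for var in categorical:
        vc = (df.groupby("_q", observed=True)[var]
              .value_counts().unstack("_q", fill_value=0))
        for lev in vc.index:
            cat_rows[(var, str(lev))] = vc.loc[lev].reindex(present,
                                                            fill_value=0)
    cat = (pd.DataFrame(cat_rows).T if cat_rows
           else pd.DataFrame(columns=present))
    if cat_rows:
        cat.index = pd.MultiIndex.from_tuples(cat.index,
                                              names=["variable", "level"])
    return QuartileTable(n=counts, continuous=cont, categorical=cat)


@dataclass
class ContrastResult:
    """Top-vs-bottom quartile contrast for one variable."""

    variable: str
    q1_mean: float
    q4_mean: float
    difference: float          # q4 - q1, exact (before rounding)
    percent_change: float      # 100 * difference / q1_mean
    rounded: float             # difference after the declared rounding
    rounding: str


_ROUNDING = {"integer": 0, "one-decimal": 1}


def q4_vs_q1_contrast(
    table: QuartileTable, variable: str, rounding: str = "integer"
) -> ContrastResult:
    """Q4 minus Q1 contrast from the table's means.

    ``rounding`` is ``"integer"``, ``"nearest-10"`` or ``"one-decimal"``
    (half-up); the exact difference is retained in ``difference``.
    """
    q1 = table.mean(variable, "Q1")
    q4 = table.mean(variable, "Q4")
    diff = q4 - q1
    if rounding == "nearest-10":
        rounded = round_half_up(diff / 10.0) * 10.0
    elif rounding in _ROUNDING:
        rounded = round_half_up(diff, _ROUNDING[rounding])
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    pct = 100.0 * diff / q1 if q1 != 0 else float("nan")
    return ContrastResult(
        variable=variable, q1_mean=q1, q4_mean=q4, difference=diff,
        percent_change=pct, rounded=rounded, rounding=rounding,
    )


def incidence_proportion(n_events: int, n_cohort: int, decimals: int = 1) -> float:
    """Percentage of the cohort with an incident event, half-up rounded."""
    if n_cohort <= 0:
        raise ValueError("n_cohort must be positive")
    if not 0 <= n_events <= n_cohort:
        raise ValueError("need 0 <= n_events <= n_cohort")
    return round_half_up(100.0 * n_events / n_cohort, decimals)


def forest_table(results) -> pd.DataFrame:
    """Ordered forest-style rows from a collection of Cox results.

    Rows are grouped by outcome; quartile exposures get a leading Q1
    reference row with HR 1.00 and no interval.
    """
    rows = []
    for res in results:
        if res.exposure == "score_quartiles":
            rows.append({
                "outcome": res.outcome, "exposure_level": "Q1",
                "hr": 1.00, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "reference": True,
                "n": res.n, "n_events": res.n_events,
            })
        for lev in res.hr.index:
            rows.append({
                "outcome": res.outcome, "exposure_level": lev,
                "hr": res.hr[lev], "ci_low": res.ci_low[lev],
                "ci_high": res.ci_high[lev], "p": res.p[lev],
                "reference": False, "n": res.n, "n_events": res.n_events,
            })
    if not rows:
        return pd.DataFrame(columns=[
            "outcome", "exposure_level", "hr", "ci_low", "ci_high", "p",
            "reference", "n", "n_events",
        ])
    return pd.DataFrame(rows)
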