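"""Heart-protective diet score (HPDS): signed quintile-rank scoring.

For each of the 22 food groups, cohort intake (grams/week) is ranked into
quintiles against the cohort's own empirical 20/40/60/80th percentiles
(linear-interpolation definition). A participant's quintile rank r in
{0,...,4} is the number of cutpoints strictly below their intake, so ties
with a cutpoint fall into the lower quintile and, when zero inflation
collapses boundaries, all zero consumers share the lowest rank. The group
subscore is direction x (r - 2), i.e. in [-2, +2] with sign +1 for
heart-protective groups and -1 for discouraged groups; the HPDS total is
the sum over groups, an integer in [-44, +44]. An alternative 1-5
("quintile15", hPDI-style reverse-coded) convention is available.

Cohort score quartiles Q1 (lowest adherence, reference) to Q4 are assigned
from the 25/50/75th percentiles of the total, again with ties to the lower
category.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .taxonomy import Taxonomy, default_taxonomy

__all__ = [
    "HeartProtectiveDietScorer",
    "HPDSResult",
    "quintile_cutpoints",
    "score_group",
    "compute_hpds",
    "assign_score_quartiles",
    "reliability",
]

logger = logging.getLogger(__name__)

CENTERED = "centered"       # direction * (rank - 2), total in [-44, 44]
QUINTILE15 = "quintile15"   # rank+1 for +1 groups, 5-rank for -1 groups


def quintile_cutpoints(values: np.ndarray | pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Empirical 20/40/60/80th percentile cutpoints for one group.

    Returns ``(cutpoints, degenerate)`` where ``degenerate[i]`` flags a
    boundary that collapsed onto its neighbour (typical when more than 20%
    of the cohort reports zero intake). Requires at least 5 non-missing
    values.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 5:
        raise ValueError(
            f"need >= 5 non-missing values for quintile cutpoints, got {v.size}"
        )
    cuts = np.percentile(v, [20, 40, 60, 80], method="linear")
    degenerate = np.zeros(4, dtype=bool)
    for i in range(4):
        degenerate[i] = (i > 0 and cuts[i] == cuts[i - 1]) or (
            i < 3 and cuts[i] == cuts[i + 1]
        )
    return cuts, degenerate


def score_group(
    intake: float | np.ndarray,
    cutpoints: np.ndarray,
    direction: int,
    convention: str = CENTERED,
) -> int | np.ndarray:
    """Signed quintile subscore(s) for one group.

    Rank = number of cutpoints strictly below the intake (ties fall into
    the lower quintile; collapsed cutpoints merge quintiles downward).
    """
    cuts = np.asarray(cutpoints, dtype=float)
    rank = (np.asarray(intake, dtype=float)[..., None] > cuts).sum(axis=-1)
    if convention == CENTERED:
        sub = direction * (rank - 2)
    elif convention == QUINTILE15:
        sub = np.where(direction == 1, rank + 1, 5 - rank)
    else:
        raise ValueError(f"unknown scoring convention {convention!r}")
    if np.isscalar(intake) or np.ndim(intake) == 0:
        return int(sub)
    return sub.astype(int)


class HeartProtectiveDietScorer(TransformerMixin, BaseEstimator):
    """Cohort-relative diet-quality scorer (sklearn transformer).

    ``fit(X)`` learns the per-group quintile cutpoints from a cohort's
    participant x group intake matrix; ``transform(X)`` returns the signed
    per-group subscores for (possibly the same) participants, and
    :meth:`score_participants` additionally totals them and assigns cohort
    score quartiles.

    Parameters
    ----------
    taxonomy
        The 22-group taxonomy; defaults to the packaged one.
    convention
        ``"centered"`` (default): subscore = direction x (rank - 2),
        total integer in [-44, 44]. ``"quintile15"``: hPDI-style 1-5 with
        reverse coding for discouraged groups, total in [22, 110].

    Attributes
    ----------
    cutpoints_ : DataFrame (4 x n_groups)
        Learned 20/40/60/80th percentile thresholds per group.
    degenerate_ : DataFrame (4 x n_groups) of bool
        Collapsed-boundary flags per group.
    group_ids_ : list of str
    """

    def __init__(
        self, taxonomy: Taxonomy | None = None, convention: str = CENTERED
    ):
        self.taxonomy = taxonomy
        self.convention = convention

    def _taxonomy(self) -> Taxonomy:
        return self.taxonomy if self.taxonomy is not None else default_taxonomy()

    def _check_matrix(self, X: pd.DataFrame, tax: Taxonomy) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a participant x group intake DataFrame")
        missing = [g for g in tax.group_ids if g not in X.columns]
        extra = [c for c in X.columns if c not in tax.group_ids]
        if missing or extra:
            raise ValueError(
                f"intake matrix columns do not match taxonomy groups "
                f"(missing={missing}, unexpected={extra})"
            )
        X = X[tax.group_ids]
        if (X.to_numpy() < 0).any():
            raise ValueError("intake matrix contains negative entries")
        return X

    def fit(self, X: pd.DataFrame, y=None) -> "HeartProtectiveDietScorer":
        tax = self._taxonomy()
        X = self._check_matrix(X, tax)
        cuts = {}
        degen = {}
        for gid in tax.group_ids:
            c, d = quintile_cutpoints(X[gid].to_numpy())
            cuts[gid] = c
            degen[gid] = d
        idx = pd.Index(["p20", "p40", "p60", "p80"], name="cutpoint")
        self.cutpoints_ = pd.DataFrame(cuts, index=idx)
        self.degenerate_ = pd.DataFrame(degen, index=idx)
        self.group_ids_ = list(tax.group_ids)
        self.n_features_in_ = len(self.group_ids_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Signed per-group subscores (participant x group DataFrame)."""
        check_is_fitted(self, "cutpoints_")
        tax = self._taxonomy()
        X = self._check_matrix(X, tax)
        out = {}
        for gid in self.group_ids_:
            out[gid] = score_group(
                X[gid].to_numpy(),
                self.cutpoints_[gid].to_numpy(),
                tax[gid].direction,
                convention=self.convention,
            )
        return pd.DataFrame(out, index=X.index)

    def score_participants(self, X: pd.DataFrame) -> "HPDSResult":
        """Subscores, totals, quartiles and cohort summary for a cohort."""
        subs = self.transform(X)
        totals = subs.sum(axis=1).rename("total_score")
        quart = assign_score_quartiles(totals)
        return HPDSResult(
            subscores=subs,
            total=totals,
            quartile=quart,
            convention=self.convention,
        )


@dataclass
class HPDSResult:
    """Per-participant scores plus cohort summary statistics."""

    subscores: pd.DataFrame
    total: pd.Series
    quartile: pd.Series
    convention: str = CENTERED

    @property
    def summary(self) -> dict[str, float]:
        t = self.total
        return {
            "mean": float(t.mean()),
            "sd": float(t.std(ddof=1)) if len(t) > 1 else float("nan"),
            "min": float(t.min()),
            "max": float(t.max()),
            "n": int(len(t)),
        }

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV-ready table: total, quartile, subscore_<group> x 22."""
        sub = self.subscores.add_prefix("subscore_")
        out = pd.concat(
            [self.total.rename("total_score"), self.quartile.rename("quartile"), sub],
            axis=1,
        )
        out.index.name = "participant_id"
        return out


def compute_hpds(
    matrix: pd.DataFrame,
    taxonomy: Taxonomy | None = None,
    convention: str = CENTERED,
) -> HPDSResult:
    """Fit-and-score a cohort in one call (cutpoints from the same cohort)."""
    scorer = HeartProtectiveDietScorer(taxonomy=taxonomy, convention=convention)
    return scorer.fit(matrix).score_participants(matrix)


def assign_score_quartiles(totals: pd.Series | np.ndarray) -> pd.Series:
    """Assign cohort quartile labels Q1..Q4 from 25/50/75th percentiles.

    Ties with a cutpoint go to the lower quartile. A fully degenerate
    distribution (all totals equal) puts everyone in Q1 with a logged
    warning.
    """
    t = pd.Series(np.asarray(totals, dtype=float),
                  index=getattr(totals, "index", None))
    if len(t) < 4:
        raise ValueError(f"need n >= 4 to assign quartiles, got {len(t)}")
    cuts = np.percentile(t.to_numpy(), [25, 50, 75], method="linear")
    if cuts[0] == cuts[2]:
        logger.warning(
            "degenerate score distribution: quartile cutpoints collapsed; "
            "assignment merges toward Q1"
        )
    rank = (t.to_numpy()[:, None] > cuts).sum(axis=1)
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])[rank]
    return pd.Series(pd.Categorical(labels, categories=["Q1", "Q2", "Q3", "Q4"]),
                     index=t.index, name="quartile")


def reliability(
    baseline_scores: np.ndarray | pd.Series,
    averaged_scores: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Pearson correlation between baseline and repeat-averaged scores.

    Quantifies how well a single 24 h recall tracks the multi-recall
    average of the same index — the usual check that one-occasion scoring
    is an acceptable exposure measurement. Returns ``(r, two-sided p)``
    from the t transform.
    """
    x = np.asarray(baseline_scores, dtype=float)
    y = np.asarray(averaged_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("baseline and averaged score vectors must be paired")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in scores")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    return float(r), float(p)
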