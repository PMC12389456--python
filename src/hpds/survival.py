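"""Cause-specific Cox survival analysis on the age timescale.

Associations between the diet score and each outcome are estimated with
Cox proportional-hazards models using attained age as the analysis time:
participants enter the risk set at their recruitment age (left
truncation) and leave at the age of event or censoring. Ties are handled
by Efron's approximation (age-scale data are tie-heavy); Breslow is
selectable. The exposure is the cohort score quartile (Q1, lowest
adherence, as reference), the continuous score (linear-trend test), or a
single standardized food-group intake. The proportional-hazards
assumption is checked per covariate with Schoenfeld-residual tests;
covariates failing at p < 0.05 are moved from the linear predictor to
strata (continuous covariates are binned into quartiles first) and the
model is refit. Multiplicative interaction terms test effect
modification by sex or deprivation; p-values across an analysis family
are adjusted by Benjamini-Hochberg step-up FDR control.

Estimation is delegated to lifelines' ``CoxPHFitter`` (partial
likelihood with ``entry_col`` left truncation); this module owns the
model specification, exposure coding, diagnostics-driven refitting and
multiplicity handling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as _stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .taxonomy import Taxonomy

__all__ = [
    "CoxSpec",
    "CoxResult",
    "CoxSurvivalModel",
    "fit_cox",
    "trend_test",
    "check_ph_and_stratify",
    "interaction_test",
    "per_food_group_models",
    "bh_adjust",
    "exclude_prevalent",
]

logger = logging.getLogger(__name__)

QUARTILE_LEVELS = ["Q1", "Q2", "Q3", "Q4"]


class DegenerateFitError(ValueError):
    """Model not estimable on the given data (constant exposure, no events...)."""


@dataclass(frozen=True)
class CoxSpec:
    """Specification of one Cox model.

    exposure: ``"score_quartiles"``, ``"continuous_score"``, or the column
    name of a single food-group intake (modelled per SD). Quartile models
    use Q1 as the reference level.
    """

    exposure: str = "score_quartiles"
    covariates: tuple[str, ...] = ()
    strata: tuple[str, ...] = ()
    outcome: str = "cvd"
    interaction_term: str | None = None
    ties: str = "efron"


@dataclass
class CoxResult:
    """Hazard ratios with inference and diagnostics for one fitted model."""

    outcome: str
    exposure: str
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    n: int
    n_events: int
    trend_p: float | None = None
    interaction_p: float | None = None
    ph_diagnostics: pd.DataFrame | None = None
    strata_applied: tuple[str, ...] = ()
    p_adjusted: pd.Series | None = None
    non_estimable: tuple[str, ...] = ()
    exposure_terms: tuple[str, ...] = ()

    def to_rows(self) -> pd.DataFrame:
        """Long-format report rows (one per exposure term)."""
        rows = pd.DataFrame({
            "outcome": self.outcome,
            "exposure_level": self.hr.index,
            "hr": self.hr.to_numpy(),
            "ci_low": self.ci_low.to_numpy(),
            "ci_high": self.ci_high.to_numpy(),
            "p": self.p.to_numpy(),
        })
        rows["p_adjusted"] = (
            self.p_adjusted.to_numpy() if self.p_adjusted is not None else np.nan
        )
        rows["trend_p"] = self.trend_p
        rows["n"] = self.n
        rows["n_events"] = self.n_events
        rows["strata"] = ";".join(self.strata_applied)
        return rows


_CATEGORICAL = {
    "sex", "ethnicity", "income", "physical_activity", "smoking", "quartile",
}


def _design_matrix(
    data: pd.DataFrame, columns: tuple[str, ...]
) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-encode categoricals (first level as reference), pass numerics."""
    parts, names = [], []
    for col in columns:
        s = data[col]
        if (s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)
                or col in _CATEGORICAL):
            d = pd.get_dummies(s.astype("category"), prefix=col,
                               drop_first=True, dtype=float)
            parts.append(d)
            names.extend(d.columns)
        elif s.dtype == bool:
            parts.append(s.astype(float).to_frame(col))
            names.append(col)
        else:
            parts.append(s.astype(float).to_frame(col))
            names.append(col)
    if not parts:
        return pd.DataFrame(index=data.index), names
    return pd.concat(parts, axis=1), names


def _exposure_design(
    data: pd.DataFrame, spec: CoxSpec
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Exposure columns and the list of non-estimable levels (zero events)."""
    non_estimable = []
    if spec.exposure == "score_quartiles":
        q = pd.Categorical(data["quartile"], categories=QUARTILE_LEVELS)
        if len(pd.unique(q.remove_unused_categories())) < 2:
            raise DegenerateFitError("quartile exposure is constant")
        dm = pd.get_dummies(q, prefix="quartile", dtype=float)
        dm.index = data.index
        events = data["event"].astype(bool)
        for lev in QUARTILE_LEVELS:
            colname = f"quartile_{lev}"
            in_level = dm[colname] == 1
            if in_level.any() and not events[in_level].any():
                non_estimable.append(lev)
                logger.warning(
                    "exposure level %s has zero events; HR non-estimable", lev
                )
        terms = [f"quartile_{lev}" for lev in QUARTILE_LEVELS[1:]]
        return dm[terms], terms, non_estimable
    col = ("total_score" if spec.exposure == "continuous_score"
           else spec.exposure)
    x = data[col].astype(float)
    if x.nunique() < 2:
        raise DegenerateFitError(f"exposure {col!r} is constant")
    sd = x.std(ddof=1)
    out = ((x - x.mean()) / sd).to_frame(f"{col}_per_sd")
    return out, [f"{col}_per_sd"], non_estimable


def _assemble(data: pd.DataFrame, spec: CoxSpec):
    for required in ("entry_age", "exit_age", "event"):
        if required not in data.columns:
            raise ValueError(f"data missing required column {required!r}")
    expo, terms, non_est = _exposure_design(data, spec)
    cov, cov_names = _design_matrix(data, spec.covariates)
    frame = pd.concat(
        [data[["entry_age", "exit_age", "event"]], expo, cov], axis=1
    )
    strata_cols = []
    for s in spec.strata:
        col = data[s]
        if col.dtype.kind in "fi" and col.nunique() > 8:
            binned = pd.qcut(col, 4, duplicates="drop")
            frame[f"{s}_strata"] = binned
            strata_cols.append(f"{s}_strata")
        else:
            frame[f"{s}_strata"] = col.astype(str)
            strata_cols.append(f"{s}_strata")
    return frame, terms, cov_names, strata_cols, non_est


def _fit_lifelines(frame, strata_cols):
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            frame,
            duration_col="exit_age",
            event_col="event",
            entry_col="entry_age",
            strata=strata_cols or None,
            robust=False,
            fit_options={"step_size": 0.5},
        )
    return cph


def _fit_summary(frame, strata_cols, ties) -> pd.DataFrame:
    """Fit and return a uniform per-term summary table.

    Efron ties go through lifelines; Breslow through statsmodels PHReg
    (lifelines implements Efron only). Columns: coef, se, exp(coef),
    ci_low, ci_high, p.
    """
    if ties == "efron":
        cph = _fit_lifelines(frame, strata_cols)
        s = cph.summary
        return pd.DataFrame({
            "coef": s["coef"],
            "se": s["se(coef)"],
            "exp(coef)": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        })
    if ties != "breslow":
        raise ValueError(f"unknown tie-handling method {ties!r}")
    from statsmodels.duration.hazard_regression import PHReg

    xcols = [c for c in frame.columns
             if c not in ("entry_age", "exit_age", "event") + tuple(strata_cols)]
    strata = (
        frame[list(strata_cols)].astype(str).agg("|".join, axis=1)
        if strata_cols else None
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(
            frame["exit_age"].to_numpy(),
            frame[xcols].to_numpy(float),
            status=frame["event"].to_numpy(),
            entry=frame["entry_age"].to_numpy(),
            strata=strata.to_numpy() if strata is not None else None,
            ties="breslow",
        )
        res = model.fit()
    ci = res.conf_int()
    return pd.DataFrame({
        "coef": res.params,
        "se": res.bse,
        "exp(coef)": np.exp(res.params),
        "ci_low": np.exp(ci[:, 0]),
        "ci_high": np.exp(ci[:, 1]),
        "p": res.pvalues,
    }, index=xcols)


def _suffix_sums(key: np.ndarray, w: np.ndarray, wx: np.ndarray,
                 wxx: np.ndarray):
    """Sorted keys with suffix cumulative sums of w, w*x, w*x xT."""
    order = np.argsort(key, kind="stable")
    k = key[order]
    sw = np.cumsum(w[order][::-1])[::-1]
    swx = np.cumsum(wx[order][::-1], axis=0)[::-1]
    swxx = np.cumsum(wxx[order][::-1], axis=0)[::-1]
    return k, sw, swx, swxx


def schoenfeld_ph_test(
    frame: pd.DataFrame,
    xcols: list[str],
    beta: np.ndarray,
    strata_cols: list[str] | None = None,
    time_transform: str = "rank",
) -> pd.DataFrame:
    """Schoenfeld-residual proportional-hazards test with left truncation.

    Grambsch-Therneau score test: at each event age t the Schoenfeld
    residual is the event's covariate vector minus the risk-weighted mean
    over the risk set {entry < t <= exit} (risk sets honor delayed entry,
    which standard residual routines do not support). The residuals'
    correlation with a transform g(t) of event age (``"rank"`` or
    ``"identity"``) gives a chi-square(1) statistic per term and a global
    chi-square(p) statistic. Strata contribute within-stratum risk sets.

    Returns a table with one row per term plus a ``__global__`` row.
    """
    p = len(xcols)
    strata_cols = strata_cols or []
    groups = (frame.groupby([frame[c].astype(str) for c in strata_cols])
              if strata_cols else [(None, frame)])
    ev_times_all, s_all = [], []
    v_sum = np.zeros((p, p))
    d_total = 0
    for _, sub in groups:
        x = sub[xcols].to_numpy(float)
        entry = sub["entry_age"].to_numpy(float)
        exit_ = sub["exit_age"].to_numpy(float)
        event = sub["event"].to_numpy() == 1
        if not event.any():
            continue
        w = np.exp(x @ beta)
        wx = w[:, None] * x
        wxx = w[:, None, None] * (x[:, :, None] * x[:, None, :])
        ke, swe, swxe, swxxe = _suffix_sums(exit_, w, wx,
                                            wxx.reshape(len(x), -1))
        ka, swa, swxa, swxxa = _suffix_sums(entry, w, wx,
                                            wxx.reshape(len(x), -1))
        t_ev = exit_[event]
        x_ev = x[event]
        for t, xi in zip(t_ev, x_ev):
            ie = np.searchsorted(ke, t, side="left")    # exit >= t
            ia = np.searchsorted(ka, t, side="left")    # entry >= t
            sw = swe[ie] - (swa[ia] if ia < len(ka) else 0.0)
            sx = swxe[ie] - (swxa[ia] if ia < len(ka) else 0.0)
            sxx = swxxe[ie] - (swxxa[ia] if ia < len(ka) else 0.0)
            xbar = sx / sw
            v = sxx.reshape(p, p) / sw - np.outer(xbar, xbar)
            ev_times_all.append(t)
            s_all.append(xi - xbar)
            v_sum += v
            d_total += 1
    if d_total < 2:
        raise DegenerateFitError("too few events for a PH test")
    s = np.array(s_all)
    t_arr = np.array(ev_times_all)
    if time_transform == "rank":
        g = _stats.rankdata(t_arr)
    elif time_transform == "identity":
        g = t_arr.copy()
    else:
        raise ValueError(f"unknown time_transform {time_transform!r}")
    g = g - g.mean()
    gg = float(g @ g)
    v_bar = v_sum / d_total
    v_bar_inv = np.linalg.pinv(v_bar)
    dvec = s.T @ g                                  # per-covariate score
    stat_j = (v_bar_inv @ dvec) ** 2 / (
        np.clip(np.diag(v_bar_inv), 1e-300, None) * gg
    )
    p_j = _stats.chi2.sf(stat_j, df=1)
    stat_g = float(dvec @ v_bar_inv @ dvec / gg)
    rows = [
        {"term": c, "statistic": float(stat_j[j]), "p": float(p_j[j])}
        for j, c in enumerate(xcols)
    ]
    rows.append({"term": "__global__", "statistic": stat_g,
                 "p": float(_stats.chi2.sf(stat_g, df=p))})
    return pd.DataFrame(rows)


def fit_cox(data: pd.DataFrame, spec: CoxSpec) -> CoxResult:
    """Fit one cause-specific Cox model with age as the timescale.

    ``data`` must carry ``entry_age, exit_age, event`` plus the exposure
    (``quartile`` / ``total_score`` / a group-intake column) and any
    covariates; prevalent cases for the outcome are assumed excluded.
    """
    frame, terms, cov_names, strata_cols, non_est = _assemble(data, spec)
    summ = _fit_summary(frame, strata_cols, spec.ties)
    keep = [t for t in terms if t in summ.index]
    hr = summ.loc[keep, "exp(coef)"].copy()
    ci_l = summ.loc[keep, "ci_low"].copy()
    ci_h = summ.loc[keep, "ci_high"].copy()
    pv = summ.loc[keep, "p"].copy()
    for lev in non_est:
        term = f"quartile_{lev}"
        if term in hr.index:
            hr[term] = np.nan
            ci_l[term] = np.nan
            ci_h[term] = np.nan
            pv[term] = np.nan
    if spec.exposure == "score_quartiles":
        rename = {f"quartile_{lev}": lev for lev in QUARTILE_LEVELS[1:]}
        hr, ci_l, ci_h, pv = (s.rename(index=rename) for s in (hr, ci_l, ci_h, pv))
    return CoxResult(
        outcome=spec.outcome,
        exposure=spec.exposure,
        hr=hr, ci_low=ci_l, ci_high=ci_h, p=pv,
        n=len(frame),
        n_events=int(frame["event"].sum()),
        strata_applied=tuple(spec.strata),
        non_estimable=tuple(non_est),
        exposure_terms=tuple(hr.index),
    )


def trend_test(data: pd.DataFrame, spec: CoxSpec) -> float:
    """Wald p for the continuous score in the otherwise identical model."""
    cont = replace(spec, exposure="continuous_score")
    frame, terms, _, strata_cols, _ = _assemble(data, cont)
    summ = _fit_summary(frame, strata_cols, spec.ties)
    return float(summ.loc[terms[0], "p"])


def check_ph_and_stratify(
    data: pd.DataFrame, spec: CoxSpec, alpha: float = 0.05
) -> tuple[pd.DataFrame, CoxSpec]:
    """Schoenfeld-residual PH tests; move failing covariates to strata.

    Returns the per-term diagnostics (test p-values) and a revised spec in
    which every covariate whose PH test rejects at ``alpha`` has been moved
    from the linear predictor to the strata list. The refit itself happens
    downstream with the revised spec; the decision is logged.
    """
    if not spec.covariates:
        return pd.DataFrame(columns=["term", "statistic", "p"]), spec
    frame, terms, cov_names, strata_cols, _ = _assemble(data, spec)
    cph = _fit_lifelines(frame, strata_cols)
    xcols = [c for c in frame.columns
             if c not in ("entry_age", "exit_age", "event")
             and c not in strata_cols]
    beta = cph.params_.reindex(xcols).to_numpy()
    diag = schoenfeld_ph_test(frame, xcols, beta, strata_cols,
                              time_transform="rank")
    failing_cov = set()
    for cov in spec.covariates:
        cov_terms = [t for t in diag["term"]
                     if t == cov or t.startswith(f"{cov}_")]
        if any(diag.loc[diag["term"] == t, "p"].iloc[0] < alpha
               for t in cov_terms):
            failing_cov.add(cov)
    if failing_cov:
        logger.info(
            "PH assumption rejected for %s; moving to strata",
            sorted(failing_cov),
        )
    revised = replace(
        spec,
        covariates=tuple(c for c in spec.covariates if c not in failing_cov),
        strata=tuple(spec.strata) + tuple(sorted(failing_cov)),
    )
    return diag, revised


def interaction_test(
    data: pd.DataFrame, spec: CoxSpec, modifier: str
) -> tuple[float, dict[str, CoxResult]]:
    """Multiplicative interaction of the continuous score with a modifier.

    The modifier is sex (coded 0/1) or a continuous variable such as the
    deprivation index. Returns the Wald p of the product term and
    subgroup fits: by sex level, or above/below the cohort median for a
    continuous modifier.
    """
    if modifier not in data.columns:
        raise ValueError(f"modifier {modifier!r} not in data")
    mod = data[modifier]
    if mod.nunique() < 2:
        raise DegenerateFitError(f"modifier {modifier!r} is constant")
    cont = replace(spec, exposure="continuous_score")
    frame, terms, _, strata_cols, _ = _assemble(data, cont)
    if mod.dtype == object or isinstance(mod.dtype, pd.CategoricalDtype):
        mod_num = (mod == sorted(mod.unique())[-1]).astype(float)
        groups = {str(v): data[mod == v] for v in mod.unique()}
    else:
        mod_num = mod.astype(float)
        med = float(mod_num.median())
        groups = {
            f"{modifier}<=median": data[mod_num <= med],
            f"{modifier}>median": data[mod_num > med],
        }
    x = frame[terms[0]]
    frame = frame.copy()
    mod_centered = (mod_num - mod_num.mean()).to_numpy()
    # add a main effect only if the modifier is not already a covariate
    has_main = modifier in spec.covariates or any(
        c == modifier or c.startswith(f"{modifier}_") for c in frame.columns
    )
    if not has_main:
        frame[f"{modifier}_main"] = mod_centered
    frame["score_x_modifier"] = x.to_numpy() * mod_centered
    summ = _fit_summary(frame, strata_cols, spec.ties)
    p_int = float(summ.loc["score_x_modifier", "p"])
    sub_results = {}
    for name, sub in groups.items():
        sub_spec = replace(
            cont,
            covariates=tuple(c for c in cont.covariates if c != modifier),
        )
        try:
            sub_results[name] = fit_cox(sub, sub_spec)
        except (DegenerateFitError, ValueError) as err:  # tiny subgroup
            logger.warning("subgroup %s not estimable: %s", name, err)
    return p_int, sub_results


def per_food_group_models(
    data: pd.DataFrame, taxonomy: Taxonomy, spec: CoxSpec | None = None
) -> dict[str, CoxResult]:
    """One Cox model per food group (grams/week per SD), same covariates."""
    spec = spec or CoxSpec()
    results = {}
    for gid in taxonomy.group_ids:
        if gid not in data.columns:
            raise ValueError(f"data missing group intake column {gid!r}")
        g_spec = replace(spec, exposure=gid)
        results[gid] = fit_cox(data, g_spec)
    return results


def bh_adjust(
    p_values: np.ndarray | pd.Series, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(adjusted p-values, rejection mask at level q)``. Adjusted
    values are the standard monotone step-up quantities
    min_k>=rank(p) (m * p_(k) / k) capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def exclude_prevalent(cohort: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Drop participants prevalent at baseline for one outcome.

    ``cohort`` is the long outcome table (one row per participant x
    outcome) with a ``prevalent_at_baseline`` flag. Incidence models must
    only see participants free of the condition at recruitment.
    """
    sub = cohort.loc[cohort["outcome"] == outcome]
    n_before = len(sub)
    kept = sub.loc[sub["prevalent_at_baseline"] != 1]
    n_excluded = n_before - len(kept)
    if len(kept) == 0:
        raise DegenerateFitError(
            f"all {n_before} participants prevalent for {outcome!r}; "
            "empty cohort"
        )
    logger.info(
        "outcome %s: excluded %d prevalent of %d", outcome, n_excluded, n_before
    )
    return kept


class CoxSurvivalModel(BaseEstimator):
    """Fit-shaped estimator wrapping the full per-outcome Cox workflow.

    ``fit(data)`` optionally runs PH diagnostics with stratification
    fallback, fits the quartile model, and attaches the trend test.
    Fitted attributes: ``result_`` (CoxResult), ``diagnostics_``,
    ``spec_`` (possibly revised by stratification).
    """

    def __init__(
        self,
        exposure: str = "score_quartiles",
        covariates: tuple[str, ...] = (),
        outcome: str = "cvd",
        check_ph: bool = True,
        ties: str = "efron",
    ):
        self.exposure = exposure
        self.covariates = covariates
        self.outcome = outcome
        self.check_ph = check_ph
        self.ties = ties

    def fit(self, X: pd.DataFrame, y=None) -> "CoxSurvivalModel":
        spec = CoxSpec(
            exposure=self.exposure,
            covariates=tuple(self.covariates),
            outcome=self.outcome,
            ties=self.ties,
        )
        if self.check_ph and spec.covariates:
            diag, spec = check_ph_and_stratify(X, spec)
        else:
            diag = pd.DataFrame(columns=["term", "p"])
        result = fit_cox(X, spec)
        try:
            result.trend_p = trend_test(X, spec)
        except DegenerateFitError:
            result.trend_p = None
        result.ph_diagnostics = diag
        self.diagnostics_ = diag
        self.spec_ = spec
        self.result_ = result
        return self
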