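"""Cox models on the age timescale, PH diagnostics, interactions, FDR."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

from hpds.survival import (
    CoxSpec,
    CoxSurvivalModel,
    DegenerateFitError,
    bh_adjust,
    check_ph_and_stratify,
    exclude_prevalent,
    fit_cox,
    interaction_test,
    per_food_group_models,
    schoenfeld_ph_test,
    trend_test,
)


def _exponential_two_group(n, true_hr, seed, censor=2.0):
    """Tie-free exponential survival with a binary exposure."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1.0 / (0.5 * true_hr**x))
    c = np.full(n, censor)
    return pd.DataFrame({
        "entry_age": 0.0,
        "exit_age": np.minimum(t, c),
        "event": (t <= c).astype(int),
        "total_score": x,
    })


@pytest.fixture(scope="module")
def scored_cohort(small_cohort, taxonomy):
    """Analysis table: covariates + score quartiles + cvd outcome."""
    from hpds.scoring import compute_hpds
    from hpds.taxonomy import aggregate_group_intake

    m = aggregate_group_intake(small_cohort.recalls, taxonomy)
    res = compute_hpds(m, taxonomy)
    rows = exclude_prevalent(small_cohort.outcomes, "cvd").set_index(
        "participant_id"
    )
    return (small_cohort.covariates
            .join(res.total).join(res.quartile)
            .join(rows[["entry_age", "exit_age", "event"]], how="inner"))


class TestFitCox:
    def test_recovers_known_exponential_hazard_ratio(self):
        true_hr = 0.8
        data = _exponential_two_group(10_000, true_hr, seed=4)
        res = fit_cox(data, CoxSpec(exposure="continuous_score"))
        # exposure is standardized internally: truth per SD of the 0/1 group
        sd = data["total_score"].std(ddof=1)
        est = np.log(res.hr.iloc[0])
        se = (np.log(res.ci_high.iloc[0]) - np.log(res.ci_low.iloc[0])) / 3.92
        assert abs(est - np.log(true_hr) * sd) < 3 * se

    def test_quartile_reference_recode_inverts_hazard_ratio(self, scored_cohort):
        res = fit_cox(scored_cohort, CoxSpec())
        swapped = scored_cohort.copy()
        swapped["quartile"] = swapped["quartile"].map(
            {"Q1": "Q4", "Q2": "Q3", "Q3": "Q2", "Q4": "Q1"}
        )
        res_swapped = fit_cox(swapped, CoxSpec())
        assert res_swapped.hr["Q4"] == pytest.approx(1 / res.hr["Q4"],
                                                     rel=1e-6)

    def test_agrees_with_independent_breslow_backend(self, scored_cohort):
        # continuous ages are tie-free, so Efron and Breslow coincide and
        # the lifelines fit can be checked against statsmodels PHReg
        spec = CoxSpec(exposure="continuous_score", covariates=("sex", "tdi"))
        efron = fit_cox(scored_cohort, spec)
        breslow = fit_cox(scored_cohort, CoxSpec(
            exposure="continuous_score", covariates=("sex", "tdi"),
            ties="breslow",
        ))
        assert np.log(breslow.hr.iloc[0]) == pytest.approx(
            np.log(efron.hr.iloc[0]), abs=1e-4
        )

    def test_zero_event_level_flagged_non_estimable(self, scored_cohort):
        data = scored_cohort.copy()
        data.loc[data["quartile"] == "Q3", "event"] = 0
        res = fit_cox(data, CoxSpec())
        assert "Q3" in res.non_estimable
        assert np.isnan(res.hr["Q3"])
        assert np.isfinite(res.hr["Q4"])

    def test_missing_time_columns_rejected(self):
        with pytest.raises(ValueError, match="entry_age"):
            fit_cox(pd.DataFrame({"total_score": [1.0, 2.0]}),
                    CoxSpec(exposure="continuous_score"))


class TestTrend:
    def test_strong_effect_detected(self):
        data = _exponential_two_group(5000, 0.74, seed=8)
        assert trend_test(data, CoxSpec()) < 1e-3

    def test_constant_exposure_rejected(self):
        data = _exponential_two_group(200, 1.0, seed=1)
        data["total_score"] = 5.0
        with pytest.raises(DegenerateFitError, match="constant"):
            trend_test(data, CoxSpec())


class TestSchoenfeld:
    def test_matches_lifelines_without_truncation(self):
        rng = np.random.default_rng(0)
        n = 1500
        x1 = rng.standard_normal(n)
        x2 = rng.binomial(1, 0.4, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.5 * x1 - 0.3 * x2))
        c = rng.exponential(2.0, n)
        df = pd.DataFrame({
            "entry_age": 0.0, "exit_age": np.minimum(t, c),
            "event": (t <= c).astype(int), "x1": x1, "x2": x2,
        })
        cph = CoxPHFitter().fit(df.drop(columns="entry_age"),
                                "exit_age", "event")
        ours = schoenfeld_ph_test(df, ["x1", "x2"], cph.params_.to_numpy())
        ref = proportional_hazard_test(
            cph, df.drop(columns="entry_age"), time_transform="rank"
        ).summary
        for term in ("x1", "x2"):
            mine = ours.loc[ours["term"] == term].iloc[0]
            assert mine["statistic"] == pytest.approx(
                ref.loc[term, "test_statistic"], rel=1e-6
            )
            assert mine["p"] == pytest.approx(ref.loc[term, "p"], rel=1e-6)

    def test_crossing_hazards_detected(self):
        rng = np.random.default_rng(3)
        n = 1500
        x = rng.binomial(1, 0.5, n).astype(float)
        t = np.where(x == 1, rng.weibull(0.7, n) * 1.2,
                     rng.weibull(2.0, n) * 1.2)
        c = rng.uniform(0.2, 2.5, n)
        df = pd.DataFrame({
            "entry_age": 0.0, "exit_age": np.minimum(t, c),
            "event": (t <= c).astype(int), "x": x,
        })
        cph = CoxPHFitter().fit(df.drop(columns="entry_age"),
                                "exit_age", "event")
        res = schoenfeld_ph_test(df, ["x"], cph.params_.to_numpy())
        assert res.loc[res["term"] == "x", "p"].iloc[0] < 1e-6


class TestStratification:
    def test_proportional_data_rarely_stratified(self):
        # false stratification is a 5%-level test error per covariate;
        # on proportional data it should stay rare across seeds
        stratified = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            n = 1200
            x1 = rng.standard_normal(n)
            x2 = rng.binomial(1, 0.5, n).astype(float)
            score = rng.standard_normal(n)
            t = rng.exponential(1.0 / (0.3 * np.exp(0.3 * x1 - 0.2 * x2)))
            c = np.full(n, 3.0)
            df = pd.DataFrame({
                "entry_age": 0.0, "exit_age": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "total_score": score, "x1": x1, "x2": x2,
            })
            spec = CoxSpec(exposure="continuous_score",
                           covariates=("x1", "x2"))
            diag, revised = check_ph_and_stratify(df, spec)
            assert set(diag["term"]) >= {"x1", "x2", "__global__"}
            stratified += bool(revised.strata)
        assert stratified <= 3

    def test_nonproportional_covariate_moved_to_strata(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        score = rng.standard_normal(n)
        t = np.where(x == 1, rng.weibull(0.6, n), rng.weibull(2.2, n))
        c = rng.uniform(0.2, 2.0, n)
        df = pd.DataFrame({
            "entry_age": 0.0, "exit_age": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "total_score": score, "bad_covariate": x,
        })
        spec = CoxSpec(exposure="continuous_score",
                       covariates=("bad_covariate",))
        _, revised = check_ph_and_stratify(df, spec)
        assert revised.strata == ("bad_covariate",)
        assert "bad_covariate" not in revised.covariates
        # and the revised model still fits
        res = fit_cox(df, revised)
        assert np.isfinite(res.hr.iloc[0])

    def test_empty_covariate_list_is_noop(self, scored_cohort):
        spec = CoxSpec(covariates=())
        diag, revised = check_ph_and_stratify(scored_cohort, spec)
        assert diag.empty
        assert revised == spec


class TestInteraction:
    @staticmethod
    def _sex_modified(n, beta_female, beta_male, seed):
        rng = np.random.default_rng(seed)
        h = rng.standard_normal(n)
        male = rng.binomial(1, 0.5, n)
        beta = np.where(male == 1, beta_male, beta_female)
        t = rng.exponential(1.0 / (0.2 * np.exp(beta * h)))
        c = np.full(n, 5.0)
        return pd.DataFrame({
            "entry_age": 0.0, "exit_age": np.minimum(t, c),
            "event": (t <= c).astype(int), "total_score": h,
            "sex": np.where(male == 1, "male", "female"),
        })

    def test_sex_specific_effect_detected(self):
        data = self._sex_modified(6000, beta_female=-0.3, beta_male=0.0,
                                  seed=12)
        p, subgroups = interaction_test(data, CoxSpec(covariates=("sex",)),
                                        "sex")
        assert p < 0.01
        assert set(subgroups) == {"female", "male"}
        assert subgroups["female"].hr.iloc[0] < subgroups["male"].hr.iloc[0]

    def test_equal_effects_rarely_flagged(self):
        rejections = 0
        for seed in range(10):
            data = self._sex_modified(1500, -0.3, -0.3, seed=100 + seed)
            p, _ = interaction_test(data, CoxSpec(), "sex")
            rejections += p < 0.05
        assert rejections <= 2

    def test_continuous_modifier_splits_at_median(self, scored_cohort):
        p, subgroups = interaction_test(scored_cohort, CoxSpec(), "tdi")
        assert 0 <= p <= 1
        assert set(subgroups) == {"tdi<=median", "tdi>median"}

    def test_constant_modifier_rejected(self, scored_cohort):
        data = scored_cohort.copy()
        data["sex"] = "female"
        with pytest.raises(DegenerateFitError, match="constant"):
            interaction_test(data, CoxSpec(), "sex")


class TestPerFoodGroup:
    def test_direction_aligned_effects(self, taxonomy):
        from hpds.simulate import OutcomeParams, SimConfig, simulate_cohort
        from hpds.taxonomy import aggregate_group_intake

        cfg = SimConfig(n=3000, seed=5,
                        outcomes={"cvd": OutcomeParams(log_hr_per_sd=-0.3)})
        sim = simulate_cohort(cfg, taxonomy)
        m = aggregate_group_intake(sim.recalls, taxonomy)
        rows = exclude_prevalent(sim.outcomes, "cvd").set_index(
            "participant_id"
        )
        data = sim.covariates.join(
            rows[["entry_age", "exit_age", "event"]], how="inner"
        ).join(m)
        results = per_food_group_models(data, taxonomy, CoxSpec())
        assert len(results) == 22
        agree = sum(
            np.sign(np.log(r.hr.iloc[0])) == -taxonomy[g].direction
            for g, r in results.items()
        )
        assert agree >= 16

    def test_identical_columns_identical_results(self, taxonomy, scored_cohort):
        data = scored_cohort.copy()
        rng = np.random.default_rng(2)
        shared = rng.lognormal(3, 1, len(data))
        for g in taxonomy.group_ids:
            data[g] = shared
        results = per_food_group_models(data, taxonomy, CoxSpec())
        hrs = {g: r.hr.iloc[0] for g, r in results.items()}
        assert len(set(np.round(list(hrs.values()), 12))) == 1


class TestBHAdjust:
    def test_single_p_identity(self):
        adj, rej = bh_adjust(np.array([0.03]))
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_step_up(self):
        adj, _ = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        adj, _ = bh_adjust(np.array([0.2, 0.2, 0.2]))
        assert adj == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust(np.array([0.5, 1.5]))


class TestExcludePrevalent:
    @staticmethod
    def _outcomes(n, n_prev, outcome="cvd"):
        return pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "outcome": outcome,
            "entry_age": 50.0,
            "exit_age": 60.0,
            "event": 0,
            "prevalent_at_baseline": [1] * n_prev + [0] * (n - n_prev),
        })

    def test_removes_prevalent_rows(self):
        kept = exclude_prevalent(self._outcomes(10, 2), "cvd")
        assert len(kept) == 8
        assert (kept["prevalent_at_baseline"] == 0).all()

    def test_no_prevalent_is_identity(self):
        out = self._outcomes(10, 0)
        pd.testing.assert_frame_equal(exclude_prevalent(out, "cvd"), out)

    def test_all_prevalent_rejected(self):
        with pytest.raises(DegenerateFitError, match="empty"):
            exclude_prevalent(self._outcomes(5, 5), "cvd")


class TestEstimatorWrapper:
    def test_fit_populates_result_and_spec(self, scored_cohort):
        model = CoxSurvivalModel(covariates=("sex", "tdi")).fit(scored_cohort)
        assert model.result_.n_events > 0
        assert model.result_.trend_p is not None
        assert set(model.result_.hr.index) == {"Q2", "Q3", "Q4"}
        assert model.get_params()["outcome"] == "cvd"
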