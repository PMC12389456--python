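"""Synthetic cohort generator for the diet-score survival pipeline.

Real cohorts of this kind (24 h recall dietary measurement linked to
clinical follow-up) are access-restricted, so every downstream stage is
exercised on simulated data with the statistical structure the analysis
assumes:

* **Intakes.** Each participant carries a standard-normal latent
  "healthy eating" factor ``h``. Group intake (grams/week) is
  zero-inflated log-normal: a consumer indicator with probability
  ``1 - zero_prob`` (logistic in ``h``, sign-aligned with the group's
  scoring direction) times ``LogNormal(loc + loading * h * direction,
  scale)``. Heart-protective groups therefore rise, and discouraged
  groups fall, with ``h`` — the gradient the score is built to detect.
* **Repeat recalls.** Occasion-specific log-intakes add
  ``Normal(0, recall_noise_sd)`` intra-individual noise to the
  person-level log-mean; occasion 1 is "baseline".
* **Covariates.** A covariate mix resembling a middle-aged UK cohort
  (43% male, mostly white ethnicity, Townsend deprivation, income and
  education bands, smoking, activity, sitting, sleep, alcohol).
* **Outcomes.** Event ages are drawn from Weibull proportional-hazards
  models on the age scale with linear predictor
  ``log_hr_per_sd * h + covariate effects``, left-truncated at the entry
  age (recruitment 40-69 y) and administratively censored after
  ``admin_censor_years`` (default 12.3 y of follow-up). Other-cause exits
  are treated as independent censoring (cause-specific hazards).

All randomness flows from a single seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import Taxonomy, default_taxonomy

__all__ = [
    "SimConfig",
    "OutcomeParams",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_survival",
    "simulate_repeat_recalls",
    "DEFAULT_GROUP_PARAMS",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the field."""


# (median positive intake g/week, baseline zero-intake probability).
# Medians follow the magnitude ordering seen in UK 24 h recall data:
# staples (tea/coffee, dairy, vegetables) are hundreds of g/week while
# nuts, sweeteners and coated fish are rare and heavily zero-inflated.
DEFAULT_GROUP_PARAMS: dict[str, tuple[float, float]] = {
    "wholegrains": (130.0, 0.25),
    "fruits": (160.0, 0.20),
    "non_starchy_vegetables": (200.0, 0.15),
    "starchy_vegetables": (40.0, 0.85),
    "nuts_and_seeds": (35.0, 0.80),
    "legumes_and_beans_other_vegetarian_protein_alternatives": (80.0, 0.60),
    "uncoated_fish_and_seafood": (120.0, 0.65),
    "eggs": (110.0, 0.60),
    "reduced_fat_milk_and_dairy_products": (180.0, 0.75),
    "tea_coffee_and_other_low_calorie_drinks": (560.0, 0.05),
    "homemade_soup": (180.0, 0.85),
    "refined_grains_and_cereals": (90.0, 0.30),
    "potatoes": (70.0, 0.25),
    "meat_poultry_and_processed_meat": (100.0, 0.20),
    "coated_fish_and_seafood": (110.0, 0.95),
    "full_fat_milk_and_dairy_products": (300.0, 0.10),
    "processed_soup": (150.0, 0.85),
    "sugar_sweets_and_desserts_cookies_and_pastries": (60.0, 0.25),
    "savory_snacks": (25.0, 0.92),
    "sugary_drinks": (90.0, 0.80),
    "artificial_sweetener": (4.0, 0.75),
    "unhealthy_fat": (10.0, 0.55),
}


@dataclass(frozen=True)
class OutcomeParams:
    """Weibull baseline hazard and score effect for one outcome.

    shape/scale parameterize the cumulative hazard H(t) = (t/scale)^shape
    on the age scale (shape > 1: risk rising with age). ``log_hr_per_sd``
    is the log hazard ratio per SD of the latent healthy-eating factor
    (negative = protective). ``prevalent_prob`` is the fraction already
    diagnosed at recruitment, to exercise prevalent-case exclusion.
    """

    shape: float = 5.0
    scale: float = 94.0
    log_hr_per_sd: float = -0.1
    prevalent_prob: float = 0.0


# Baseline scales chosen so a 40-69 y cohort followed 12.3 y under the
# default covariate mix sees marginal event fractions of ~10% (incidence)
# and ~0.6% (mortality).
DEFAULT_OUTCOMES: dict[str, OutcomeParams] = {
    "cvd": OutcomeParams(shape=5.0, scale=102.0, log_hr_per_sd=-0.1,
                         prevalent_prob=0.02),
    "cvd_death": OutcomeParams(shape=5.0, scale=178.0, log_hr_per_sd=-0.15),
}

DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "sex_male": 0.30,
    "smoking_current": 0.40,
    "tdi": 0.03,
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort; every default is a study condition."""

    n: int = 2000
    seed: int = 0
    latent_loading: float = 0.5
    zero_inflation_slope: float = 0.8
    log_scale_sd: float = 0.8
    group_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    n_recalls: int = 1
    recall_noise_sd: float = 0.0
    multi_item: bool = False
    entry_age_range: tuple[float, float] = (40.0, 69.0)
    admin_censor_years: float = 12.3
    outcomes: dict[str, OutcomeParams] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES)
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ConfigError(f"n: cohort size must be >= 4, got {self.n}")
        if self.n_recalls < 1:
            raise ConfigError(f"n_recalls: must be >= 1, got {self.n_recalls}")
        if self.recall_noise_sd < 0:
            raise ConfigError("recall_noise_sd: must be >= 0")
        if not self.admin_censor_years > 0:
            raise ConfigError("admin_censor_years: must be > 0")
        if not self.log_scale_sd > 0:
            raise ConfigError("log_scale_sd: must be > 0")
        lo, hi = self.entry_age_range
        if not (0 < lo < hi):
            raise ConfigError(f"entry_age_range: invalid range ({lo}, {hi})")
        for gid, (med, zp) in self.group_params.items():
            if not med > 0:
                raise ConfigError(f"group_params[{gid!r}]: median must be > 0")
            if not 0 <= zp <= 1:
                raise ConfigError(
                    f"group_params[{gid!r}]: zero probability must be in [0, 1]"
                )
        for name, op in self.outcomes.items():
            if not (op.shape > 0 and op.scale > 0):
                raise ConfigError(
                    f"outcomes[{name!r}]: Weibull shape/scale must be > 0"
                )
            if not 0 <= op.prevalent_prob <= 1:
                raise ConfigError(
                    f"outcomes[{name!r}]: prevalent_prob must be in [0, 1]"
                )


@dataclass
class SimulatedCohort:
    """Bundle of simulator outputs."""

    recalls: pd.DataFrame      # participant_id, recall_index, item_id, amount_g
    covariates: pd.DataFrame   # indexed by participant_id
    outcomes: pd.DataFrame     # long: one row per participant x outcome
    truth: pd.DataFrame        # participant_id, latent h


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _person_log_means(
    config: SimConfig, taxonomy: Taxonomy, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-person log weekly intake means and zero-intake logits (n x 22).

    The probability of reporting zero intake of a group is logistic in
    the latent factor, sign-aligned with the group's direction: healthy
    eaters rarely skip protective groups and often skip discouraged ones.
    """
    gids = taxonomy.group_ids
    dirs = np.array([taxonomy[g].direction for g in gids], dtype=float)
    med = np.array([config.group_params[g][0] for g in gids])
    zp0 = np.array([config.group_params[g][1] for g in gids])
    # clip base zero-probabilities away from 0/1 so the logistic shift is defined
    logit0 = np.log(np.clip(zp0, 1e-6, 1 - 1e-6) /
                    (1 - np.clip(zp0, 1e-6, 1 - 1e-6)))
    shift = config.zero_inflation_slope * h[:, None] * dirs[None, :]
    zero_logit = logit0[None, :] - shift
    log_mu = (np.log(med)[None, :]
              + config.latent_loading * h[:, None] * dirs[None, :])
    return log_mu, zero_logit


def _emit_recalls(
    config: SimConfig,
    taxonomy: Taxonomy,
    participant_ids: np.ndarray,
    log_mu: np.ndarray,
    zero_logit: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Item-level recall rows for n_recalls occasions.

    Weekly group mass is divided by 7 to a 24 h amount. The zero-intake
    indicator uses a person-level uniform compared against an
    occasion-level logistic propensity: at zero recall noise every
    occasion reproduces the same consumption pattern, while increasing
    noise perturbs both the amounts (log-additive) and the day's
    consumption pattern — a single 24 h window both mismeasures amounts
    and misses episodically eaten foods. By default one representative
    item per group carries the whole group mass; in multi-item mode the
    mass is split across the group's items with symmetric Dirichlet
    weights (fixed per participant).
    """
    n, g = log_mu.shape
    gids = taxonomy.group_ids
    # person-level between-subject variation on the log scale
    person_dev = rng.normal(0.0, config.log_scale_sd, size=(n, g))
    # shared latent uniform: ties the consumption pattern across occasions
    u_consume = rng.random((n, g))
    frames = []
    splits: dict[str, np.ndarray] = {}
    if config.multi_item:
        for gid in gids:
            k = len(taxonomy[gid].items)
            splits[gid] = rng.dirichlet(np.ones(k), size=n)
    noisy = config.recall_noise_sd > 0 and config.n_recalls > 1
    for occ in range(1, config.n_recalls + 1):
        occ_noise = (
            rng.normal(0.0, config.recall_noise_sd, size=(n, g))
            if noisy else np.zeros((n, g))
        )
        zero_noise = (
            rng.normal(0.0, config.recall_noise_sd, size=(n, g))
            if noisy else np.zeros((n, g))
        )
        consumer = u_consume >= _sigmoid(zero_logit + zero_noise)
        weekly = np.where(
            consumer, np.exp(log_mu + person_dev + occ_noise), 0.0
        )
        daily = weekly / 7.0
        for j, gid in enumerate(gids):
            col = daily[:, j]
            nz = col > 0
            if not nz.any():
                continue
            if config.multi_item:
                w = splits[gid][nz]
                items = taxonomy[gid].item_ids
                for i_idx, item in enumerate(items):
                    amt = col[nz] * w[:, i_idx]
                    frames.append(pd.DataFrame({
                        "participant_id": participant_ids[nz],
                        "recall_index": occ,
                        "item_id": item,
                        "amount_g": amt,
                    }))
            else:
                frames.append(pd.DataFrame({
                    "participant_id": participant_ids[nz],
                    "recall_index": occ,
                    "item_id": taxonomy[gid].item_ids[0],
                    "amount_g": col[nz],
                }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["participant_id", "recall_index", "item_id"], kind="stable"
    ).reset_index(drop=True)


def _simulate_covariates(
    n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Covariate mix resembling a middle-aged volunteer cohort."""
    income_levels = ["<18k", "18-31k", "31-52k", "52-100k", ">100k"]
    activity_levels = ["low", "moderate", "high"]
    smoking_levels = ["never", "former", "current"]
    alcohol_zero = rng.random(n) < 0.20
    alcohol = np.where(
        alcohol_zero, 0.0, rng.lognormal(mean=2.5, sigma=0.9, size=n)
    )
    return pd.DataFrame({
        "sex": rng.choice(["male", "female"], size=n, p=[0.433, 0.567]),
        "ethnicity": rng.choice(["white", "other"], size=n, p=[0.955, 0.045]),
        "tdi": rng.normal(-1.6, 2.9, size=n),
        "income": rng.choice(
            income_levels, size=n, p=[0.14, 0.23, 0.28, 0.25, 0.10]
        ),
        "education_degree": rng.random(n) < 0.43,
        "supplement_use": rng.random(n) < 0.52,
        "cancer_history": rng.random(n) < 0.08,
        "t2dm_history": rng.random(n) < 0.05,
        "physical_activity": rng.choice(
            activity_levels, size=n, p=[0.12, 0.45, 0.43]
        ),
        "sitting_hours": np.clip(rng.normal(4.7, 2.3, size=n), 0.0, None),
        "sleep_score": np.clip(np.round(rng.normal(3.7, 1.0, size=n)), 0, 5),
        "smoking": rng.choice(smoking_levels, size=n, p=[0.575, 0.345, 0.08]),
        "alcohol_g_day": alcohol,
    })


def _covariate_linear_predictor(
    covariates: pd.DataFrame, effects: dict[str, float]
) -> np.ndarray:
    """Declared covariate contributions to the log hazard."""
    lp = np.zeros(len(covariates))
    for key, beta in effects.items():
        if key == "sex_male":
            lp += beta * (covariates["sex"] == "male").to_numpy(float)
        elif key == "smoking_current":
            lp += beta * (covariates["smoking"] == "current").to_numpy(float)
        elif key in covariates.columns:
            x = covariates[key].to_numpy(float)
            lp += beta * (x - x.mean())
        else:
            raise ConfigError(f"covariate_effects[{key!r}]: unknown covariate")
    return lp


def _draw_event_ages(
    entry_age: np.ndarray,
    lp: np.ndarray,
    params: OutcomeParams,
    admin_censor_years: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Left-truncated Weibull-PH event ages via inverse cumulative hazard.

    Conditional on being event-free at the entry age a, the event age T
    solves H(T) = H(a) + E / exp(lp) with E ~ Exp(1), H(t) = (t/scale)^shape.
    Events are administratively censored at a + admin_censor_years.
    """
    e = rng.exponential(1.0, size=len(entry_age))
    h_entry = (entry_age / params.scale) ** params.shape
    t_event = params.scale * (h_entry + e / np.exp(lp)) ** (1.0 / params.shape)
    censor_age = entry_age + admin_censor_years
    event = t_event <= censor_age
    exit_age = np.where(event, t_event, censor_age)
    # exit strictly after entry (guards the degenerate T == a corner)
    exit_age = np.maximum(exit_age, entry_age + 1e-9)
    return exit_age, event.astype(int)


def simulate_cohort(
    config: SimConfig, taxonomy: Taxonomy | None = None
) -> SimulatedCohort:
    """Generate a full synthetic cohort (recalls, covariates, outcomes, truth).

    Reproducible: identical config (including seed) gives identical output.
    """
    taxonomy = taxonomy if taxonomy is not None else default_taxonomy()
    missing = [g for g in taxonomy.group_ids if g not in config.group_params]
    if missing:
        raise ConfigError(f"group_params: missing groups {missing}")
    rng = np.random.default_rng(config.seed)
    n = config.n
    pids = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    h = rng.standard_normal(n)

    log_mu, zero_logit = _person_log_means(config, taxonomy, h)
    recalls = _emit_recalls(config, taxonomy, pids, log_mu, zero_logit, rng)

    covariates = _simulate_covariates(n, rng)
    covariates.insert(0, "participant_id", pids)
    covariates = covariates.set_index("participant_id")

    cov_lp = _covariate_linear_predictor(covariates, config.covariate_effects)
    entry = rng.uniform(*config.entry_age_range, size=n)
    rows = []
    for name, params in config.outcomes.items():
        lp = params.log_hr_per_sd * h + cov_lp
        exit_age, event = _draw_event_ages(
            entry, lp, params, config.admin_censor_years, rng
        )
        prevalent = (rng.random(n) < params.prevalent_prob).astype(int)
        rows.append(pd.DataFrame({
            "participant_id": pids,
            "outcome": name,
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event,
            "prevalent_at_baseline": prevalent,
        }))
    outcomes = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({"participant_id": pids, "h": h}).set_index(
        "participant_id"
    )
    return SimulatedCohort(
        recalls=recalls, covariates=covariates, outcomes=outcomes, truth=truth
    )


def simulate_survival(config: SimConfig) -> SimulatedCohort:
    """Covariates, outcomes and truth only — no item-level diet data.

    For parameter-recovery and calibration experiments the diet exposure
    enters the hazard through the latent factor alone, so the item-level
    recall tables are dead weight; this path skips them (its RNG stream
    therefore differs from :func:`simulate_cohort` at the same seed).
    ``recalls`` in the returned bundle is an empty table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    pids = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    h = rng.standard_normal(n)
    covariates = _simulate_covariates(n, rng)
    covariates.insert(0, "participant_id", pids)
    covariates = covariates.set_index("participant_id")
    cov_lp = _covariate_linear_predictor(covariates, config.covariate_effects)
    entry = rng.uniform(*config.entry_age_range, size=n)
    rows = []
    for name, params in config.outcomes.items():
        lp = params.log_hr_per_sd * h + cov_lp
        exit_age, event = _draw_event_ages(
            entry, lp, params, config.admin_censor_years, rng
        )
        prevalent = (rng.random(n) < params.prevalent_prob).astype(int)
        rows.append(pd.DataFrame({
            "participant_id": pids,
            "outcome": name,
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event,
            "prevalent_at_baseline": prevalent,
        }))
    outcomes = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({"participant_id": pids, "h": h}).set_index(
        "participant_id"
    )
    recalls = pd.DataFrame(
        columns=["participant_id", "recall_index", "item_id", "amount_g"]
    )
    return SimulatedCohort(
        recalls=recalls, covariates=covariates, outcomes=outcomes, truth=truth
    )


def simulate_repeat_recalls(
    config: SimConfig, taxonomy: Taxonomy | None = None
) -> pd.DataFrame:
    """Recall table with ``n_recalls`` occasions per participant.

    Occasion 1 is the baseline measurement; later occasions add
    independent Normal(0, recall_noise_sd) intra-individual noise on the
    log scale. Requires ``n_recalls >= 2``.
    """
    if config.n_recalls < 2:
        raise ConfigError("n_recalls: repeat recalls require n_recalls >= 2")
    return simulate_cohort(config, taxonomy).recalls
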