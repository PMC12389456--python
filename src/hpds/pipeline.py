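"""End-to-end pipeline: simulate -> score -> analyze -> report.

Each stage reads and writes plain CSV so any stage can be swapped for
real data with the same schemas. A run writes a manifest listing every
artifact with its SHA-256 content hash; identical config and seed give
identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .reporting import forest_table
from .scoring import compute_hpds
from .simulate import SimConfig, simulate_cohort
from .survival import (
    CoxSpec,
    bh_adjust,
    check_ph_and_stratify,
    exclude_prevalent,
    fit_cox,
    trend_test,
)
from .taxonomy import Taxonomy, aggregate_group_intake, default_taxonomy, load_taxonomy

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = (
    "sex", "ethnicity", "tdi", "income", "education_degree",
    "supplement_use", "cancer_history", "t2dm_history",
    "physical_activity", "sitting_hours", "sleep_score", "smoking",
    "alcohol_g_day",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    n: int = 2000
    taxonomy_path: Path | None = None   # packaged taxonomy when None
    recalls_path: Path | None = None    # simulate when None
    covariates_path: Path | None = None
    outcomes_path: Path | None = None
    recall_policy: str = "earliest"
    scoring_convention: str = "centered"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    check_ph: bool = True
    fdr_family: str = "global"          # or "per-outcome"
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("taxonomy_path", "recalls_path", "covariates_path",
                     "outcomes_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the output manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    taxonomy = (load_taxonomy(config.taxonomy_path)
                if config.taxonomy_path else default_taxonomy())
    artifacts: list[Path] = []

    # --- stage 1: inputs (simulated unless provided) -----------------------
    if config.recalls_path is None:
        sim = simulate_cohort(SimConfig(n=config.n, seed=config.seed), taxonomy)
        recalls, covariates, outcomes = sim.recalls, sim.covariates, sim.outcomes
        _write(sim.truth, out / "truth.csv", index=True)
        artifacts.append(out / "truth.csv")
    else:
        recalls = pd.read_csv(config.recalls_path)
        covariates = pd.read_csv(config.covariates_path,
                                 index_col="participant_id")
        outcomes = pd.read_csv(config.outcomes_path)
    _write(recalls, out / "recalls.csv", index=False)
    _write(covariates, out / "covariates.csv", index=True)
    _write(outcomes, out / "outcomes.csv", index=False)
    artifacts += [out / "recalls.csv", out / "covariates.csv",
                  out / "outcomes.csv"]
    logger.info("inputs: %d recall rows, %d participants",
                len(recalls), len(covariates))

    # --- stage 2: aggregate + score ---------------------------------------
    matrix = aggregate_group_intake(recalls, taxonomy,
                                    recall_policy=config.recall_policy)
    result = compute_hpds(matrix, taxonomy,
                          convention=config.scoring_convention)
    scores = result.to_frame()
    _write(scores, out / "scores.csv", index=True)
    artifacts.append(out / "scores.csv")
    logger.info("scores: n=%d mean=%.2f sd=%.2f", result.summary["n"],
                result.summary["mean"], result.summary["sd"])

    # --- stage 3: per-outcome Cox models -----------------------------------
    analysis = covariates.join(result.total).join(result.quartile)
    results = []
    for outcome in outcomes["outcome"].unique():
        rows = exclude_prevalent(outcomes, outcome).set_index("participant_id")
        data = analysis.join(
            rows[["entry_age", "exit_age", "event"]], how="inner"
        )
        spec = CoxSpec(exposure="score_quartiles",
                       covariates=config.covariates, outcome=outcome)
        if config.check_ph:
            _, spec = check_ph_and_stratify(data, spec)
        res = fit_cox(data, spec)
        res.trend_p = trend_test(data, spec)
        results.append(res)
        logger.info("outcome %s: n=%d events=%d strata=%s",
                    outcome, res.n, res.n_events, list(spec.strata))

    # --- stage 4: FDR adjustment + report ----------------------------------
    table = pd.concat([r.to_rows() for r in results], ignore_index=True)
    estimable = table["p"].notna()
    if config.fdr_family == "global":
        adj = pd.Series(float("nan"), index=table.index)
        if estimable.any():
            adj.loc[estimable], _ = bh_adjust(table.loc[estimable, "p"],
                                              q=config.fdr_q)
        table["p_adjusted"] = adj
        table["fdr_family"] = "global"
    else:
        for outcome, idx in table.groupby("outcome").groups.items():
            mask = table.index.isin(idx) & estimable
            if mask.any():
                table.loc[mask, "p_adjusted"], _ = bh_adjust(
                    table.loc[mask, "p"], q=config.fdr_q
                )
        table["fdr_family"] = "per-outcome"
    _write(table, out / "results.csv", index=False)
    forest = forest_table(results)
    _write(forest, out / "forest.csv", index=False)
    artifacts += [out / "results.csv", out / "forest.csv"]

    manifest = {
        "seed": config.seed,
        "n": int(len(covariates)),
        "scoring_convention": config.scoring_convention,
        "recall_policy": config.recall_policy,
        "fdr_family": config.fdr_family,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
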