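"""End-to-end orchestration of the HAI economic-burden study.

Runs the full analysis on synthetic or user-supplied episode/infection
tables: CACI scoring, infection profiling, the category-level comparison
(top-k DIP categories by HAI concentration), the infection-classification
strata, the matched case-control comparison for each matching design, and
the robust Gaussian GLM of DIP payment differentials.  All report amounts
are converted to USD at the configured rate (7.12 CNY/USD by default);
internal arithmetic stays in CNY at full precision, and rounding happens
only at the reporting boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .comorbidity import score_episodes
from .errors import ConfigurationError, DomainError, RankDeficiencyError
from .glm_analysis import GLMFit, build_design, fit_glm, glm_table
from .inference import GroupComparison, compare_groups, kruskal_wallis, mann_whitney
from .matching import MatchCriteria, MatchedCohort, exact_match, propensity_match, risk_set_match
from .settlement import (
    DEFAULT_USD_RATE,
    add_differential_column,
    build_profiles,
    convert_currency,
    incidence_rate,
    incidence_rate_exact,
    round_half_up,
)
from .synthetic_cohort import (
    CohortConfig,
    default_config,
    generate_cohort,
    read_episodes,
    read_infections,
    write_tables,
)

__all__ = [
    "AnalysisConfig",
    "INDICATORS",
    "prepare_tables",
    "indicator_values",
    "run_category_report",
    "run_classification_report",
    "run_matched_analysis",
    "run_full",
]

log = logging.getLogger(__name__)

#: settlement indicators compared between groups (name -> column, is_currency)
INDICATORS: Mapping[str, tuple[str, bool]] = {
    "hospitalization_cost": ("hospitalization_cost_cny", True),
    "diagnostic_cost": ("diagnostic_cost_cny", True),
    "length_of_stay": ("length_of_stay", False),
    "dip_differential": ("dip_differential_cny", True),
}

MODEL_RUNNERS = ("exact", "psm", "risk_set")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    simulate: CohortConfig | None = None
    episodes_path: str | None = None
    infections_path: str | None = None
    models: tuple[str, ...] = ("exact", "psm", "risk_set")
    caliper: float = 0.2
    alpha: float = 0.05
    currency_rate: float = DEFAULT_USD_RATE
    output_dir: str = "haiburden_out"
    seed: int = 0
    rounding: int = 2
    top_k: int = 5
    criteria: MatchCriteria = field(default_factory=MatchCriteria)

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.currency_rate <= 0:
            raise ConfigurationError(f"currency_rate must be > 0, got {self.currency_rate}")
        if self.caliper <= 0:
            raise ConfigurationError(f"caliper must be > 0, got {self.caliper}")
        unknown = [m for m in self.models if m not in MODEL_RUNNERS]
        if unknown:
            raise ConfigurationError(f"models contains unknown entries {unknown}")
        if self.simulate is None and (self.episodes_path is None or self.infections_path is None):
            raise ConfigurationError(
                "either a simulate block or episodes_path/infections_path must be given"
            )


def prepare_tables(
    episodes: pd.DataFrame, infections: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score CACI, add the differential column and build infection profiles."""
    scored = add_differential_column(score_episodes(episodes))
    profiles = build_profiles(scored, infections)
    return scored, profiles


def indicator_values(df: pd.DataFrame, indicator: str, rate: float | None) -> np.ndarray:
    column, is_currency = INDICATORS[indicator]
    vals = df[column].to_numpy(float)
    if is_currency and rate is not None:
        vals = vals / rate
    return vals


def _comparison_row(comp: GroupComparison, ndigits: int) -> dict:
    fmt = lambda s: (
        f"{round_half_up(s.median, ndigits)}"
        f"({round_half_up(s.p25, ndigits)}, {round_half_up(s.p75, ndigits)})"
    )
    return {
        "indicator": comp.indicator,
        "case_summary": fmt(comp.case_summary),
        "control_summary": fmt(comp.control_summary),
        "z": round_half_up(comp.z_statistic, 3),
        "md": round_half_up(comp.md, ndigits),
        "ci_low": round_half_up(comp.ci_low, ndigits),
        "ci_high": round_half_up(comp.ci_high, ndigits),
        "p_value": comp.p_value,
    }


def run_category_report(
    episodes: pd.DataFrame,
    infections: pd.DataFrame,
    top_k: int = 5,
    rate: float | None = DEFAULT_USD_RATE,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Top-k DIP categories by HAI case count, with infected-vs-uninfected contrasts.

    Reports per-category HAI incidence, the category's share of all HAI cases
    ("infection percentage"), and the four settlement-indicator comparisons
    between infected and uninfected episodes of the category.
    """
    if infections.empty:
        raise DomainError("category report requires at least one infection event")
    df = episodes if "dip_differential_cny" in episodes.columns else add_differential_column(episodes)
    infected_ids = set(infections["episode_id"])
    df = df.assign(_infected=df["episode_id"].isin(infected_ids))
    total_cases = int(df["_infected"].sum())
    counts = (
        df[df["_infected"]].groupby("dip_category").size().sort_values(ascending=False)
    )
    # rank by case count descending, category id ascending on ties
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    rows = []
    for cat, n_cases in ranked:
        sub = df[df["dip_category"] == cat]
        inf_sub = sub[sub["_infected"]]
        non_sub = sub[~sub["_infected"]]
        base = {
            "dip_category": cat,
            "total_cases": int(len(sub)),
            "n_hai_cases": int(n_cases),
            "incidence_pct": incidence_rate(int(n_cases), int(len(sub))),
            "infection_pct": incidence_rate(int(n_cases), total_cases),
        }
        for indicator in INDICATORS:
            if non_sub.empty:
                rows.append({**base, "indicator": indicator})
                continue
            comp = compare_groups(
                indicator_values(inf_sub, indicator, rate),
                indicator_values(non_sub, indicator, rate),
                indicator,
            )
            rows.append({**base, **_comparison_row(comp, ndigits)})
    return pd.DataFrame(rows)


def run_classification_report(
    episodes: pd.DataFrame,
    profiles: pd.DataFrame,
    rate: float | None = DEFAULT_USD_RATE,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Settlement indicators across HAI classifications, infected episodes only.

    Stratifications and their tests: infection frequency (Kruskal-Wallis),
    catheter association (Mann-Whitney, two groups), number of distinct MDRO
    types (Kruskal-Wallis), and SSI wound class including the non-SSI group
    (Kruskal-Wallis).  Strata with no members are dropped with a log notice.
    """
    df = episodes if "dip_differential_cny" in episodes.columns else add_differential_column(episodes)
    merged = df.merge(profiles, on="episode_id", how="inner")
    infected = merged[merged["frequency"] != "0"]
    if infected.empty:
        raise DomainError("classification report requires at least one infected episode")

    stratifications: dict[str, tuple[str, Sequence[str]]] = {
        "frequency": ("frequency", ("1", "2", "3+")),
        "catheter_associated": ("catheter_associated", (False, True)),
        "mdro_type_count": ("mdro_type_count", ("0", "1", "2", "3+")),
        "ssi_wound_class": ("ssi_wound_class", ("non-SSI", "0", "I", "II", "III")),
    }
    rows = []
    for label, (col, levels) in stratifications.items():
        groups = {lv: infected[infected[col] == lv] for lv in levels}
        groups = {lv: g for lv, g in groups.items() if len(g) > 0}
        if len(groups) < 2:
            log.info("stratification %s skipped: fewer than two non-empty groups", label)
            continue
        for indicator in INDICATORS:
            samples = [indicator_values(g, indicator, rate) for g in groups.values()]
            if len(groups) == 2:
                mw = mann_whitney(samples[0], samples[1])
                stat, p, test = mw.z, mw.p_value, "mann_whitney"
            else:
                stat, p = kruskal_wallis(samples)
                test = "kruskal_wallis"
            for lv, vals in zip(groups, samples):
                p25, med, p75 = np.percentile(vals, [25, 50, 75])
                rows.append(
                    {
                        "stratification": label,
                        "level": str(lv),
                        "n": len(vals),
                        "indicator": indicator,
                        "summary": f"{round_half_up(float(med), ndigits)}"
                        f"({round_half_up(float(p25), ndigits)}, {round_half_up(float(p75), ndigits)})",
                        "test": test,
                        "statistic": round_half_up(float(stat), 3),
                        "p_value": p,
                    }
                )
    return pd.DataFrame(rows)


def run_matched_analysis(
    episodes: pd.DataFrame,
    infections: pd.DataFrame,
    model: str = "risk_set",
    criteria: MatchCriteria | None = None,
    caliper: float = 0.2,
    seed: int = 0,
    rate: float | None = DEFAULT_USD_RATE,
) -> tuple[MatchedCohort, dict[str, GroupComparison]]:
    """Match with the chosen design, then compare cases vs controls.

    For the exact and propensity designs, cases are the infected episodes and
    the control pool is the never-infected remainder; the risk-set design
    works from the full table and infection onset times.  Returns the cohort
    and one :class:`GroupComparison` per settlement indicator (empty dict when
    nothing matched).
    """
    if model not in MODEL_RUNNERS:
        raise ConfigurationError(f"unknown matching model {model!r}")
    criteria = criteria or MatchCriteria()
    df = episodes if "dip_differential_cny" in episodes.columns else add_differential_column(episodes)
    infected_ids = set(infections["episode_id"])
    if model == "risk_set":
        cohort = risk_set_match(df, infections, criteria, seed=seed)
    else:
        cases = df[df["episode_id"].isin(infected_ids)]
        controls = df[~df["episode_id"].isin(infected_ids)]
        if model == "exact":
            cohort = exact_match(cases, controls, criteria, seed=seed)
        else:
            cohort = propensity_match(cases, controls, criteria, caliper=caliper, seed=seed)
    if not cohort.pairs:
        log.warning("model %s produced zero matched pairs", model)
        return cohort, {}
    idx = df.set_index("episode_id")
    case_df = idx.loc[list(cohort.case_ids)].reset_index()
    ctrl_df = idx.loc[list(cohort.control_ids)].reset_index()
    comparisons = {
        indicator: compare_groups(
            indicator_values(case_df, indicator, rate),
            indicator_values(ctrl_df, indicator, rate),
            indicator,
        )
        for indicator in INDICATORS
    }
    return cohort, comparisons


def _decisions_in_force(config: AnalysisConfig) -> dict:
    return {
        "caliper_convention": "0.2 x SD of logit propensity, pooled sample",
        "exact_p_threshold": "exact Mann-Whitney enumeration when min(n) <= 20 and no ties",
        "hl_interval": "Moses rank interval, normal-quantile cut, no interpolation",
        "control_reuse": "without replacement; first assignment wins on case/control conflict",
        "risk_set_boundary": "onset == T1 excludes the candidate (strictly not-yet-infected)",
        "glm_covariance": "HC1 sandwich, normal reference",
        "report_currency": f"USD at {config.currency_rate} CNY/USD",
        "rounding": f"half-up to {config.rounding} decimals at the reporting boundary",
    }


def run_full(config: AnalysisConfig) -> dict:
    """Execute the whole study and write the report bundle.

    Stages: simulate (optional) -> CACI -> profiles -> category report ->
    classification report -> matched comparisons (each configured model) ->
    GLM on the risk-set cohort -> manifest.  Identical configuration yields a
    byte-identical bundle.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rate = config.currency_rate

    if config.simulate is not None:
        episodes, infections = generate_cohort(config.simulate)
    else:
        episodes = read_episodes(config.episodes_path)
        infections = read_infections(config.infections_path)

    scored, profiles = prepare_tables(episodes, infections)
    write_tables(episodes, infections, out)
    profiles.to_csv(out / "profiles.csv", index=False)
    scored[["episode_id", "caci_score", "caci_stratum"]].to_csv(out / "caci.csv", index=False)

    n_patients = len(scored)
    n_cases = int(scored["episode_id"].isin(set(infections["episode_id"])).sum())
    bundle: dict = {
        "n_patients": n_patients,
        "n_hai_cases": n_cases,
        "hai_incidence_pct": incidence_rate(n_cases, n_patients),
        "hai_incidence_pct_exact": incidence_rate_exact(n_cases, n_patients),
    }

    if not infections.empty:
        category = run_category_report(scored, infections, config.top_k, rate, config.rounding)
        category.to_csv(out / "category_report.csv", index=False)
        bundle["category_report"] = category
        classification = run_classification_report(scored, profiles, rate, config.rounding)
        classification.to_csv(out / "classification_report.csv", index=False)
        bundle["classification_report"] = classification

    bundle["matched"] = {}
    risk_set_cohort: MatchedCohort | None = None
    for model in config.models:
        cohort, comparisons = run_matched_analysis(
            scored, infections, model, config.criteria, config.caliper, config.seed, rate
        )
        cohort.to_frame().to_csv(out / f"pairs_{model}.csv", index=False)
        table = pd.DataFrame(
            [_comparison_row(c, config.rounding) for c in comparisons.values()]
        )
        table.to_csv(out / f"matched_comparison_{model}.csv", index=False)
        bundle["matched"][model] = {
            "cohort": cohort,
            "comparisons": comparisons,
            "n_pairs": len(cohort.pairs),
            "n_unmatched_cases": cohort.n_unmatched_cases,
        }
        if model == "risk_set":
            risk_set_cohort = cohort

    if risk_set_cohort is not None and risk_set_cohort.pairs:
        design = build_design(scored, profiles, risk_set_cohort, currency_rate=rate)
        try:
            fit = fit_glm(None, design)
        except RankDeficiencyError as exc:
            # small matched samples can leave two dummies perfectly aligned;
            # report everything else rather than failing the whole run
            log.warning("GLM skipped: %s", exc)
        else:
            glm_table(fit, config.rounding).to_csv(out / "glm_table.csv", index=False)
            bundle["glm"] = fit

    manifest = {
        "package": "haiburden",
        "version": _version,
        "seed": config.seed,
        "models": list(config.models),
        "alpha": config.alpha,
        "currency_rate": rate,
        "n_patients": n_patients,
        "n_hai_cases": n_cases,
        "decisions": _decisions_in_force(config),
        "simulated": config.simulate is not None,
    }
    if config.simulate is not None:
        manifest["cohort_config"] = json.loads(
            json.dumps(dataclasses.asdict(config.simulate), default=str)
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
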