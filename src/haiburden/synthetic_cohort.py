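"""Synthetic inpatient cohorts for a cancer center under DIP settlement.

The generator emulates the statistical structure the analysis pipeline
assumes: a large discharge cohort (right-skewed, category-specific cost and
length-of-stay distributions; a per-category DIP standard payment), a rare
hospital-acquired-infection (HAI) process acting only from day 2 of the stay
(the >=48 h rule), and known-magnitude infection effects injected into the
infected episodes' costs, length of stay and standard payment.  Because the
injected effects are known exactly, the pipeline's estimators can be tested
for parameter recovery.

Time model: day 0 is admission, days are integers, and an episode is at risk
of acquiring an infection on days ``2..length_of_stay``; the daily hazard acts
as an independent Bernoulli trial per at-risk day (a geometric onset time,
truncated at discharge).  Multiple infections per stay are allowed: after an
onset, trials continue on the remaining pre-extension days.

Determinism: generation is a pure function of ``(config, seed)``.  One master
seed spawns independent child streams (demographics, category assignment,
costs, comorbidities, hazard, event attributes), so changing one component of
the configuration does not perturb draws in the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .settlement import DEFAULT_USD_RATE

__all__ = [
    "DipCategorySpec",
    "EffectSpec",
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "inject_effects",
    "write_tables",
    "read_episodes",
    "read_infections",
]

WOUND_LEVEL = {"none": 0, "0": 0, "I": 1, "II": 2, "III": 3}
MDRO_LABELS = ("CRE", "MRSA", "CRAB", "CRPA", "VRE")
ORGANISMS = (
    "Escherichia coli",
    "Klebsiella pneumoniae",
    "Pseudomonas aeruginosa",
    "Staphylococcus aureus",
    "Acinetobacter baumannii",
    "Enterococcus faecium",
    "Candida albicans",
)


@dataclass(frozen=True)
class DipCategorySpec:
    """Baseline distributions for one DIP category.

    Costs are log-normal around ``cost_median_cny``; length of stay is
    log-normal around ``los_median_days`` rounded to whole days (``los_sigma``
    of 0 gives a fixed stay).  ``standard_payment_cny`` defaults to the
    baseline cost median, so uninfected differentials center near zero.
    ``hazard_multiplier`` scales the cohort-wide daily infection hazard; high
    multipliers model surgical categories where HAIs concentrate.
    """

    code: str
    weight: float = 1.0
    cost_median_cny: float = 10_000.0
    cost_sigma: float = 0.5
    los_median_days: float = 8.0
    los_sigma: float = 0.4
    standard_payment_cny: float | None = None
    surgery_probability: float = 0.0
    wound_class_distribution: tuple[float, float, float, float] = (0.05, 0.45, 0.45, 0.05)
    hazard_multiplier: float = 1.0
    principal_icd10: str = "C80.9"

    @property
    def payment(self) -> float:
        return self.cost_median_cny if self.standard_payment_cny is None else self.standard_payment_cny


@dataclass(frozen=True)
class EffectSpec:
    """Known-magnitude infection effects injected into infected episodes.

    The per-episode cost delta is::

        cost_inflation * mdro_escalation**max(k - 1, 0)
            + wound_class_escalation * wound_level        (SSI episodes only)

    where ``k`` is the number of distinct MDRO types across the stay and
    ``wound_level`` maps surgical wound classes 0/I/II/III to 0..3.  The
    diagnostic delta is ``diagnostic_inflation`` under the same MDRO
    multiplier (diagnostic cost is a sub-ledger of the total, so the subset
    invariant is preserved).  ``payment_uplift_cny`` is added to the infected
    episode's DIP standard payment, modelling partial regrouping of
    complicated stays into higher-paying groups; it decouples the cost
    inflation from the (smaller) DIP-differential deficit.

    Defaults are CNY equivalents (at 7.12 CNY/USD) of a +$5,031.01 cost,
    +$798.81 diagnostic and 9-day stay extension, with a payment uplift
    leaving a -$1,436.27 differential effect at MDRO count 0.
    """

    cost_inflation_cny: float = 35_820.79
    diagnostic_inflation_cny: float = 5_687.53
    los_extension_days: int = 9
    mdro_escalation: float = 1.5
    wound_class_escalation_cny: float = 2_500.0
    payment_uplift_cny: float = 25_594.55

    def cost_delta(self, n_mdro_types: int, wound_level: int, has_ssi: bool) -> float:
        mult = self.mdro_escalation ** max(n_mdro_types - 1, 0)
        delta = self.cost_inflation_cny * mult
        if has_ssi:
            delta += self.wound_class_escalation_cny * wound_level
        return delta

    def diagnostic_delta(self, n_mdro_types: int) -> float:
        return self.diagnostic_inflation_cny * self.mdro_escalation ** max(n_mdro_types - 1, 0)


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 20_000
    dip_catalogue: tuple[DipCategorySpec, ...] = ()
    daily_infection_hazard: float = 7.22e-4
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    # P(0, 1, 2, >=3 distinct MDRO types | infected)
    mdro_count_distribution: tuple[float, float, float, float] = (0.7456, 0.2157, 0.0237, 0.0150)
    age_mean: float = 56.0
    age_sd: float = 12.0
    age_range: tuple[int, int] = (18, 90)
    sex_ratio_male: float = 0.55
    dip_settlement_probability: float = 0.597
    comorbidity_code_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {
            "C78.0": 0.15,  # lung metastasis
            "C79.5": 0.08,  # bone metastasis
            "E11.9": 0.10,  # type 2 diabetes
            "I10": 0.08,    # hypertension (outside Charlson map)
            "I25.2": 0.03,  # old myocardial infarction
            "I50.0": 0.03,  # congestive heart failure
            "J44.9": 0.05,  # COPD
            "N18.3": 0.03,  # chronic kidney disease
            "B18.1": 0.04,  # chronic hepatitis B
            "I63.9": 0.03,  # cerebral infarction
        }
    )
    diagnostic_fraction_beta: tuple[float, float] = (2.5, 12.0)
    # probability a surgical episode has its wound class recorded on the sheet
    wound_recorded_probability: float = 0.9
    device_probability: tuple[float, float] = (0.15, 0.60)  # (non-surgical, surgical)
    # event-site probabilities (SSI, CLABSI, VAP, CAUTI, other)
    site_probs_surgical: tuple[float, ...] = (0.55, 0.03, 0.03, 0.02, 0.37)
    site_probs_medical: tuple[float, ...] = (0.0, 0.03, 0.03, 0.02, 0.92)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if not self.dip_catalogue:
            raise ConfigurationError("dip_catalogue must contain at least one category")
        if not (0.0 <= self.daily_infection_hazard < 1.0):
            raise ConfigurationError(
                f"daily_infection_hazard must lie in [0, 1), got {self.daily_infection_hazard}"
            )
        for name, dist in (
            ("mdro_count_distribution", self.mdro_count_distribution),
            ("site_probs_surgical", self.site_probs_surgical),
            ("site_probs_medical", self.site_probs_medical),
        ):
            if any(p < 0 for p in dist) or abs(sum(dist) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be non-negative and sum to 1")
        if not (0.0 <= self.sex_ratio_male <= 1.0):
            raise ConfigurationError(f"sex_ratio_male must lie in [0, 1], got {self.sex_ratio_male}")
        if not (0.0 <= self.dip_settlement_probability <= 1.0):
            raise ConfigurationError("dip_settlement_probability must lie in [0, 1]")
        if not (0.0 <= self.wound_recorded_probability <= 1.0):
            raise ConfigurationError("wound_recorded_probability must lie in [0, 1]")
        for code, p in self.comorbidity_code_frequencies.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"comorbidity_code_frequencies[{code!r}] must lie in [0, 1], got {p}"
                )
        for cat in self.dip_catalogue:
            if cat.cost_median_cny <= 0 or cat.cost_sigma <= 0:
                raise ConfigurationError(
                    f"dip_catalogue[{cat.code}]: cost location/scale must be > 0"
                )
            if cat.los_median_days < 1 or cat.los_sigma < 0:
                raise ConfigurationError(
                    f"dip_catalogue[{cat.code}]: LOS distribution invalid"
                )
            if not (0.0 <= cat.surgery_probability <= 1.0):
                raise ConfigurationError(
                    f"dip_catalogue[{cat.code}].surgery_probability must lie in [0, 1]"
                )
            wd = cat.wound_class_distribution
            if len(wd) != 4 or any(p < 0 for p in wd) or abs(sum(wd) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"dip_catalogue[{cat.code}].wound_class_distribution must be 4 "
                    "non-negative probabilities summing to 1"
                )
            if cat.hazard_multiplier < 0:
                raise ConfigurationError(
                    f"dip_catalogue[{cat.code}].hazard_multiplier must be >= 0"
                )
            if cat.weight <= 0:
                raise ConfigurationError(f"dip_catalogue[{cat.code}].weight must be > 0")
        if self.effect_spec.los_extension_days < 0:
            raise ConfigurationError("effect_spec.los_extension_days must be >= 0")
        if self.effect_spec.mdro_escalation < 1.0:
            raise ConfigurationError("effect_spec.mdro_escalation must be >= 1")


# Category catalogue loosely modelled on the HAI-concentrated surgical groups
# of a large specialty cancer center (baseline medians in CNY; LOS in days),
# plus a dominant low-risk "general oncology" remainder.  Hazard multipliers
# are calibrated so surgical categories reach several-percent incidence while
# the cohort-wide incidence stays near 0.4%.
_DEFAULT_CATALOGUE = (
    DipCategorySpec("ESOPH-3INC", weight=395, cost_median_cny=115_365.0, cost_sigma=0.35,
                    los_median_days=15.0, los_sigma=0.35, surgery_probability=1.0,
                    hazard_multiplier=8.37, principal_icd10="C15.3"),
    DipCategorySpec("STOMACH-SURG", weight=746, cost_median_cny=30_516.0, cost_sigma=0.45,
                    los_median_days=9.0, los_sigma=0.40, surgery_probability=1.0,
                    hazard_multiplier=6.30, principal_icd10="C16.9"),
    DipCategorySpec("RECTUM-LAR", weight=452, cost_median_cny=46_700.0, cost_sigma=0.30,
                    los_median_days=10.0, los_sigma=0.35, surgery_probability=1.0,
                    hazard_multiplier=6.51, principal_icd10="C20"),
    DipCategorySpec("RECTUM-LAR-ILEO", weight=286, cost_median_cny=54_924.0, cost_sigma=0.35,
                    los_median_days=10.0, los_sigma=0.30, surgery_probability=1.0,
                    hazard_multiplier=10.06, principal_icd10="C20"),
    DipCategorySpec("CERVIX-RH-BSO", weight=580, cost_median_cny=40_195.0, cost_sigma=0.35,
                    los_median_days=10.0, los_sigma=0.30, surgery_probability=1.0,
                    hazard_multiplier=4.61, principal_icd10="C53.9"),
    DipCategorySpec("ONC-GENERAL", weight=203_110, cost_median_cny=10_680.0, cost_sigma=0.55,
                    los_median_days=5.0, los_sigma=0.50, surgery_probability=0.05,
                    hazard_multiplier=1.0, principal_icd10="C34.9"),
)


def default_config(n_patients: int = 20_000, seed: int = 0, **overrides) -> CohortConfig:
    """Study-scale defaults: ~0.4% HAI incidence with surgical hot spots."""
    cfg = CohortConfig(n_patients=n_patients, dip_catalogue=_DEFAULT_CATALOGUE, seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def _truncated_geometric(u: np.ndarray, h: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Inverse-CDF sample of the first success day index in ``0..d-1``.

    ``u`` uniform(0,1), ``h`` per-trial hazard, ``d`` number of trials;
    conditioned on at least one success within ``d`` trials.
    """
    total = 1.0 - (1.0 - h) ** d
    g = np.floor(np.log1p(-u * total) / np.log1p(-h))
    return np.clip(g.astype(np.int64), 0, d - 1)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns ``(episodes, infections)`` tables.

    Infected episodes have their cost, diagnostic cost, length of stay and
    standard payment inflated per ``config.effect_spec`` relative to their own
    pre-infection draw (see :func:`inject_effects`).  Identical ``config``
    (including its seed) reproduces bit-identical tables.
    """
    config.validate()
    n = config.n_patients
    cats = config.dip_catalogue
    k = len(cats)
    ss = np.random.SeedSequence(config.seed)
    (s_demo, s_cat, s_cost, s_comorb, s_hazard, s_events) = ss.spawn(6)
    rng_demo = np.random.default_rng(s_demo)
    rng_cat = np.random.default_rng(s_cat)
    rng_cost = np.random.default_rng(s_cost)
    rng_comorb = np.random.default_rng(s_comorb)
    rng_hazard = np.random.default_rng(s_hazard)
    rng_events = np.random.default_rng(s_events)

    weights = np.array([c.weight for c in cats], float)
    weights /= weights.sum()
    cat_idx = rng_cat.choice(k, size=n, p=weights)

    lo, hi = config.age_range
    age = np.clip(np.rint(rng_demo.normal(config.age_mean, config.age_sd, n)), lo, hi).astype(int)
    sex = np.where(rng_demo.random(n) < config.sex_ratio_male, "male", "female")
    admission_day = rng_demo.integers(0, 365, n)
    payment_type = np.where(
        rng_demo.random(n) < config.dip_settlement_probability, "DIP", "non-DIP"
    )
    surgery = rng_demo.random(n) < np.array([c.surgery_probability for c in cats])[cat_idx]
    wound_u = rng_demo.random(n)
    wound_rec_u = rng_demo.random(n)
    device_u = rng_demo.random(n)

    cost_med = np.array([c.cost_median_cny for c in cats])[cat_idx]
    cost_sig = np.array([c.cost_sigma for c in cats])[cat_idx]
    cost = np.exp(rng_cost.normal(np.log(cost_med), cost_sig))
    diag_frac = rng_cost.beta(*config.diagnostic_fraction_beta, size=n)
    diagnostic = cost * diag_frac
    payment = np.array([c.payment for c in cats])[cat_idx]

    los_med = np.array([c.los_median_days for c in cats])[cat_idx]
    los_sig = np.array([c.los_sigma for c in cats])[cat_idx]
    los = np.maximum(1, np.rint(np.exp(rng_cost.normal(np.log(los_med), los_sig)))).astype(np.int64)

    wound_class = np.full(n, "none", dtype=object)
    recorded = wound_rec_u < config.wound_recorded_probability
    for j, cat in enumerate(cats):
        mask = surgery & recorded & (cat_idx == j)
        if not mask.any():
            continue
        cum = np.cumsum(cat.wound_class_distribution)
        wound_class[mask] = np.array(["0", "I", "II", "III"], dtype=object)[
            np.searchsorted(cum, wound_u[mask], side="right").clip(0, 3)
        ]
    p_dev = np.where(surgery, config.device_probability[1], config.device_probability[0])
    device = device_u < p_dev

    # comorbidity codes: principal malignancy code per category plus
    # independently sampled secondary codes at the configured frequencies
    sec_codes = list(config.comorbidity_code_frequencies.items())
    sec_draws = rng_comorb.random((n, len(sec_codes))) if sec_codes else np.zeros((n, 0))
    principal = np.array([c.principal_icd10 for c in cats], dtype=object)[cat_idx]
    code_lists: list[str] = []
    for i in range(n):
        codes = [principal[i]]
        codes.extend(code for j, (code, p) in enumerate(sec_codes) if sec_draws[i, j] < p)
        code_lists.append(";".join(codes))

    # infection process: Bernoulli trial per at-risk day (days 2..LOS)
    hazard = np.clip(
        config.daily_infection_hazard * np.array([c.hazard_multiplier for c in cats])[cat_idx],
        0.0, 0.999,
    )
    at_risk = np.maximum(los - 1, 0)
    with np.errstate(divide="ignore"):
        p_inf = np.where(at_risk > 0, 1.0 - (1.0 - hazard) ** at_risk, 0.0)
    u_inf = rng_hazard.random(n)
    u_onset = rng_hazard.random(n)
    infected = u_inf < p_inf
    inf_idx = np.flatnonzero(infected)
    onset1 = np.zeros(n, dtype=np.int64)
    if inf_idx.size:
        onset1[inf_idx] = 2 + _truncated_geometric(
            u_onset[inf_idx], hazard[inf_idx], at_risk[inf_idx]
        )

    episode_ids = np.array([f"E{i:07d}" for i in range(n)], dtype=object)
    events: list[dict] = []
    horizon_extra = int(config.effect_spec.los_extension_days)
    for i in inf_idx:
        onsets = [int(onset1[i])]
        # subsequent events may occur up to the (extended) discharge day
        day = onsets[0]
        horizon = int(los[i]) + horizon_extra
        while day < horizon:
            remaining = int(horizon - day)
            if rng_events.random() >= 1.0 - (1.0 - hazard[i]) ** remaining:
                break
            g = _truncated_geometric(
                np.array([rng_events.random()]), np.array([hazard[i]]), np.array([remaining])
            )[0]
            day = day + 1 + int(g)
            onsets.append(day)
        n_mdro = int(rng_events.choice(4, p=config.mdro_count_distribution))
        mdro = list(rng_events.choice(MDRO_LABELS, size=min(n_mdro, len(MDRO_LABELS)), replace=False)) if n_mdro else []
        site_p = config.site_probs_surgical if surgery[i] else config.site_probs_medical
        for j, onset in enumerate(onsets):
            site = ("SSI", "CLABSI", "VAP", "CAUTI", "other")[int(rng_events.choice(5, p=site_p))]
            organisms = list(rng_events.choice(ORGANISMS, size=int(rng_events.integers(1, 3)), replace=False))
            events.append(
                {
                    "episode_id": episode_ids[i],
                    "onset_day": int(onset),
                    "site": site,
                    "organisms": ";".join(organisms),
                    "mdro_types": ";".join(mdro) if j == 0 else "",
                }
            )

    episodes = pd.DataFrame(
        {
            "episode_id": episode_ids,
            "sex": sex,
            "age": age,
            "admission_day": admission_day,
            "length_of_stay": los,
            "dip_category": np.array([c.code for c in cats], dtype=object)[cat_idx],
            "payment_type": payment_type,
            "hospitalization_cost_cny": cost,
            "diagnostic_cost_cny": diagnostic,
            "dip_standard_payment_cny": payment.astype(float),
            "icd10_codes": code_lists,
            "surgery_flag": surgery,
            "wound_class": wound_class,
            "invasive_device_flag": device,
        }
    )
    infections = pd.DataFrame(
        events,
        columns=["episode_id", "onset_day", "site", "organisms", "mdro_types"],
    )
    infections.insert(0, "event_id", [f"H{j:06d}" for j in range(len(infections))])
    # any catheter-associated event implies an invasive device was in place
    if len(infections):
        cath_eps = set(infections.loc[infections["site"].isin(("CLABSI", "VAP", "CAUTI")), "episode_id"])
        if cath_eps:
            episodes.loc[episodes["episode_id"].isin(cath_eps), "invasive_device_flag"] = True

    episodes = inject_effects(episodes, infections, config.effect_spec)
    return episodes, infections


def inject_effects(
    episodes: pd.DataFrame, infections: pd.DataFrame, effect_spec: EffectSpec
) -> pd.DataFrame:
    """Apply infection effects to infected episodes; uninfected rows unchanged.

    The cost delta is ``cost_inflation`` scaled by the MDRO escalation
    multiplier plus the wound-class gradient (SSI episodes); the stay is
    extended by ``los_extension_days``; the standard payment is raised by
    ``payment_uplift_cny``.  Returns a new table.
    """
    out = episodes.copy()
    if infections.empty:
        return out
    known = pd.Index(out["episode_id"])
    orphan = ~infections["episode_id"].isin(known)
    if orphan.any():
        raise DataIntegrityError(
            "infection events reference unknown episodes: "
            f"{sorted(infections.loc[orphan, 'episode_id'].unique())[:5]}"
        )
    mdro_n = (
        infections.assign(
            _t=infections["mdro_types"].fillna("").map(
                lambda s: frozenset(t for t in str(s).split(";") if t)
            )
        )
        .groupby("episode_id")["_t"]
        .agg(lambda col: len(frozenset().union(*col)))
    )
    has_ssi = (
        infections.assign(_s=infections["site"].eq("SSI")).groupby("episode_id")["_s"].any()
    )
    pos = {eid: i for i, eid in enumerate(out["episode_id"])}
    rows = np.array([pos[eid] for eid in mdro_n.index])
    wound = out["wound_class"].map(WOUND_LEVEL).to_numpy()
    k_arr = mdro_n.to_numpy(int)
    ssi_arr = has_ssi.reindex(mdro_n.index).fillna(False).to_numpy(bool)
    cost_delta = np.array(
        [
            effect_spec.cost_delta(k, int(wound[r]), bool(s))
            for k, r, s in zip(k_arr, rows, ssi_arr)
        ]
    )
    diag_delta = np.array([effect_spec.diagnostic_delta(k) for k in k_arr])
    cost_col = out.columns.get_loc("hospitalization_cost_cny")
    diag_col = out.columns.get_loc("diagnostic_cost_cny")
    los_col = out.columns.get_loc("length_of_stay")
    pay_col = out.columns.get_loc("dip_standard_payment_cny")
    out.iloc[rows, cost_col] = out.iloc[rows, cost_col].to_numpy(float) + cost_delta
    out.iloc[rows, diag_col] = out.iloc[rows, diag_col].to_numpy(float) + diag_delta
    out.iloc[rows, los_col] = out.iloc[rows, los_col].to_numpy(np.int64) + int(
        effect_spec.los_extension_days
    )
    out.iloc[rows, pay_col] = out.iloc[rows, pay_col].to_numpy(float) + effect_spec.payment_uplift_cny
    return out


def write_tables(episodes: pd.DataFrame, infections: pd.DataFrame, out_dir) -> None:
    """Write ``episodes.csv`` and ``infections.csv`` (UTF-8, RFC-4180)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    episodes.to_csv(out / "episodes.csv", index=False)
    infections.to_csv(out / "infections.csv", index=False)


def read_episodes(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"episode_id": str, "dip_category": str, "wound_class": str, "icd10_codes": str},
        keep_default_na=False,
        na_values=[],
    )
    for col in ("age", "admission_day", "length_of_stay"):
        df[col] = df[col].astype(np.int64)
    for col in ("hospitalization_cost_cny", "diagnostic_cost_cny", "dip_standard_payment_cny"):
        df[col] = df[col].astype(float)
    for col in ("surgery_flag", "invasive_device_flag"):
        df[col] = df[col].map({"True": True, "False": False, True: True, False: False}).astype(bool)
    return df


def read_infections(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"event_id": str, "episode_id": str, "site": str, "organisms": str, "mdro_types": str},
        keep_default_na=False,
        na_values=[],
    )
    if len(df):
        df["onset_day"] = df["onset_day"].astype(np.int64)
    return df
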