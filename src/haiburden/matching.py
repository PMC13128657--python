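"""Case-control construction: exact, propensity-score and risk-set matching.

Three 1:1 designs, all without replacement and all matching on the same
criteria (identical DIP category, same sex, age difference within 5 years,
same CACI risk stratum):

* ``exact_match`` — conventional greedy 1:1 exact matching of infected cases
  to never-infected controls.
* ``propensity_match`` — 1:1 nearest-neighbour matching on the logit
  propensity score with a caliper of 0.2 pooled logit standard deviations;
  the propensity model regresses case status on age, sex and CACI stratum,
  while the DIP category enters as an exact-match constraint (avoiding a
  high-cardinality dummy expansion prone to separation).
* ``risk_set_match`` — the primary design for time-dependent exposure: each
  case infected on day T1 is matched to a patient still hospitalized and not
  yet infected on day T1 (future cases are eligible), which removes the
  time-dependent bias that inflates length-of-stay contrasts when cases are
  compared against never-infected patients.

Greedy sequential matching is used throughout (risk-set cases in ascending
T1); ties break by smallest absolute age difference, then stable episode-id
order, so all three matchers are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MatchingError

__all__ = [
    "MatchCriteria",
    "MatchedPair",
    "MatchedCohort",
    "exact_match",
    "propensity_match",
    "eligible_risk_set",
    "risk_set_match",
    "first_onset_by_episode",
]

log = logging.getLogger(__name__)

_REQUIRED_COLS = ("episode_id", "sex", "age", "dip_category", "caci_stratum")


@dataclass(frozen=True)
class MatchCriteria:
    require_same_dip_category: bool = True
    require_same_sex: bool = True
    max_age_difference: float = 5.0
    require_same_caci_stratum: bool = True

    def __post_init__(self) -> None:
        if self.max_age_difference < 0:
            raise MatchingError("max_age_difference must be >= 0")


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: str
    model: str  # "exact" | "psm" | "risk_set"
    t1: int | None = None  # infection onset day (risk_set only)
    distance: float | None = None  # logit-propensity distance (psm only)


@dataclass(frozen=True)
class MatchedCohort:
    model: str
    pairs: tuple[MatchedPair, ...]
    n_unmatched_cases: int
    n_cases_retained_as_controls: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [p.model for p in self.pairs],
                "case_id": [p.case_id for p in self.pairs],
                "control_id": [p.control_id for p in self.pairs],
                "t1": [p.t1 for p in self.pairs],
                "distance": [p.distance for p in self.pairs],
            }
        )

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(p.case_id for p in self.pairs)

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(p.control_id for p in self.pairs)


def _check_columns(df: pd.DataFrame, what: str) -> None:
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise MatchingError(f"{what} table lacks required columns {missing}; "
                            "score CACI strata first")


class _Pool:
    """Control pool with vectorised criteria masks and a used flag."""

    def __init__(self, controls: pd.DataFrame):
        ordered = controls.sort_values("episode_id", kind="mergesort").reset_index(drop=True)
        self.ids = ordered["episode_id"].to_numpy(object)
        self.sex = ordered["sex"].to_numpy(object)
        self.age = ordered["age"].to_numpy(float)
        self.cat = ordered["dip_category"].to_numpy(object)
        self.stratum = ordered["caci_stratum"].to_numpy(object)
        self.los = (
            ordered["length_of_stay"].to_numpy(float)
            if "length_of_stay" in ordered.columns
            else np.full(len(ordered), np.inf)
        )
        self.first_onset = (
            ordered["first_onset_day"].to_numpy(float)
            if "first_onset_day" in ordered.columns
            else np.full(len(ordered), np.inf)
        )
        self.used = np.zeros(len(ordered), dtype=bool)
        self.extra = ordered

    def criteria_mask(self, case, criteria: MatchCriteria) -> np.ndarray:
        mask = ~self.used
        if criteria.require_same_dip_category:
            mask &= self.cat == case["dip_category"]
        if criteria.require_same_sex:
            mask &= self.sex == case["sex"]
        if criteria.require_same_caci_stratum:
            mask &= self.stratum == case["caci_stratum"]
        mask &= np.abs(self.age - float(case["age"])) <= criteria.max_age_difference
        mask &= self.ids != case["episode_id"]
        return mask

    def take_nearest_age(self, case, mask: np.ndarray) -> int | None:
        """Smallest |age difference|; ties go to the smallest episode id."""
        if not mask.any():
            return None
        dist = np.abs(self.age - float(case["age"]))
        dist[~mask] = np.inf
        j = int(np.argmin(dist))  # ids are sorted, argmin keeps first = smallest id
        self.used[j] = True
        return j


def exact_match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    criteria: MatchCriteria | None = None,
    seed: int | None = None,
) -> MatchedCohort:
    """Greedy 1:1 exact matching without replacement (Model 1).

    Cases are processed in stable episode-id order; ``seed`` is accepted for
    interface parity with the stochastic designs but unused.  An empty control
    pool yields a cohort with every case unmatched, not an error.
    """
    criteria = criteria or MatchCriteria()
    _check_columns(cases, "cases")
    if len(controls) == 0:
        return MatchedCohort("exact", (), len(cases))
    _check_columns(controls, "controls")
    pool = _Pool(controls)
    pairs: list[MatchedPair] = []
    unmatched = 0
    for _, case in cases.sort_values("episode_id", kind="mergesort").iterrows():
        j = pool.take_nearest_age(case, pool.criteria_mask(case, criteria))
        if j is None:
            unmatched += 1
        else:
            pairs.append(MatchedPair(case["episode_id"], pool.ids[j], "exact"))
    return MatchedCohort("exact", tuple(pairs), unmatched)


def _fit_propensity(pooled: pd.DataFrame, is_case: np.ndarray) -> np.ndarray:
    """Logit propensity of case status given age, sex, CACI stratum."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = pd.DataFrame(
        {
            "const": 1.0,
            "age": pooled["age"].astype(float),
            "female": (pooled["sex"] == "female").astype(float),
            "caci_high": (pooled["caci_stratum"] == "high").astype(float),
        }
    )
    if len(np.unique(X.to_numpy(), axis=0)) < 2:
        raise MatchingError(
            "propensity model is not estimable: fewer than two distinct "
            "covariate patterns; use exact matching instead"
        )
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(is_case.astype(float), X).fit(disp=False, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise MatchingError(
            "degenerate propensity fit (perfect separation); use exact matching instead"
        ) from exc
    params = np.asarray(res.params, float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 30:
        raise MatchingError(
            "degenerate propensity fit (perfect separation); use exact matching instead"
        )
    return X.to_numpy() @ params  # linear predictor = logit propensity


def propensity_match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    criteria: MatchCriteria | None = None,
    caliper: float = 0.2,
    seed: int = 0,
) -> MatchedCohort:
    """1:1 nearest-neighbour propensity matching with a logit-SD caliper (Model 2).

    The caliper is ``caliper`` times the standard deviation of the logit
    propensity over the pooled sample; cases are processed in random order
    under ``seed``; matching is without replacement within the exact
    DIP-category constraint.
    """
    criteria = criteria or MatchCriteria()
    _check_columns(cases, "cases")
    _check_columns(controls, "controls")
    pooled = pd.concat([cases, controls], ignore_index=True)
    is_case = np.concatenate([np.ones(len(cases), bool), np.zeros(len(controls), bool)])
    logit = _fit_propensity(pooled, is_case)
    case_logit = dict(zip(pooled.loc[is_case, "episode_id"], logit[is_case]))
    sd = float(np.std(logit, ddof=1)) if len(logit) > 1 else 0.0
    caliper_abs = caliper * sd

    ctrl = controls.assign(_logit=logit[~is_case])
    ordered = ctrl.sort_values("episode_id", kind="mergesort").reset_index(drop=True)
    pool = _Pool(ordered)
    ctrl_logit = ordered["_logit"].to_numpy(float)

    rng = np.random.default_rng(seed)
    case_rows = cases.sort_values("episode_id", kind="mergesort").reset_index(drop=True)
    order = rng.permutation(len(case_rows))
    pairs: list[MatchedPair] = []
    unmatched = 0
    for i in order:
        case = case_rows.iloc[i]
        mask = np.ones(len(pool.ids), dtype=bool) & ~pool.used
        if criteria.require_same_dip_category:
            mask &= pool.cat == case["dip_category"]
        mask &= pool.ids != case["episode_id"]
        dist = np.abs(ctrl_logit - case_logit[case["episode_id"]])
        dist_m = np.where(mask & (dist <= caliper_abs), dist, np.inf)
        if not np.isfinite(dist_m).any():
            unmatched += 1
            continue
        j = int(np.argmin(dist_m))  # ties -> first index = smallest episode id
        pool.used[j] = True
        pairs.append(
            MatchedPair(case["episode_id"], pool.ids[j], "psm", distance=float(dist_m[j]))
        )
    pairs.sort(key=lambda p: p.case_id)
    return MatchedCohort("psm", tuple(pairs), unmatched)


def first_onset_by_episode(infections: pd.DataFrame) -> pd.Series:
    """Earliest infection onset day per episode (T1)."""
    if infections.empty:
        return pd.Series(dtype=float)
    return infections.groupby("episode_id")["onset_day"].min()


def eligible_risk_set(
    case,
    t1: int,
    pool: pd.DataFrame,
    criteria: MatchCriteria | None = None,
) -> pd.DataFrame:
    """Candidates at risk when the case is infected at day ``t1``.

    A candidate must satisfy the matching criteria, still be hospitalized at
    T1 (``length_of_stay >= t1``) and have no infection with onset day <= T1;
    patients infected later than T1 remain eligible.  The pool table may carry
    a ``first_onset_day`` column (NaN/inf for never infected).
    """
    criteria = criteria or MatchCriteria()
    p = _Pool(pool)
    mask = p.criteria_mask(case, criteria)
    mask &= p.los >= t1
    first = np.where(np.isnan(p.first_onset), np.inf, p.first_onset)
    mask &= first > t1
    return p.extra.loc[mask].drop(columns=["first_onset_day"], errors="ignore")


def risk_set_match(
    episodes: pd.DataFrame,
    infections: pd.DataFrame,
    criteria: MatchCriteria | None = None,
    seed: int | None = None,
) -> MatchedCohort:
    """Risk-set matching on infection time (Model 3, the primary design).

    Cases are processed in ascending T1 (ties by episode id) and matched 1:1
    without replacement to a member of their risk set.  An episode never
    serves as both case and control: if a selected control is infected later,
    it is retained as a control and dropped from the case list (logged and
    counted in ``n_cases_retained_as_controls``).
    """
    criteria = criteria or MatchCriteria()
    _check_columns(episodes, "episodes")
    first = first_onset_by_episode(infections)
    df = episodes.copy()
    df["first_onset_day"] = df["episode_id"].map(first)

    cases = df[df["first_onset_day"].notna()].copy()
    cases["t1"] = cases["first_onset_day"].astype(int)
    cases = cases.sort_values(["t1", "episode_id"], kind="mergesort")

    pool = _Pool(df)
    pos_of = {eid: j for j, eid in enumerate(pool.ids)}
    pairs: list[MatchedPair] = []
    unmatched = 0
    retained = 0
    used_control = set()
    for _, case in cases.iterrows():
        cid = case["episode_id"]
        if cid in used_control:
            retained += 1
            log.info("case %s already serves as a control; retained as control", cid)
            continue
        t1 = int(case["t1"])
        mask = pool.criteria_mask(case, criteria)
        mask &= pool.los >= t1
        first_arr = np.where(np.isnan(pool.first_onset), np.inf, pool.first_onset)
        mask &= first_arr > t1
        j = pool.take_nearest_age(case, mask)
        if j is None:
            unmatched += 1
            continue
        control_id = pool.ids[j]
        used_control.add(control_id)
        # the case itself can no longer serve as a control for later cases
        kj = pos_of[cid]
        pool.used[kj] = True
        pairs.append(MatchedPair(cid, control_id, "risk_set", t1=t1))
    return MatchedCohort("risk_set", tuple(pairs), unmatched, retained)
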