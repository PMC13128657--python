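import itertools

import numpy as np
import pandas as pd
import pytest

from haiburden.errors import MatchingError
from haiburden.matching import (
    MatchCriteria,
    eligible_risk_set,
    exact_match,
    first_onset_by_episode,
    propensity_match,
    risk_set_match,
)
from haiburden.pipeline import prepare_tables
from haiburden.synthetic_cohort import CohortConfig, default_config, generate_cohort

from conftest import NULL_EFFECT, episodes_frame, infections_frame, tiny_catalogue

CRIT = MatchCriteria()


def satisfies(case, control, criteria=CRIT):
    return (
        (not criteria.require_same_dip_category or case["dip_category"] == control["dip_category"])
        and (not criteria.require_same_sex or case["sex"] == control["sex"])
        and (not criteria.require_same_caci_stratum or case["caci_stratum"] == control["caci_stratum"])
        and abs(case["age"] - control["age"]) <= criteria.max_age_difference
    )


class TestExactMatch:
    def test_age_within_five_years_matches(self):
        cases = episodes_frame([{"episode_id": "C1", "age": 60}])
        controls = episodes_frame([{"episode_id": "K1", "age": 64}])
        cohort = exact_match(cases, controls)
        assert [(p.case_id, p.control_id) for p in cohort.pairs] == [("C1", "K1")]

    def test_age_beyond_five_years_unmatched(self):
        cases = episodes_frame([{"episode_id": "C1", "age": 60}])
        controls = episodes_frame([{"episode_id": "K1", "age": 66}])
        assert exact_match(cases, controls).n_unmatched_cases == 1

    def test_different_sex_unmatched(self):
        cases = episodes_frame([{"episode_id": "C1", "sex": "male"}])
        controls = episodes_frame([{"episode_id": "K1", "sex": "female"}])
        assert not exact_match(cases, controls).pairs

    def test_different_caci_stratum_unmatched(self):
        cases = episodes_frame([{"episode_id": "C1", "caci_score": 4, "caci_stratum": "high"}])
        controls = episodes_frame([{"episode_id": "K1", "caci_score": 2, "caci_stratum": "low"}])
        assert not exact_match(cases, controls).pairs

    def test_empty_pool_everyone_unmatched_not_an_error(self):
        cases = episodes_frame([{"episode_id": "C1"}, {"episode_id": "C2"}])
        cohort = exact_match(cases, cases.iloc[0:0])
        assert cohort.n_unmatched_cases == 2

    def test_tie_break_smallest_age_difference_then_id(self):
        cases = episodes_frame([{"episode_id": "C1", "age": 60}])
        controls = episodes_frame(
            [
                {"episode_id": "K3", "age": 62},
                {"episode_id": "K2", "age": 61},
                {"episode_id": "K1", "age": 61},
            ]
        )
        cohort = exact_match(cases, controls)
        assert cohort.pairs[0].control_id == "K1"

    def test_without_replacement(self):
        cases = episodes_frame([{"episode_id": f"C{i}", "age": 60} for i in range(3)])
        controls = episodes_frame([{"episode_id": "K1", "age": 60}])
        cohort = exact_match(cases, controls)
        assert len(cohort.pairs) == 1 and cohort.n_unmatched_cases == 2


class TestPropensityMatch:
    def pool(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            rows.append(
                {
                    "episode_id": f"P{i:03d}",
                    "age": int(rng.integers(40, 80)),
                    "sex": "male" if rng.random() < 0.5 else "female",
                    "caci_stratum": "high" if rng.random() < 0.5 else "low",
                }
            )
        return episodes_frame(rows)

    def test_identical_covariates_distance_zero(self):
        cases = episodes_frame(
            [
                {"episode_id": "C1", "age": 60},
                {"episode_id": "C2", "age": 48, "sex": "female"},
                {"episode_id": "C3", "age": 71, "caci_stratum": "high"},
            ]
        )
        controls = episodes_frame(
            [
                {"episode_id": "K1", "age": 60},
                {"episode_id": "K2", "age": 75},
                {"episode_id": "K3", "age": 52, "sex": "female"},
                {"episode_id": "K4", "age": 66, "caci_stratum": "high"},
                {"episode_id": "K5", "age": 44},
            ]
        )
        cohort = propensity_match(cases, controls, seed=1)
        got = {p.case_id: p for p in cohort.pairs}
        # K1 shares C1's covariates exactly, so its logit distance is zero
        assert got["C1"].control_id == "K1"
        assert got["C1"].distance == pytest.approx(0.0, abs=1e-9)

    def test_all_beyond_caliper_unmatched(self):
        df = self.pool(30)
        cases, controls = df.iloc[:10], df.iloc[10:]
        cohort = propensity_match(cases, controls, caliper=1e-9, seed=1)
        # a zero-width caliper admits only exact logit equality
        assert all(p.distance == 0.0 for p in cohort.pairs)

    def test_pairs_respect_category_constraint_and_caliper(self):
        df = self.pool(60, seed=3)
        df.loc[df.index[::2], "dip_category"] = "CAT-2"
        cases, controls = df.iloc[:20], df.iloc[20:]
        cohort = propensity_match(cases, controls, seed=2)
        ctrl = controls.set_index("episode_id")
        for p in cohort.pairs:
            case = cases.set_index("episode_id").loc[p.case_id]
            assert case["dip_category"] == ctrl.loc[p.control_id, "dip_category"]

    def test_greedy_equals_enumeration_on_toy_set(self):
        """Sequential nearest-neighbour agrees with explicit per-case enumeration."""
        cases = episodes_frame(
            [
                {"episode_id": "C1", "age": 50},
                {"episode_id": "C2", "age": 60, "sex": "female"},
                {"episode_id": "C3", "age": 70, "caci_stratum": "high"},
            ]
        )
        controls = episodes_frame(
            [
                {"episode_id": "K1", "age": 52},
                {"episode_id": "K2", "age": 59, "sex": "female"},
                {"episode_id": "K3", "age": 71, "caci_stratum": "high"},
                {"episode_id": "K4", "age": 45},
                {"episode_id": "K5", "age": 64, "sex": "female"},
            ]
        )
        seed = 7
        cohort = propensity_match(cases, controls, seed=seed)
        # independent re-derivation: same propensity model, same random case
        # order, explicit minimum over remaining candidates
        import statsmodels.api as sm

        pooled = pd.concat([cases, controls], ignore_index=True)
        y = np.r_[np.ones(len(cases)), np.zeros(len(controls))]
        X = np.column_stack(
            [
                np.ones(len(pooled)),
                pooled["age"].astype(float),
                (pooled["sex"] == "female").astype(float),
                (pooled["caci_stratum"] == "high").astype(float),
            ]
        )
        logit = X @ sm.Logit(y, X).fit(disp=False, maxiter=200).params
        caliper = 0.2 * np.std(logit, ddof=1)
        case_logit = dict(zip(pooled["episode_id"][: len(cases)], logit[: len(cases)]))
        ctrl_logit = dict(zip(pooled["episode_id"][len(cases):], logit[len(cases):]))
        order = np.random.default_rng(seed).permutation(len(cases))
        case_sorted = cases.sort_values("episode_id").reset_index(drop=True)
        available = dict(ctrl_logit)
        expected = {}
        for i in order:
            cid = case_sorted.loc[i, "episode_id"]
            cands = [
                (abs(v - case_logit[cid]), k)
                for k, v in available.items()
                if abs(v - case_logit[cid]) <= caliper
            ]
            if cands:
                _, best = min(cands)
                expected[cid] = best
                del available[best]
        got = {p.case_id: p.control_id for p in cohort.pairs}
        assert got == expected

    def test_degenerate_fit_advises_exact_matching(self):
        cases = episodes_frame([{"episode_id": "C1", "age": 80}, {"episode_id": "C2", "age": 81}])
        controls = episodes_frame([{"episode_id": "K1", "age": 40}, {"episode_id": "K2", "age": 41}])
        with pytest.raises(MatchingError, match="exact matching"):
            propensity_match(cases, controls, seed=0)

    def test_single_covariate_pattern_not_estimable(self):
        cases = episodes_frame([{"episode_id": "C1"}])
        controls = episodes_frame([{"episode_id": "K1"}])
        with pytest.raises(MatchingError, match="exact matching"):
            propensity_match(cases, controls, seed=0)


class TestEligibleRiskSet:
    def make_pool(self):
        df = episodes_frame(
            [
                {"episode_id": "K1", "length_of_stay": 3},
                {"episode_id": "K2", "length_of_stay": 12},
                {"episode_id": "K3", "length_of_stay": 12},
                {"episode_id": "K4", "length_of_stay": 12},
            ]
        )
        df["first_onset_day"] = [np.nan, 2.0, 9.0, np.nan]
        return df

    def test_eligibility_rules(self):
        case = episodes_frame([{"episode_id": "C1"}]).iloc[0]
        pool = self.make_pool()
        ids = set(eligible_risk_set(case, 5, pool)["episode_id"])
        # K1 discharged before T1; K2 already infected at T1; K3 infected later
        # (still eligible); K4 never infected
        assert ids == {"K3", "K4"}

    def test_onset_equal_to_t1_excludes(self):
        case = episodes_frame([{"episode_id": "C1"}]).iloc[0]
        pool = self.make_pool()
        ids = set(eligible_risk_set(case, 9, pool)["episode_id"])
        assert "K3" not in ids


class TestRiskSetMatch:
    def test_four_episode_toy_set(self):
        episodes = episodes_frame(
            [
                {"episode_id": "A", "length_of_stay": 20},
                {"episode_id": "B", "length_of_stay": 3},
                {"episode_id": "C", "length_of_stay": 12},
                {"episode_id": "D", "length_of_stay": 12},
            ]
        )
        infections = infections_frame(
            [
                {"episode_id": "A", "onset_day": 5},
                {"episode_id": "D", "onset_day": 2},
            ]
        )
        cohort = risk_set_match(episodes, infections)
        # D (T1=2) finds no eligible control (A infected later is eligible...)
        # A is infected at 5 > 2 and LOS 20 >= 2 -> D matches A; then A is
        # consumed as a control and dropped from the case list.
        assert {(p.case_id, p.control_id) for p in cohort.pairs} == {("D", "A")}
        assert cohort.n_cases_retained_as_controls == 1

    def test_case_a_matches_only_never_infected_survivor(self):
        episodes = episodes_frame(
            [
                {"episode_id": "A", "length_of_stay": 20},
                {"episode_id": "B", "length_of_stay": 3},
                {"episode_id": "C", "length_of_stay": 12},
            ]
        )
        infections = infections_frame([{"episode_id": "A", "onset_day": 5}])
        cohort = risk_set_match(episodes, infections)
        assert {(p.case_id, p.control_id, p.t1) for p in cohort.pairs} == {("A", "C", 5)}

    def test_no_candidates_all_unmatched(self):
        episodes = episodes_frame(
            [
                {"episode_id": "A", "length_of_stay": 20, "sex": "male"},
                {"episode_id": "B", "length_of_stay": 20, "sex": "female"},
            ]
        )
        infections = infections_frame([{"episode_id": "A", "onset_day": 4}])
        cohort = risk_set_match(episodes, infections)
        assert not cohort.pairs and cohort.n_unmatched_cases == 1

    def test_deterministic_and_valid_on_simulated_cohort(self, prepared_small_cohort):
        _, scored, infections, _ = prepared_small_cohort
        c1 = risk_set_match(scored, infections, seed=0)
        c2 = risk_set_match(scored, infections, seed=0)
        assert c1 == c2
        assert len(c1.pairs) > 10
        idx = scored.set_index("episode_id")
        first = first_onset_by_episode(infections)
        used_cases = set()
        used_controls = set()
        for p in c1.pairs:
            case, ctrl = idx.loc[p.case_id], idx.loc[p.control_id]
            assert satisfies(case, ctrl)
            assert p.case_id != p.control_id
            assert p.case_id not in used_cases and p.control_id not in used_controls
            used_cases.add(p.case_id)
            used_controls.add(p.control_id)
            assert ctrl["length_of_stay"] >= p.t1
            assert first.get(p.control_id, np.inf) > p.t1
        # never both case and control in the final cohort
        assert not (used_cases & used_controls)


def brute_force_risk_set(episodes: pd.DataFrame, infections: pd.DataFrame, criteria=CRIT):
    """Independent loop-based reference of the risk-set rules."""
    first = {}
    for _, ev in infections.iterrows():
        eid = ev["episode_id"]
        first[eid] = min(first.get(eid, 10**9), ev["onset_day"])
    cases = sorted(first.items(), key=lambda kv: (kv[1], kv[0]))
    taken = set()
    pairs = []
    matched_cases = set()
    for cid, t1 in cases:
        if cid in taken:
            continue
        case = episodes.set_index("episode_id").loc[cid]
        best = None
        for _, cand in episodes.iterrows():
            kid = cand["episode_id"]
            if kid == cid or kid in taken or kid in matched_cases:
                continue
            if not satisfies(case, cand, criteria):
                continue
            if cand["length_of_stay"] < t1:
                continue
            if first.get(kid, 10**9) <= t1:
                continue
            key = (abs(case["age"] - cand["age"]), kid)
            if best is None or key < best[0]:
                best = (key, kid)
        if best is not None:
            pairs.append((cid, best[1], t1))
            taken.add(best[1])
            matched_cases.add(cid)
    return pairs


def test_risk_set_matcher_equals_brute_force_on_small_sets():
    for seed in range(5):
        cfg = CohortConfig(n_patients=50, dip_catalogue=tiny_catalogue(),
                           daily_infection_hazard=0.02, effect_spec=NULL_EFFECT,
                           seed=100 + seed)
        episodes, infections = generate_cohort(cfg)
        scored, _ = prepare_tables(episodes, infections)
        got = [(p.case_id, p.control_id, p.t1) for p in risk_set_match(scored, infections).pairs]
        assert got == brute_force_risk_set(scored, infections)


def test_all_models_only_emit_criteria_satisfying_pairs(prepared_small_cohort):
    _, scored, infections, _ = prepared_small_cohort
    infected = scored["episode_id"].isin(set(infections["episode_id"]))
    cases, controls = scored[infected], scored[~infected]
    idx = scored.set_index("episode_id")
    for cohort in (
        exact_match(cases, controls),
        risk_set_match(scored, infections),
    ):
        assert cohort.pairs
        for p in cohort.pairs:
            assert satisfies(idx.loc[p.case_id], idx.loc[p.control_id])
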