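import numpy as np
import pandas as pd
import pytest

from haiburden.synthetic_cohort import (
    CohortConfig,
    DipCategorySpec,
    EffectSpec,
    default_config,
    generate_cohort,
)

NULL_EFFECT = EffectSpec(
    cost_inflation_cny=0.0,
    diagnostic_inflation_cny=0.0,
    los_extension_days=0,
    mdro_escalation=1.0,
    wound_class_escalation_cny=0.0,
    payment_uplift_cny=0.0,
)

#: pure-shift effects with no MDRO/wound escalation (for recovery tests)
SHIFT_EFFECT = EffectSpec(mdro_escalation=1.0, wound_class_escalation_cny=0.0)


def tiny_catalogue(**kw) -> tuple[DipCategorySpec, ...]:
    return (
        DipCategorySpec("SURG-A", weight=1.0, cost_median_cny=50_000.0, cost_sigma=0.4,
                        los_median_days=12.0, los_sigma=0.3, surgery_probability=1.0,
                        hazard_multiplier=kw.get("surg_mult", 5.0), principal_icd10="C16.9"),
        DipCategorySpec("MED-B", weight=4.0, cost_median_cny=12_000.0, cost_sigma=0.5,
                        los_median_days=6.0, los_sigma=0.5, surgery_probability=0.0,
                        hazard_multiplier=1.0, principal_icd10="C34.9"),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A ~2,000-episode cohort with an elevated hazard (plenty of cases)."""
    cfg = default_config(n_patients=2_000, seed=42, daily_infection_hazard=7.22e-4 * 10)
    episodes, infections = generate_cohort(cfg)
    return cfg, episodes, infections


@pytest.fixture(scope="session")
def prepared_small_cohort(small_cohort):
    from haiburden.pipeline import prepare_tables

    cfg, episodes, infections = small_cohort
    scored, profiles = prepare_tables(episodes, infections)
    return cfg, scored, infections, profiles


def episodes_frame(rows):
    """Build an episode table from compact dicts, filling schema defaults."""
    defaults = dict(
        sex="male", age=60, admission_day=0, length_of_stay=10,
        dip_category="CAT-1", payment_type="DIP",
        hospitalization_cost_cny=10_000.0, diagnostic_cost_cny=1_000.0,
        dip_standard_payment_cny=10_000.0, icd10_codes="C16.9",
        surgery_flag=False, wound_class="none", invasive_device_flag=False,
        caci_score=2, caci_stratum="low",
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


def infections_frame(rows):
    defaults = dict(site="other", organisms="Escherichia coli", mdro_types="")
    out = [{"event_id": f"H{i:03d}", **defaults, **r} for i, r in enumerate(rows)]
    return pd.DataFrame(out, columns=["event_id", "episode_id", "onset_day", "site",
                                      "organisms", "mdro_types"])
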