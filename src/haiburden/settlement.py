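"""Medical-insurance settlement quantities under DIP case-based payment.

Under the Diagnosis-Intervention Packet (DIP) payment model each case group
carries a standard payment; the hospital's surplus or loss on a discharge is
the *DIP payment differential*::

    differential = DIP standard payment - actual hospitalization cost

A positive differential is a surplus, a negative one a hospital loss.  This
module also computes hospital-acquired infection (HAI) incidence rates,
converts CNY amounts to USD, and derives the per-episode infection profile
(event frequency, catheter association, number of distinct multidrug-resistant
organism (MDRO) types, surgical-site-infection wound class) used by the
stratified analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, DomainError

__all__ = [
    "PatientEpisode",
    "InfectionEvent",
    "InfectionProfile",
    "dip_differential",
    "incidence_rate",
    "incidence_rate_exact",
    "round_half_up",
    "convert_currency",
    "classify_infections",
    "build_profiles",
    "add_differential_column",
]

DEFAULT_USD_RATE = 7.12  # CNY per USD, 2024 annual average

CATHETER_SITES = frozenset({"CLABSI", "VAP", "CAUTI"})
WOUND_CLASSES = ("none", "0", "I", "II", "III")


@dataclass(frozen=True)
class PatientEpisode:
    """One inpatient discharge record (costs in CNY)."""

    episode_id: str
    sex: str  # "male" | "female"
    age: int
    admission_day: int
    length_of_stay: int
    dip_category: str
    payment_type: str  # "DIP" | "non-DIP"
    hospitalization_cost: float
    diagnostic_cost: float
    dip_standard_payment: float
    icd10_codes: frozenset[str] = field(default_factory=frozenset)
    surgery_flag: bool = False
    wound_class: str = "none"
    invasive_device_flag: bool = False

    def __post_init__(self) -> None:
        if self.length_of_stay < 1:
            raise DomainError(f"length_of_stay must be >= 1, got {self.length_of_stay}")
        if not (0 <= self.diagnostic_cost <= self.hospitalization_cost):
            raise DomainError(
                "diagnostic_cost must lie in [0, hospitalization_cost], got "
                f"{self.diagnostic_cost} vs {self.hospitalization_cost}"
            )
        if self.wound_class not in WOUND_CLASSES:
            raise DomainError(f"unknown wound_class {self.wound_class!r}")
        if self.wound_class != "none" and not self.surgery_flag:
            raise DomainError("wound_class set on an episode without surgery_flag")


@dataclass(frozen=True)
class InfectionEvent:
    """A time-stamped HAI; ``onset_day`` (T1) counts days since admission (day 0)."""

    event_id: str
    episode_id: str
    onset_day: int
    site: str  # "SSI" | "CLABSI" | "VAP" | "CAUTI" | "other"
    organisms: frozenset[str] = field(default_factory=frozenset)
    mdro_types: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.onset_day < 2:
            raise DomainError(
                f"onset_day must be >= 2 (the >=48 h rule), got {self.onset_day}"
            )


@dataclass(frozen=True)
class InfectionProfile:
    """Per-episode infection classification used by the stratified tables."""

    episode_id: str
    frequency: str  # "0" | "1" | "2" | "3+"
    n_events: int
    catheter_associated: bool
    mdro_type_count: str  # "0" | "1" | "2" | "3+"
    n_mdro_types: int
    ssi_wound_class: str  # "non-SSI" | "0" | "I" | "II" | "III"


def dip_differential(standard_payment: float, actual_cost: float) -> float:
    """Standard DIP payment minus actual cost (surplus > 0, loss < 0)."""
    if not (math.isfinite(standard_payment) and math.isfinite(actual_cost)):
        raise DomainError("payment and cost must be finite")
    if actual_cost < 0:
        raise DomainError(f"actual_cost must be >= 0, got {actual_cost}")
    return standard_payment - actual_cost


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used at the reporting boundary."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def incidence_rate_exact(n_cases: int, n_patients: int) -> float:
    """Unrounded HAI incidence: newly infected patients / patients x 100%."""
    if n_patients <= 0:
        raise DomainError(f"n_patients must be > 0, got {n_patients}")
    if not (0 <= n_cases <= n_patients):
        raise DomainError(f"n_cases must lie in [0, n_patients], got {n_cases}")
    return 100.0 * n_cases / n_patients


def incidence_rate(n_cases: int, n_patients: int) -> float:
    """HAI incidence as a percentage, rounded half-up to 2 decimals for reporting."""
    return round_half_up(incidence_rate_exact(n_cases, n_patients), 2)


def convert_currency(amount_cny: float, rate: float = DEFAULT_USD_RATE) -> float:
    """Convert a CNY amount to USD at ``rate`` CNY per USD."""
    if rate <= 0:
        raise DomainError(f"exchange rate must be > 0, got {rate}")
    return amount_cny / rate


def _bin_count(n: int) -> str:
    return "3+" if n >= 3 else str(n)


def classify_infections(
    episode: PatientEpisode, events: Sequence[InfectionEvent]
) -> InfectionProfile:
    """Derive the episode's infection profile from its events.

    Frequency is the event count (binned 1/2/3+); catheter association is true
    iff any event site is CLABSI, VAP or CAUTI; the MDRO type count is the
    cardinality of the union of MDRO labels across all events of the stay
    (distinct types, not a per-event sum); the SSI wound class is the episode's
    surgical wound class when any event is an SSI, else ``"non-SSI"``.
    """
    for ev in events:
        if ev.episode_id != episode.episode_id:
            raise DataIntegrityError(
                f"event {ev.event_id} references episode {ev.episode_id}, "
                f"not {episode.episode_id}"
            )
    n_events = len(events)
    mdro_union: frozenset[str] = frozenset().union(*(ev.mdro_types for ev in events)) if events else frozenset()
    has_ssi = any(ev.site == "SSI" for ev in events)
    return InfectionProfile(
        episode_id=episode.episode_id,
        frequency=_bin_count(n_events),
        n_events=n_events,
        catheter_associated=any(ev.site in CATHETER_SITES for ev in events),
        mdro_type_count=_bin_count(len(mdro_union)),
        n_mdro_types=len(mdro_union),
        ssi_wound_class=episode.wound_class if has_ssi else "non-SSI",
    )


def build_profiles(episodes: pd.DataFrame, infections: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`classify_infections` over episode/infection tables."""
    known = set(episodes["episode_id"])
    orphans = set(infections["episode_id"]) - known
    if orphans:
        raise DataIntegrityError(
            f"infection events reference unknown episodes: {sorted(orphans)[:5]}"
        )
    idx = episodes.set_index("episode_id")
    n_events = infections.groupby("episode_id").size()
    mdro_sets = (
        infections.assign(
            _types=infections["mdro_types"].fillna("").map(
                lambda s: frozenset(t for t in str(s).split(";") if t)
            )
        )
        .groupby("episode_id")["_types"]
        .agg(lambda col: frozenset().union(*col))
        .map(len)
    )
    catheter = (
        infections.assign(_cath=infections["site"].isin(CATHETER_SITES))
        .groupby("episode_id")["_cath"]
        .any()
    )
    has_ssi = (
        infections.assign(_ssi=infections["site"].eq("SSI"))
        .groupby("episode_id")["_ssi"]
        .any()
    )
    rows = []
    for eid in episodes["episode_id"]:
        n = int(n_events.get(eid, 0))
        k = int(mdro_sets.get(eid, 0))
        ssi = bool(has_ssi.get(eid, False))
        rows.append(
            {
                "episode_id": eid,
                "frequency": _bin_count(n),
                "n_events": n,
                "catheter_associated": bool(catheter.get(eid, False)),
                "mdro_type_count": _bin_count(k),
                "n_mdro_types": k,
                "ssi_wound_class": idx.at[eid, "wound_class"] if ssi else "non-SSI",
            }
        )
    return pd.DataFrame(rows)


def add_differential_column(episodes: pd.DataFrame) -> pd.DataFrame:
    """Append ``dip_differential_cny`` = standard payment - hospitalization cost."""
    out = episodes.copy()
    out["dip_differential_cny"] = (
        out["dip_standard_payment_cny"].to_numpy(float)
        - out["hospitalization_cost_cny"].to_numpy(float)
    )
    return out
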