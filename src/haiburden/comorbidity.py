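"""Charlson age-comorbidity index (CACI) from ICD-10 diagnosis codes.

The index combines Charlson comorbidity weights — mapped from ICD-10 codes with
the Quan-2005 coding algorithm and the original Charlson weights — with age
points (one point per decade from age 50, capped at four points for age >= 80).
Patients are stratified into a high-risk stratum (CACI > 3) and a low-risk
stratum (CACI <= 3); the stratum is one of the matching criteria used by the
case-control designs in :mod:`haiburden.matching`.

The code-to-category mapping ships as a delimited text resource
(``data/charlson_quan2005.tsv``) so an institution-specific table can be
dropped in without code changes.  Matching is by code prefix, case-insensitive,
and ignores the decimal point (``"C780"`` is equivalent to ``"C78.0"``).
Category hierarchies are applied: metastatic solid tumor supersedes any
malignancy, moderate/severe liver disease supersedes mild liver disease, and
diabetes with chronic complication supersedes uncomplicated diabetes.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import DomainError

__all__ = [
    "CACIResult",
    "caci_score",
    "caci_stratum",
    "score_episodes",
    "load_mapping",
]

HIGH_RISK_THRESHOLD = 3  # stratum is "high" iff score > 3

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


@dataclass(frozen=True)
class CharlsonCategory:
    name: str
    weight: int
    supersedes: tuple[str, ...]
    prefixes: tuple[str, ...]


@dataclass(frozen=True)
class CACIResult:
    score: int
    stratum: str  # "high" | "low"


def load_mapping(path: str | None = None) -> tuple[CharlsonCategory, ...]:
    """Load a Charlson category table from a TSV resource.

    Columns: category, weight, supersedes (pipe-separated, may be empty),
    prefixes (comma-separated normalised ICD-10 prefixes, dots stripped).
    """
    if path is None:
        ref = resources.files("haiburden") / "data" / "charlson_quan2005.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    cats = []
    for row in rows:
        supersedes = tuple(s for s in row.get("supersedes", "").split("|") if s)
        prefixes = tuple(p.strip().upper() for p in row["prefixes"].split(",") if p.strip())
        cats.append(
            CharlsonCategory(row["category"], int(row["weight"]), supersedes, prefixes)
        )
    return tuple(cats)


@lru_cache(maxsize=1)
def _default_tables() -> tuple[Mapping[str, CharlsonCategory], Mapping[str, str]]:
    """(prefix -> category) lookup plus superseded-by relations.

    All shipped prefixes are 3 or 4 characters after dot removal, so category
    assignment is two dictionary probes per code.
    """
    cats = load_mapping()
    prefix_map: dict[str, CharlsonCategory] = {}
    superseded_by: dict[str, str] = {}
    for cat in cats:
        for p in cat.prefixes:
            prefix_map[p] = cat
        for lower in cat.supersedes:
            superseded_by[lower] = cat.name
    return prefix_map, superseded_by


def normalise_code(code: str) -> str:
    return code.strip().upper().replace(".", "")


def _category_of(code: str) -> CharlsonCategory | None:
    prefix_map, _ = _default_tables()
    for cut in (4, 3):
        cat = prefix_map.get(code[:cut])
        if cat is not None:
            return cat
    return None


@lru_cache(maxsize=65536)
def _comorbidity_score(codes_key: frozenset[str] | str) -> int:
    """Charlson weight sum for a normalised code collection (no age points)."""
    if isinstance(codes_key, str):
        codes = [c for c in codes_key.split(";") if c]
    else:
        codes = list(codes_key)
    hit: dict[str, int] = {}
    for raw in codes:
        code = normalise_code(raw)
        if not code:
            continue
        if not _CODE_RE.match(code):
            warnings.warn(f"ignoring unparseable ICD-10 code {raw!r}", stacklevel=3)
            continue
        cat = _category_of(code)
        if cat is not None:
            hit[cat.name] = cat.weight
    _, superseded_by = _default_tables()
    for lower, upper in superseded_by.items():
        if upper in hit and lower in hit:
            del hit[lower]
    return sum(hit.values())


def age_points(age: int) -> int:
    """One point per decade from 50-59, capped at 4 for age >= 80."""
    if age < 0:
        raise DomainError(f"age must be non-negative, got {age}")
    if age < 50:
        return 0
    return min(4, (int(age) - 40) // 10)


def caci_stratum(score: int) -> str:
    """Risk stratum for a CACI score: ``"high"`` iff score > 3, else ``"low"``."""
    if score < 0:
        raise DomainError(f"CACI score must be non-negative, got {score}")
    return "high" if score > HIGH_RISK_THRESHOLD else "low"


def caci_score(age: int, icd10_codes: Iterable[str]) -> CACIResult:
    """Score a patient: Charlson category weights (with hierarchies) + age points.

    Each category counts once regardless of how many codes map to it.
    Unparseable code strings raise a warning and are ignored.
    """
    if age < 0:
        raise DomainError(f"age must be non-negative, got {age}")
    score = _comorbidity_score(frozenset(normalise_code(c) for c in icd10_codes)) + age_points(age)
    return CACIResult(score=score, stratum=caci_stratum(score))


def score_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Append ``caci_score`` and ``caci_stratum`` columns to an episode table.

    Expects ``age`` (integer years) and ``icd10_codes`` (semicolon-joined
    string) columns; returns a copy.
    """
    out = episodes.copy()
    comorb = [
        _comorbidity_score(";".join(sorted(normalise_code(c) for c in str(s).split(";") if c)))
        for s in out["icd10_codes"].fillna("")
    ]
    ages = out["age"].astype(int)
    out["caci_score"] = [c + age_points(a) for c, a in zip(comorb, ages)]
    out["caci_stratum"] = [caci_stratum(s) for s in out["caci_score"]]
    return out
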