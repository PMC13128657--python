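"""Gaussian GLM of DIP payment differentials with robust standard errors.

On the risk-set-matched sample, the DIP payment differential (standard
payment minus actual cost) is regressed on patient and infection covariates
with a Gaussian family and identity link — so the point estimates are
ordinary least squares — while the covariance is the heteroskedasticity-
consistent HC1 sandwich, appropriate for the heavily skewed cost residuals.
Confidence intervals are ``B +/- z_{0.025} * robust SE`` and p-values use the
normal reference (a t reference is available behind a flag).

Covariates and reference levels: sex (male), payment type (non-DIP), age
(continuous), CACI stratum (<=3), invasive device (no), surgery (no), wound
classification (no surgery as reference; dummies 0/I/II/III), HAI (no),
catheter-associated infection (no), number of distinct MDRO types (0;
dummies 1/2/3+).  The matched-pair structure is deliberately not modelled
with a random effect; the model is a plain GLM on the matched sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, RankDeficiencyError
from .matching import MatchedCohort
from .settlement import add_differential_column

__all__ = ["GLMTerm", "GLMFit", "DesignSpec", "build_design", "fit_glm", "glm_table"]

WOUND_ORDER = ("0", "I", "II", "III")
MDRO_ORDER = ("1", "2", "3+")


@dataclass(frozen=True)
class GLMTerm:
    name: str
    b: float
    robust_se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class GLMFit:
    terms: tuple[GLMTerm, ...]
    n_obs: int
    family: str = "gaussian"
    link: str = "identity"
    cov_type: str = "HC1"

    def term(self, name: str) -> GLMTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class DesignSpec:
    outcome: pd.Series
    matrix: pd.DataFrame
    dropped_levels: tuple[str, ...]


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DomainError(f"{what} table lacks columns {missing}")


def build_design(
    episodes: pd.DataFrame,
    profiles: pd.DataFrame,
    matched_cohort: MatchedCohort | None = None,
    currency_rate: float | None = None,
) -> DesignSpec:
    """Assemble outcome and reference-coded design matrix.

    ``episodes`` must carry CACI columns; ``profiles`` the infection profile.
    When a matched cohort is given, only its cases and controls enter (each
    episode once).  ``currency_rate`` divides the outcome (CNY per USD) so
    coefficients are reported in the analysis currency.  Covariate levels
    absent from the data are dropped with a warning.
    """
    _require(episodes, ("episode_id", "sex", "age", "payment_type", "caci_stratum",
                        "invasive_device_flag", "surgery_flag", "wound_class",
                        "dip_standard_payment_cny", "hospitalization_cost_cny"), "episodes")
    _require(profiles, ("episode_id", "frequency", "catheter_associated", "mdro_type_count"),
             "profiles")
    df = add_differential_column(episodes).merge(profiles, on="episode_id", how="left")
    df["frequency"] = df["frequency"].fillna("0")
    df["mdro_type_count"] = df["mdro_type_count"].fillna("0")
    df["catheter_associated"] = df["catheter_associated"].fillna(False)
    if matched_cohort is not None:
        keep = set(matched_cohort.case_ids) | set(matched_cohort.control_ids)
        df = df[df["episode_id"].isin(keep)].reset_index(drop=True)
    if df.empty:
        raise DomainError("no episodes selected for the design")

    y = df["dip_differential_cny"].astype(float)
    if currency_rate is not None:
        if currency_rate <= 0:
            raise DomainError("currency_rate must be > 0")
        y = y / currency_rate
    y = y.rename("dip_differential")
    if float(np.ptp(y.to_numpy())) == 0.0:
        raise DomainError("outcome is constant; the model is not estimable")

    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["sex_female"] = (df["sex"] == "female").astype(float)
    X["payment_dip"] = (df["payment_type"] == "DIP").astype(float)
    X["age"] = df["age"].astype(float)
    X["caci_high"] = (df["caci_stratum"] == "high").astype(float)
    X["device_yes"] = df["invasive_device_flag"].astype(float)
    X["surgery_yes"] = df["surgery_flag"].astype(float)
    for w in WOUND_ORDER:
        X[f"wound_{w}"] = (df["wound_class"] == w).astype(float)
    X["hai_yes"] = (df["frequency"] != "0").astype(float)
    X["catheter_yes"] = df["catheter_associated"].astype(bool).astype(float)
    for m in MDRO_ORDER:
        X[f"mdro_{m}"] = (df["mdro_type_count"] == m).astype(float)

    dropped = [c for c in X.columns if c != "intercept" and X[c].nunique() == 1]
    if dropped:
        warnings.warn(f"dropping empty design levels: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    return DesignSpec(outcome=y, matrix=X, dropped_levels=tuple(dropped))


def fit_glm(outcome, design, *, use_t: bool = False, level: float = 0.95) -> GLMFit:
    """Fit the Gaussian identity-link GLM with HC1 sandwich covariance.

    ``design`` may be a :class:`DesignSpec` (in which case ``outcome`` is
    ignored if None) or a design matrix aligned with ``outcome``.
    """
    import statsmodels.api as sm

    if isinstance(design, DesignSpec):
        X = design.matrix
        y = design.outcome if outcome is None else pd.Series(np.asarray(outcome, float))
    else:
        X = pd.DataFrame(design)
        y = pd.Series(np.asarray(outcome, float))
    Xv = X.to_numpy(float)
    yv = np.asarray(y, float)
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise DomainError("design or outcome contains missing values")
    if len(yv) <= Xv.shape[1]:
        raise DomainError(
            f"need more observations ({len(yv)}) than design columns ({Xv.shape[1]})"
        )
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name the columns involved in the collinearity via the null space
        _, s, vt = np.linalg.svd(Xv, full_matrices=False)
        null_mask = np.abs(vt[-1]) > 1e-8
        cols = list(np.asarray(X.columns)[null_mask])
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear terms: {cols}")
    model = sm.GLM(yv, Xv, family=sm.families.Gaussian())
    res = model.fit(cov_type="HC1", use_t=use_t)
    q = (
        stats.t.ppf(0.5 + level / 2.0, res.df_resid)
        if use_t
        else stats.norm.ppf(0.5 + level / 2.0)
    )
    terms = []
    for name, b, se, p in zip(X.columns, res.params, res.bse, res.pvalues):
        terms.append(
            GLMTerm(
                name=name,
                b=float(b),
                robust_se=float(se),
                ci_low=float(b - q * se),
                ci_high=float(b + q * se),
                p_value=float(p),
            )
        )
    return GLMFit(terms=tuple(terms), n_obs=int(len(yv)))


def glm_table(fit: GLMFit, ndigits: int = 2) -> pd.DataFrame:
    """Table-shaped view: variable, B, robust SE, 95% CI, p-value."""
    return pd.DataFrame(
        {
            "variable": [t.name for t in fit.terms],
            "B": [round(t.b, ndigits) for t in fit.terms],
            "robust_se": [round(t.robust_se, ndigits) for t in fit.terms],
            "ci_low": [round(t.ci_low, ndigits) for t in fit.terms],
            "ci_high": [round(t.ci_high, ndigits) for t in fit.terms],
            "p_value": [t.p_value for t in fit.terms],
        }
    )
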