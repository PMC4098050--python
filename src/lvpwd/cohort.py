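"""Synthetic clinical cohorts emulating the echocardiographic study populations.

No individual-level clinical data are public, so downstream statistics are
exercised on synthetic cohorts whose per-sex demographic structure (sample
size, age and BSA mean/SD/range) follows the published summary tables for the
Polish and UHZ data sets, and whose LVPWd is drawn from a chosen published
coefficient set at each subject's own covariates.

Ages and BSAs follow truncated normal laws whose parent parameters are
moment-matched so the *truncated* distribution reproduces the target mean and
SD inside the stated range.  Height is drawn per sex and weight back-solved
through the DuBois body-surface-area formula, so the record is internally
consistent; the joint (age, BSA) law is independent by assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import published
from .betareg import RESPONSE_COLUMN

__all__ = [
    "DemographicStats",
    "SexRecipe",
    "CohortRecipe",
    "RecipeError",
    "bsa_dubois",
    "weight_from_bsa",
    "generate_cohort",
    "apply_inclusion_criteria",
    "to_design",
    "read_cohort_csv",
    "write_cohort_csv",
]

COHORT_COLUMNS = ["subject_id", "age_years", "sex", "height_m", "weight_kg",
                  "bsa_m2", "bmi", "lvpwd_mm"]

DUBOIS_COEF, DUBOIS_H_EXP, DUBOIS_W_EXP = 0.20247, 0.725, 0.425


class RecipeError(ValueError):
    """Infeasible cohort recipe."""


def bsa_dubois(height_m, weight_kg):
    """DuBois body surface area, 0.20247 * height(m)^0.725 * weight(kg)^0.425."""
    h = np.asarray(height_m, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise ValueError("height and weight must be positive")
    out = DUBOIS_COEF * h ** DUBOIS_H_EXP * w ** DUBOIS_W_EXP
    return float(out) if out.ndim == 0 else out


def weight_from_bsa(bsa_m2, height_m):
    """Invert the DuBois formula for weight at a given height."""
    b = np.asarray(bsa_m2, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(b <= 0) or np.any(h <= 0):
        raise ValueError("BSA and height must be positive")
    out = (b / (DUBOIS_COEF * h ** DUBOIS_H_EXP)) ** (1.0 / DUBOIS_W_EXP)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DemographicStats:
    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise RecipeError(
                f"range [{self.low}, {self.high}] does not contain mean {self.mean}")
        if self.sd <= 0:
            raise RecipeError("sd must be positive")


@dataclass(frozen=True)
class SexRecipe:
    n: int
    age: DemographicStats
    bsa: DemographicStats
    height_mean_m: float
    height_sd_m: float = 0.07

    def __post_init__(self) -> None:
        if self.n < 0:
            raise RecipeError("count must be non-negative")


@dataclass(frozen=True)
class CohortRecipe:
    """Per-sex demographic targets plus the generating LVPWd model."""

    male: SexRecipe
    female: SexRecipe
    lvpwd_model: published.CoefficientSet
    seed: int | None = None
    dataset: str = "custom"

    @classmethod
    def default(cls, dataset: str = "polish", seed: int | None = None,
                lvpwd_predictors: str = "age_sex") -> "CohortRecipe":
        """Recipe with the published per-sex demographic summaries."""
        if dataset == "polish":
            male = SexRecipe(189, DemographicStats(36.6, 13.6, 18.0, 75.0),
                             DemographicStats(2.00, 0.16, 1.53, 2.44), 1.78)
            female = SexRecipe(128, DemographicStats(42.3, 14.1, 18.0, 71.0),
                               DemographicStats(1.69, 0.13, 1.44, 2.04), 1.65)
        elif dataset == "uhz":
            male = SexRecipe(2104, DemographicStats(42.1, 13.2, 18.0, 79.8),
                             DemographicStats(1.95, 0.17, 1.34, 2.73), 1.78)
            female = SexRecipe(2368, DemographicStats(42.9, 13.1, 18.0, 78.4),
                               DemographicStats(1.69, 0.15, 1.28, 2.34), 1.65)
        else:
            raise RecipeError(f"unknown dataset {dataset!r}; use 'polish' or 'uhz'")
        model = published.get_coefficient_set(dataset, lvpwd_predictors)
        return cls(male=male, female=female, lvpwd_model=model,
                   seed=seed, dataset=dataset)

    def with_counts(self, n_male: int, n_female: int) -> "CohortRecipe":
        return replace(self, male=replace(self.male, n=n_male),
                       female=replace(self.female, n=n_female))


def _matched_truncnorm(target: DemographicStats) -> stats._distn_infrastructure.rv_frozen:
    """Truncated normal whose truncated mean/SD equal the target values.

    Solves for the parent (m, s); falls back to the naive parameterization if
    the moment equations have no solution inside the range.
    """
    lo, hi, m_t, s_t = target.low, target.high, target.mean, target.sd

    def moments(x):
        m, log_s = x
        s = np.exp(log_s)
        a, b = (lo - m) / s, (hi - m) / s
        mean, var = stats.truncnorm.stats(a, b, loc=m, scale=s, moments="mv")
        return [mean - m_t, np.sqrt(var) - s_t]

    sol = optimize.root(moments, [m_t, np.log(s_t)], method="hybr")
    if sol.success:
        m, s = sol.x[0], float(np.exp(sol.x[1]))
    else:
        m, s = m_t, s_t
    a, b = (lo - m) / s, (hi - m) / s
    return stats.truncnorm(a, b, loc=m, scale=s)


def _generate_sex(recipe: SexRecipe, sex: str, model: published.CoefficientSet,
                  rng: np.random.Generator, id_offset: int) -> pd.DataFrame:
    n = recipe.n
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    age = _matched_truncnorm(recipe.age).rvs(size=n, random_state=rng)
    bsa = _matched_truncnorm(recipe.bsa).rvs(size=n, random_state=rng)

    # draw height, solve weight from BSA; redraw heights until BMI lands in
    # the physiological window (BMI is not modelled directly)
    height = rng.normal(recipe.height_mean_m, recipe.height_sd_m, size=n)
    for _ in range(200):
        height = np.clip(height, 1.30, 2.20)
        weight = weight_from_bsa(bsa, height)
        bmi = weight / height ** 2
        bad = (bmi < 16.0) | (bmi > 35.0)
        if not np.any(bad):
            break
        height[bad] = rng.normal(recipe.height_mean_m, recipe.height_sd_m,
                                 size=int(bad.sum()))
    else:
        raise RecipeError("could not realize BMI in [16, 35] for the given BSA range")

    sex_num = 1.0 if sex == "M" else 0.0
    cov = {"age": age, "sex": np.full(n, sex_num), "bsa": bsa}
    needed = {p for t in list(model.beta) + list(model.gamma) for p in t.split(":")
              if t != "intercept"}
    lvpwd = published.sample_lvpwd(model, {k: cov[k] for k in needed},
                                   n=n, seed=rng)
    return pd.DataFrame({
        "subject_id": [f"{sex}{i + id_offset:05d}" for i in range(n)],
        "age_years": age, "sex": sex, "height_m": height, "weight_kg": weight,
        "bsa_m2": bsa, "bmi": bmi, "lvpwd_mm": lvpwd,
    })


def generate_cohort(recipe: CohortRecipe) -> pd.DataFrame:
    """Generate a synthetic cohort that passes the inclusion criteria.

    Reproducible from ``recipe.seed``; LVPWd values come from the recipe's
    generating coefficient set evaluated at each subject's own covariates.
    """
    rng = np.random.default_rng(recipe.seed)
    parts = [_generate_sex(recipe.male, "M", recipe.lvpwd_model, rng, 0),
             _generate_sex(recipe.female, "F", recipe.lvpwd_model, rng, 0)]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def apply_inclusion_criteria(raw: pd.DataFrame, *, strict_interior: bool = False
                             ) -> tuple[pd.DataFrame, list[tuple]]:
    """Screen a cohort against the clinical inclusion criteria.

    Keeps subjects with LVPWd in the physiological 6-11 mm range, age >= 18
    and BMI in [16, 35]; each rejection is labelled with the first failed
    criterion in that order.  ``strict_interior=True`` additionally excludes
    values exactly on 6 or 11 mm, which carry no probability mass under the
    bounded beta law and cannot enter a fit.
    """
    rejected: list[tuple] = []
    keep = np.ones(len(raw), dtype=bool)
    lo_ok = raw["lvpwd_mm"] > 6.0 if strict_interior else raw["lvpwd_mm"] >= 6.0
    hi_ok = raw["lvpwd_mm"] < 11.0 if strict_interior else raw["lvpwd_mm"] <= 11.0
    checks = [
        (~(lo_ok & hi_ok), "LVPWd out of range"),
        (raw["age_years"] < 18.0, "age<18"),
        ((raw["bmi"] < 16.0) | (raw["bmi"] > 35.0), "BMI out of range"),
    ]
    for i in range(len(raw)):
        for mask, reason in checks:
            if bool(mask.iloc[i]):
                keep[i] = False
                rejected.append((raw["subject_id"].iloc[i], reason))
                break
    return raw.loc[keep].reset_index(drop=True), rejected


def to_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric design frame for the regression core (sex coded 1 = male)."""
    return pd.DataFrame({
        "age": cohort["age_years"].to_numpy(dtype=float),
        "sex": (cohort["sex"] == "M").to_numpy(dtype=float),
        "bsa": cohort["bsa_m2"].to_numpy(dtype=float),
        RESPONSE_COLUMN: cohort["lvpwd_mm"].to_numpy(dtype=float),
    })


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
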