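"""Published LVPWd population models and the bounded random sampler.

Four variable-dispersion beta-regression coefficient sets describe the
diastolic LV posterior wall thickness (bounded on (6, 11) mm) of healthy
adults, fitted separately on a Polish multicenter cohort and on the
University Hospital Zurich (UHZ) cohort, each with either {age, sex} or
{BSA, sex} predictors.  Two legacy linear models (Sjögren's age-sex
equations and Henry's BSA/weight equations) are kept for comparison; unlike
the beta-regression models they are not bounded and can predict outside the
physiological range.

Conditional percentiles invert the regularized incomplete beta function;
random LVPWd values are drawn by inverse-CDF sampling so a sequence is fully
reproducible from its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .betareg import DEFAULT_BOUNDS, ModelSpec, linear_predictors, scale_to_mm

__all__ = [
    "CoefficientSet",
    "LegacyModel",
    "COEFFICIENT_SETS",
    "LEGACY_MODELS",
    "get_coefficient_set",
    "conditional_percentile",
    "sample_lvpwd",
    "legacy_mean",
    "ExtrapolationWarning",
]


class ExtrapolationWarning(UserWarning):
    """Covariates outside the observed clinical ranges."""


# observed covariate ranges of the pooled clinical cohorts, used only to warn
OBSERVED_RANGES = {"age": (18.0, 80.0), "bsa": (1.28, 2.73)}


@dataclass(frozen=True)
class CoefficientSet:
    """One published fitted model: named coefficient values on (6, 11) mm."""

    dataset: str                  # "polish" | "uhz"
    predictors: str               # "age_sex" | "bsa_sex"
    beta: dict[str, float]        # mean submodel (logit link)
    gamma: dict[str, float]       # precision submodel (log link)
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    source: str = ""

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(mean_terms=tuple(self.beta),
                         precision_terms=tuple(self.gamma),
                         bounds=self.bounds,
                         allow_orphan_interactions=True)

    @property
    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array(list(self.beta.values())),
                np.array(list(self.gamma.values())))

    def mu_phi(self, covariates) -> tuple[float, float]:
        _warn_extrapolation(covariates)
        return linear_predictors(self.spec, self.coefficients, covariates)


_SRC = "healthy-adult echocardiographic LVPWd study, multicenter PL / UHZ data"

COEFFICIENT_SETS: dict[tuple[str, str], CoefficientSet] = {
    ("polish", "age_sex"): CoefficientSet(
        dataset="polish", predictors="age_sex",
        beta={"intercept": -1.428, "age": 0.034, "sex": 2.169, "age:sex": -0.029},
        gamma={"intercept": 2.696, "age": -0.030, "sex": -1.382, "age:sex": 0.032},
        source=_SRC),
    ("uhz", "age_sex"): CoefficientSet(
        dataset="uhz", predictors="age_sex",
        beta={"intercept": -1.176, "age": 0.013, "sex": 0.851},
        gamma={"intercept": 1.432},
        source=_SRC),
    ("polish", "bsa_sex"): CoefficientSet(
        dataset="polish", predictors="bsa_sex",
        beta={"intercept": -3.372, "bsa": 2.128},
        gamma={"intercept": -0.218, "bsa": 0.824},
        source=_SRC),
    ("uhz", "bsa_sex"): CoefficientSet(
        dataset="uhz", predictors="bsa_sex",
        beta={"intercept": -3.201, "bsa": 1.534, "sex": 0.452},
        gamma={"intercept": 1.469},
        source=_SRC),
}


def get_coefficient_set(dataset: str, predictors: str) -> CoefficientSet:
    """Look up a published coefficient set by (dataset, predictor-set) tag."""
    try:
        return COEFFICIENT_SETS[(dataset, predictors)]
    except KeyError:
        valid = ", ".join(f"({d}, {p})" for d, p in COEFFICIENT_SETS)
        raise KeyError(
            f"unknown model ({dataset}, {predictors}); valid pairs: {valid}"
        ) from None


def _warn_extrapolation(covariates) -> None:
    cov = dict(covariates)
    for name, (lo, hi) in OBSERVED_RANGES.items():
        if name in cov:
            v = np.atleast_1d(np.asarray(cov[name], dtype=float))
            if np.any((v < lo) | (v > hi)):
                warnings.warn(
                    f"{name} outside the observed clinical range [{lo}, {hi}]; "
                    "model predictions are extrapolations",
                    ExtrapolationWarning, stacklevel=3)


def conditional_percentile(coefs: CoefficientSet, covariates, p) -> float | np.ndarray:
    """Conditional LVPWd percentile in mm at probability ``p``.

    Evaluates (mu, phi) at the covariates, inverts the beta CDF with shapes
    (mu*phi, (1-mu)*phi) and maps back to the mm scale.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("percentile probability must lie strictly in (0, 1)")
    mu, phi = coefs.mu_phi(covariates)
    q = stats.beta.ppf(p, mu * np.asarray(phi), (1.0 - np.asarray(mu)) * np.asarray(phi))
    out = scale_to_mm(q, coefs.bounds)
    return float(out) if out.ndim == 0 else out


def sample_lvpwd(coefs: CoefficientSet, covariates, n: int = 1,
                 seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. LVPWd values (mm) from the conditional bounded beta law.

    Inverse-CDF sampling: uniform draws pushed through the beta quantile
    function, so every value is strictly inside the bounds and the sequence is
    reproducible from the seed.  Covariates may be scalars (one law) or
    length-``n`` arrays (one law per draw).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    mu, phi = coefs.mu_phi(covariates)
    mu, phi = np.broadcast_to(mu, (n,)), np.broadcast_to(phi, (n,))
    q = stats.beta.ppf(u, mu * phi, (1.0 - mu) * phi)
    return scale_to_mm(q, coefs.bounds)


# ---------------------------------------------------------------------------
# legacy mean-only models


@dataclass(frozen=True)
class LegacyModel:
    """Pre-existing linear/power mean models of LV wall thickness (mm).

    Not bounded to the physiological (6, 11) mm interval.
    """

    name: str
    required: tuple[str, ...]
    terms: dict = field(default_factory=dict)

    def evaluate(self, covariates: dict) -> float:
        cov = {k: float(v) for k, v in dict(covariates).items()}
        for r in self.required:
            if r not in cov:
                raise ValueError(f"legacy model {self.name!r} requires covariate {r!r}")
            if cov[r] < 0:
                raise ValueError(f"negative {r!r} is outside the model domain")
        t = self.terms
        out = t["intercept"]
        for var, (slope, power) in t["powers"].items():
            out += slope * cov[var] ** power
        return out


LEGACY_MODELS: dict[str, LegacyModel] = {
    "sjogren_male": LegacyModel(
        "sjogren_male", ("age",),
        {"intercept": 5.95, "powers": {"age": (0.055, 1.0)}}),
    "sjogren_female": LegacyModel(
        "sjogren_female", ("age",),
        {"intercept": 3.83, "powers": {"age": (0.096, 1.0)}}),
    "henry_bsa": LegacyModel(
        "henry_bsa", ("age", "bsa"),
        {"intercept": 1.1, "powers": {"bsa": (5.56, 0.5), "age": (0.03, 1.0)}}),
    "henry_weight": LegacyModel(
        "henry_weight", ("age", "weight"),
        {"intercept": 1.1, "powers": {"weight": (1.92, 0.32), "age": (0.03, 1.0)}}),
}


def legacy_mean(model: str | LegacyModel, covariates: dict) -> float:
    """Deterministic mean LVPWd (mm) from a legacy regression equation."""
    if isinstance(model, str):
        try:
            model = LEGACY_MODELS[model]
        except KeyError:
            raise KeyError(
                f"unknown legacy model {model!r}; valid: {sorted(LEGACY_MODELS)}"
            ) from None
    return model.evaluate(covariates)
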