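"""Variable-dispersion beta regression for responses bounded on a known interval.

The response (here: diastolic LV posterior wall thickness, LVPWd, bounded on
(6, 11) mm) is mapped to the unit interval and modelled with the
mean/precision parameterization of the beta law,

    f(y; mu, phi) = Gamma(phi) / (Gamma(mu*phi) * Gamma((1-mu)*phi))
                    * y**(mu*phi - 1) * (1 - y)**((1-mu)*phi - 1),

with mean ``mu`` in (0, 1) and precision ``phi > 0``; the implied variance is
``mu*(1-mu)/(1+phi)``.  Both parameters carry their own linear predictor:
a logit link for the mean and a log link for the precision, so the dispersion
may vary with covariates (the "variable dispersion" model of Simas et al.,
extending Ferrari & Cribari-Neto's beta regression).

Estimation is plain maximum likelihood by quasi-Newton iteration from a
deterministic start; model reduction uses backward elimination guided by
likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "BoundedBetaParams",
    "ModelSpec",
    "FittedModel",
    "LRTResult",
    "SelectionResult",
    "Diagnostics",
    "scale_to_unit",
    "scale_to_mm",
    "beta_density",
    "beta_logpdf",
    "design_matrix",
    "linear_predictors",
    "log_likelihood",
    "fit_model",
    "likelihood_ratio_test",
    "backward_select",
    "pseudo_r2",
    "diagnostics",
]

DEFAULT_BOUNDS = (6.0, 11.0)

_ETA_CLIP = 30.0  # linear predictors beyond this are saturated anyway


class BoundaryError(ValueError):
    """A response value lies on or outside the support bounds."""


class SpecificationError(ValueError):
    """Model specification and data/coefficients are inconsistent."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BoundedBetaParams:
    """Mean/precision parameterization of a beta law on a bounded mm scale."""

    mu: float
    phi: float
    lower_mm: float = DEFAULT_BOUNDS[0]
    upper_mm: float = DEFAULT_BOUNDS[1]

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if not self.phi > 0.0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if not self.upper_mm > self.lower_mm:
            raise ValueError("upper_mm must exceed lower_mm")

    @property
    def shape1(self) -> float:
        return self.mu * self.phi

    @property
    def shape2(self) -> float:
        return (1.0 - self.mu) * self.phi

    @property
    def variance(self) -> float:
        """Variance of the unit-scale law."""
        return self.mu * (1.0 - self.mu) / (1.0 + self.phi)


def _parents(term: str) -> tuple[str, ...]:
    return tuple(term.split(":")) if ":" in term else ()


@dataclass(frozen=True)
class ModelSpec:
    """Covariate terms of the mean and precision submodels.

    Terms are covariate names (``"age"``, ``"sex"``, ``"bsa"``), the literal
    ``"intercept"``, or colon-joined pairwise interactions (``"age:sex"``).
    Sex is coded 1 = male.
    """

    mean_terms: tuple[str, ...]
    precision_terms: tuple[str, ...] = ("intercept",)
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    allow_orphan_interactions: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_terms", tuple(self.mean_terms))
        object.__setattr__(self, "precision_terms", tuple(self.precision_terms))
        for name, terms in (("mean", self.mean_terms), ("precision", self.precision_terms)):
            if "intercept" not in terms:
                raise SpecificationError(f"{name} submodel must include an intercept")
            if len(set(terms)) != len(terms):
                raise SpecificationError(f"duplicate terms in {name} submodel: {terms}")
            if not self.allow_orphan_interactions:
                for t in terms:
                    for p in _parents(t):
                        if p not in terms:
                            raise SpecificationError(
                                f"interaction {t!r} in {name} submodel requires parent {p!r}"
                            )

    @property
    def n_coef(self) -> int:
        return len(self.mean_terms) + len(self.precision_terms)

    def drop(self, submodel: str, term: str) -> "ModelSpec":
        """Return a new spec without ``term`` in the given submodel."""
        mean, prec = list(self.mean_terms), list(self.precision_terms)
        target = mean if submodel == "mean" else prec
        if term not in target:
            raise SpecificationError(f"{term!r} not in {submodel} submodel")
        target.remove(term)
        return ModelSpec(tuple(mean), tuple(prec), self.bounds,
                         self.allow_orphan_interactions)


@dataclass
class FittedModel:
    spec: ModelSpec
    beta: np.ndarray
    gamma: np.ndarray
    vcov: np.ndarray
    loglik: float
    pseudo_r2: float
    n_obs: int
    converged: bool
    message: str = ""
    grad_norm: float = np.nan

    def __post_init__(self) -> None:
        if len(self.beta) != len(self.spec.mean_terms):
            raise SpecificationError("beta length does not match mean terms")
        if len(self.gamma) != len(self.spec.precision_terms):
            raise SpecificationError("gamma length does not match precision terms")

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma])

    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def coefficient_table(self) -> pd.DataFrame:
        """Tidy coefficient table (submodel, predictor, estimate, CI, p)."""
        se = self.std_errors()
        est = self.params
        z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        sub = (["mean"] * len(self.spec.mean_terms)
               + ["precision"] * len(self.spec.precision_terms))
        pred = list(self.spec.mean_terms) + list(self.spec.precision_terms)
        return pd.DataFrame({
            "submodel": sub, "predictor": pred, "estimate": est,
            "ci_low": est - 1.959964 * se, "ci_high": est + 1.959964 * se,
            "p_value": p,
        })


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class SelectionResult:
    fit: FittedModel
    trace: list[dict] = field(default_factory=list)


@dataclass
class Diagnostics:
    residuals: np.ndarray        # standardized (Pearson) residuals
    cooks_distance: np.ndarray
    leverage: np.ndarray         # generalized leverage dmu_hat/dy
    fitted_mu: np.ndarray        # unit scale
    predicted_mm: np.ndarray


# ---------------------------------------------------------------------------
# scaling and density


def scale_to_unit(value_mm, bounds: tuple[float, float] = DEFAULT_BOUNDS):
    """Map a bounded measurement to the open unit interval, (y-a)/(b-a)."""
    a, b = bounds
    v = np.asarray(value_mm, dtype=float)
    if np.any(v <= a) or np.any(v >= b):
        bad = v[(v <= a) | (v >= b)]
        raise BoundaryError(
            f"values {np.atleast_1d(bad).tolist()} lie on or outside bounds ({a}, {b}); "
            "the beta law has no mass at the endpoints"
        )
    out = (v - a) / (b - a)
    return float(out) if np.isscalar(value_mm) else out


def scale_to_mm(y_unit, bounds: tuple[float, float] = DEFAULT_BOUNDS):
    """Inverse of :func:`scale_to_unit`."""
    a, b = bounds
    return a + (b - a) * np.asarray(y_unit, dtype=float)


def beta_logpdf(y_unit, mu, phi):
    """Log density of the mean/precision beta law at unit-scale values."""
    y = np.asarray(y_unit, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise BoundaryError("unit-scale response must lie strictly in (0, 1)")
    if np.any((mu <= 0.0) | (mu >= 1.0)) or np.any(phi <= 0.0):
        raise ValueError("require 0 < mu < 1 and phi > 0")
    return stats.beta.logpdf(y, mu * phi, (1.0 - mu) * phi)


def beta_density(y_unit, params: BoundedBetaParams):
    """Density of the reparameterized beta law on the unit scale.

    The normalizing constant is Gamma(phi) / (Gamma(mu*phi) * Gamma((1-mu)*phi)).
    """
    return np.exp(beta_logpdf(y_unit, params.mu, params.phi))


# ---------------------------------------------------------------------------
# linear predictors and likelihood


def design_matrix(terms: tuple[str, ...], covariates, n: int | None = None) -> np.ndarray:
    """Build an n x len(terms) design matrix from named covariates.

    ``covariates`` is a mapping or DataFrame of numeric arrays/scalars keyed by
    base covariate name; ``n`` overrides the row count (needed when every term
    is the intercept).
    """
    if isinstance(covariates, pd.DataFrame):
        cov = {c: covariates[c].to_numpy(dtype=float) for c in covariates.columns}
    else:
        cov = {k: np.asarray(v, dtype=float) for k, v in dict(covariates).items()}
    if n is None:
        n = 1
        for v in cov.values():
            n = max(n, np.size(v))

    def column(term: str) -> np.ndarray:
        if term == "intercept":
            return np.ones(n)
        cols = []
        for p in _parents(term) or (term,):
            if p not in cov:
                raise SpecificationError(f"covariate {p!r} required by term {term!r} is missing")
            cols.append(np.broadcast_to(cov[p], (n,)))
        return np.prod(cols, axis=0)

    return np.column_stack([column(t) for t in terms])


def linear_predictors(spec: ModelSpec, coefficients, covariates):
    """Evaluate (mu, phi) through the logit and log links.

    ``coefficients`` is a pair ``(beta, gamma)`` ordered as the spec's terms.
    Returns scalars for scalar covariates, arrays otherwise.
    """
    beta, gamma = (np.asarray(c, dtype=float) for c in coefficients)
    X = design_matrix(spec.mean_terms, covariates)
    Z = design_matrix(spec.precision_terms, covariates)
    if X.shape[1] != beta.size:
        raise SpecificationError("beta length does not match mean terms")
    if Z.shape[1] != gamma.size:
        raise SpecificationError("gamma length does not match precision terms")
    eta1 = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    eta2 = np.clip(Z @ gamma, -_ETA_CLIP, _ETA_CLIP)
    mu = special.expit(eta1)
    phi = np.exp(eta2)
    if mu.size == 1:
        return float(mu[0]), float(phi[0])
    return mu, phi


RESPONSE_COLUMN = "lvpwd_mm"


def _extract(spec: ModelSpec, data: pd.DataFrame):
    if len(data) == 0:
        raise ValueError("empty data")
    y = scale_to_unit(data[RESPONSE_COLUMN].to_numpy(dtype=float), spec.bounds)
    cov = data.drop(columns=[RESPONSE_COLUMN])
    X = design_matrix(spec.mean_terms, cov, n=len(data))
    Z = design_matrix(spec.precision_terms, cov, n=len(data))
    return y, X, Z


def _loglik_terms(y, X, Z, beta, gamma):
    eta1 = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    eta2 = np.clip(Z @ gamma, -_ETA_CLIP, _ETA_CLIP)
    mu = special.expit(eta1)
    phi = np.exp(eta2)
    a, b = mu * phi, (1.0 - mu) * phi
    ll = (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
          + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    return ll, mu, phi


def log_likelihood(spec: ModelSpec, coefficients, data: pd.DataFrame) -> float:
    """Sum of per-observation log beta densities at the covariate-specific (mu, phi)."""
    beta, gamma = (np.asarray(c, dtype=float) for c in coefficients)
    y, X, Z = _extract(spec, data)
    ll, _, _ = _loglik_terms(y, X, Z, beta, gamma)
    return float(np.sum(ll))


def _negloglik_and_grad(theta, y, X, Z):
    k = X.shape[1]
    beta, gamma = theta[:k], theta[k:]
    ll, mu, phi = _loglik_terms(y, X, Z, beta, gamma)
    ystar = np.log(y) - np.log1p(-y)          # logit(y)
    mustar = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
    dll_dmu = phi * (ystar - mustar)
    dll_dphi = (special.digamma(phi)
                - mu * special.digamma(mu * phi)
                - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
                + mu * np.log(y) + (1.0 - mu) * np.log1p(-y))
    gbeta = X.T @ (dll_dmu * mu * (1.0 - mu))
    ggamma = Z.T @ (dll_dphi * phi)
    return -float(np.sum(ll)), -np.concatenate([gbeta, ggamma])


def _observed_information(theta, y, X, Z, step: float = 1e-5) -> np.ndarray:
    """Observed information as the symmetrized Jacobian of the analytic gradient."""
    m = theta.size
    H = np.empty((m, m))
    for j in range(m):
        h = step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _negloglik_and_grad(tp, y, X, Z)
        _, gm = _negloglik_and_grad(tm, y, X, Z)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _start_values(y, X, Z):
    """Deterministic start: least squares on logit(y) for the mean submodel,
    method-of-moments precision intercept, remaining gamma at zero."""
    ystar = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(X, ystar, rcond=None)
    mu0 = special.expit(np.clip(X @ beta0, -_ETA_CLIP, _ETA_CLIP))
    resid_var = float(np.var(y - mu0)) or 1e-4
    phi0 = max(float(np.mean(mu0 * (1.0 - mu0))) / resid_var - 1.0, 0.1)
    gamma0 = np.zeros(Z.shape[1])
    gamma0[0] = np.log(phi0)  # caller relocates this onto the intercept column
    return np.concatenate([beta0, gamma0])


def fit_model(spec: ModelSpec, data: pd.DataFrame, *, gtol: float = 1e-6,
              maxiter: int = 500, compute_vcov: bool = True) -> FittedModel:
    """Maximum-likelihood fit of the variable-dispersion beta regression."""
    y, X, Z = _extract(spec, data)
    n = y.size
    if n <= spec.n_coef:
        raise ValueError(
            f"n_obs={n} must exceed the number of coefficients ({spec.n_coef})")
    theta0 = _start_values(y, X, Z)
    # intercept column may not be first; put the MoM phi on the true intercept
    zi = spec.precision_terms.index("intercept")
    g0 = np.zeros(Z.shape[1])
    g0[zi] = theta0[X.shape[1]]
    theta0[X.shape[1]:] = g0

    res = optimize.minimize(
        _negloglik_and_grad, theta0, args=(y, X, Z), jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter})
    theta = res.x
    _, g = _negloglik_and_grad(theta, y, X, Z)
    gnorm = float(np.max(np.abs(g)))
    converged = bool(gnorm < max(gtol, 1e-4 * (1.0 + abs(res.fun))) and np.isfinite(res.fun))
    message = res.message
    k = X.shape[1]
    beta, gamma = theta[:k], theta[k:]
    phi_max = float(np.max(np.exp(np.clip(Z @ gamma, -_ETA_CLIP, _ETA_CLIP))))
    if phi_max > 1e8:
        converged = False
        message = f"degenerate fit: precision diverged (max phi {phi_max:.3g})"

    if compute_vcov and converged:
        info = _observed_information(theta, y, X, Z)
        try:
            vcov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            vcov = np.full((theta.size, theta.size), np.nan)
            converged = False
            message = "singular observed information"
    else:
        vcov = np.full((theta.size, theta.size), np.nan)

    fit = FittedModel(spec=spec, beta=beta, gamma=gamma, vcov=vcov,
                      loglik=-float(res.fun), pseudo_r2=np.nan, n_obs=n,
                      converged=converged, message=message, grad_norm=gnorm)
    fit.pseudo_r2 = pseudo_r2(fit, data)
    return fit


# ---------------------------------------------------------------------------
# inference and selection


def likelihood_ratio_test(nested: FittedModel, full: FittedModel) -> LRTResult:
    """Chi-square LRT of a nested model against the full model."""
    if not (set(nested.spec.mean_terms) <= set(full.spec.mean_terms)
            and set(nested.spec.precision_terms) <= set(full.spec.precision_terms)):
        raise SpecificationError("models are not nested")
    if nested.n_obs != full.n_obs:
        raise SpecificationError("models were fitted on different data")
    df = full.spec.n_coef - nested.spec.n_coef
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-6 * (1.0 + abs(full.loglik)):
        warnings.warn(f"negative LRT statistic {stat:.3g}; optimizer artifact")
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), df=df, p_value=p)


def _removable(spec: ModelSpec):
    """Candidate (submodel, term) pairs: interactions first shield their parents."""
    out = []
    for sub, terms in (("precision", spec.precision_terms), ("mean", spec.mean_terms)):
        locked = {p for t in terms for p in _parents(t)}
        for t in terms:
            if t == "intercept" or (t in locked and ":" not in t):
                continue
            out.append((sub, t))
    return out


def backward_select(start: ModelSpec, data: pd.DataFrame, alpha: float = 0.05,
                    **fit_kw) -> SelectionResult:
    """Backward elimination driven by likelihood-ratio tests.

    At each step every removable term (interactions before their parents) is
    dropped in turn; the term with the largest LRT p-value is eliminated while
    that p-value exceeds ``alpha``.  Ties (to 1e-12) prefer removing precision-
    submodel terms, biasing selection toward a simpler dispersion structure.
    """
    spec = start
    current = fit_model(spec, data, compute_vcov=False, **fit_kw)
    trace: list[dict] = []
    while True:
        candidates = _removable(spec)
        if not candidates:
            break
        best = None
        for sub, term in candidates:
            reduced_spec = spec.drop(sub, term)
            reduced = fit_model(reduced_spec, data, compute_vcov=False, **fit_kw)
            lrt = likelihood_ratio_test(reduced, current)
            key = (lrt.p_value, 1 if sub == "precision" else 0)
            if best is None or key[0] > best[0][0] + 1e-12 or (
                    abs(key[0] - best[0][0]) <= 1e-12 and key[1] > best[0][1]):
                best = (key, sub, term, reduced, lrt)
        (p_best, _), sub, term, reduced, lrt = best
        if p_best <= alpha:
            break
        trace.append({"submodel": sub, "term": term,
                      "p_value": lrt.p_value, "statistic": lrt.statistic})
        spec, current = reduced.spec, reduced
    final = fit_model(spec, data, **fit_kw)
    return SelectionResult(fit=final, trace=trace)


def pseudo_r2(fit: FittedModel, data: pd.DataFrame) -> float:
    """Squared correlation between the mean linear predictor and logit(y).

    Returns 0 for an intercept-only mean submodel (no predictor variance by
    construction); NaN, with a warning, if a non-trivial predictor happens to
    be constant.
    """
    if fit.spec.mean_terms == ("intercept",):
        return 0.0
    y, X, _ = _extract(fit.spec, data)
    eta = X @ fit.beta
    ystar = np.log(y) - np.log1p(-y)
    if np.var(eta) == 0.0:
        warnings.warn("zero-variance mean predictor; pseudo-R2 undefined")
        return float("nan")
    r = np.corrcoef(eta, ystar)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# diagnostics


def diagnostics(fit: FittedModel, data: pd.DataFrame) -> Diagnostics:
    """Per-observation residual diagnostics for a converged fit.

    Standardized residuals use the beta variance mu(1-mu)/(1+phi); leverage is
    the generalized leverage d mu_hat_i / d y_i evaluated through the observed
    information; Cook's distance combines residuals with the mean-submodel
    weighted hat matrix.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    y, X, Z = _extract(fit.spec, data)
    _, mu, phi = _loglik_terms(y, X, Z, fit.beta, fit.gamma)
    var = mu * (1.0 - mu) / (1.0 + phi)
    resid = (y - mu) / np.sqrt(var)

    theta = fit.params
    info = _observed_information(theta, y, X, Z)  # -Hessian of loglik
    # d(score)/dy cross-derivatives
    k = X.shape[1]
    dmu_deta = mu * (1.0 - mu)
    Lby = X.T * (phi * dmu_deta / (y * (1.0 - y)))                 # k x n
    Lgy = Z.T * (phi * (mu / y - (1.0 - mu) / (1.0 - y)))          # p x n
    Lty = np.vstack([Lby, Lgy])
    Dtheta = np.hstack([dmu_deta[:, None] * X, np.zeros((y.size, Z.shape[1]))])
    try:
        GL = Dtheta @ np.linalg.solve(info, Lty)
        leverage = np.diag(GL).copy()
    except np.linalg.LinAlgError:
        leverage = np.full(y.size, np.nan)

    # mean-submodel hat matrix with Fisher weights (logit link)
    w = phi * (special.polygamma(1, mu * phi) + special.polygamma(1, (1.0 - mu) * phi)) \
        * dmu_deta ** 2
    Xw = X * np.sqrt(w)[:, None]
    try:
        h = np.einsum("ij,ij->i", Xw @ np.linalg.inv(Xw.T @ Xw), Xw)
    except np.linalg.LinAlgError:
        h = np.full(y.size, np.nan)
    cooks = h * resid ** 2 / (k * (1.0 - h) ** 2)

    return Diagnostics(residuals=resid, cooks_distance=cooks, leverage=leverage,
                       fitted_mu=mu, predicted_mm=scale_to_mm(mu, fit.spec.bounds))
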