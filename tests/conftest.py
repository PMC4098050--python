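import numpy as np
import pandas as pd
import pytest

from lvpwd import betareg, cohort

POLISH_AGE_SEX_SPEC = betareg.ModelSpec(
    mean_terms=("intercept", "age", "sex", "age:sex"),
    precision_terms=("intercept", "age", "sex", "age:sex"),
)


@pytest.fixture(scope="session")
def polish_design():
    """n=1000 synthetic subjects from the Polish age-sex generator."""
    recipe = cohort.CohortRecipe.default("polish", seed=20259).with_counts(500, 500)
    return cohort.to_design(cohort.generate_cohort(recipe))


@pytest.fixture(scope="session")
def polish_fit(polish_design):
    return betareg.fit_model(POLISH_AGE_SEX_SPEC, polish_design)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def simulate_beta_design(n, beta, gamma, spec, seed, age_range=(18.0, 75.0)):
    """Direct simulator used as an independent data source for fitting tests."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, size=n)
    sex = (rng.uniform(size=n) < 0.5).astype(float)
    cov = pd.DataFrame({"age": age, "sex": sex})
    mu, phi = betareg.linear_predictors(spec, (beta, gamma), cov)
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    y = np.clip(y, 1e-12, 1.0 - 1e-12)
    cov[betareg.RESPONSE_COLUMN] = 6.0 + 5.0 * y
    return cov
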