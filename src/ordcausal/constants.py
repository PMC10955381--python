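"""Default ground-truth parameter values for the synthetic-data generator.

Every structural-equation default lives here, in one place.  Magnitudes
are chosen to give visible but realistic effects (|log-odds| mostly in
[0.3, 1] for indicator contrasts, small per-increment values for the
monotonic predictors); the covariate distributions are conveniences that
respect the survey's ranges (age 17+, education 0-30 years).
"""

from __future__ import annotations

import numpy as np

# Cross-site layout
DEFAULT_N_SITES = 14
DEFAULT_N_PER_SITE = 150

# Outcome scale: 5 ordered categories, 4 latent thresholds
DEFAULT_CUTPOINTS = (-1.8, -0.6, 0.4, 1.5)

# Log-odds effects on religiosity (monotonic coefficients are per-increment
# average adjacent-level differences, as in the analysis model)
DEFAULT_BETA_SEX_ON_Y = 0.4
DEFAULT_BETA_M_ON_Y = 0.8          # food insecurity indicator
DEFAULT_BETA_EDU_ON_Y = -0.04      # per year of education
DEFAULT_BETA_AGE_ON_Y = 0.02       # per year of age above the minimum
DEFAULT_BETA_CHILDREN_ON_Y = 0.1   # per child

# Monotonic-effect domains
EDUCATION_DOMAIN = 30      # years of education 0..30
AGE_MIN = 17
AGE_DOMAIN = 60            # ages 17..77
CHILDREN_DOMAIN = 10       # counts capped at 10

# Food-insecurity logit: intercept, sex, age increment, education, children
DEFAULT_FOOD_INSECURITY_COEFS = (-0.6, 0.2, 0.008, -0.05, 0.15)

# Children log-rate: intercept, education, age increment
DEFAULT_CHILDREN_RATE_COEFS = (-0.7, -0.03, 0.035)

# Education: Binomial(30, p) with logit(p) = b0 + b1*sex + b2*age_increment
DEFAULT_EDUCATION_COEFS = (-0.2, 0.15, -0.01)

# Age increment above 17: Binomial(AGE_DOMAIN, p)
DEFAULT_AGE_MEAN_FRAC = 0.3

# Site-level intercept spread
DEFAULT_SITE_EFFECT_SD = 0.5

# Latent education-type scenario (off by default)
DEFAULT_EDUCATION_TYPE_EFFECT = 0.0
DEFAULT_EDUCATION_TYPE_FOOD_EFFECT = 0.0
DEFAULT_EDUCATION_TYPE_PREVALENCE = 0.5


def _mild_simplex(d: int, tilt: float) -> tuple:
    """A fixed, gently tilted simplex (geometric weights, normalized)."""
    w = np.exp(tilt * np.arange(d))
    w = w / w.sum()
    return tuple(w.tolist())


DEFAULT_EDU_SIMPLEX = _mild_simplex(EDUCATION_DOMAIN, -0.03)
DEFAULT_AGE_SIMPLEX = _mild_simplex(AGE_DOMAIN, 0.02)
DEFAULT_CHILDREN_SIMPLEX = _mild_simplex(CHILDREN_DOMAIN, -0.08)
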