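"""Weakly informative priors for the free model parameters.

Gamma priors are parameterized shape-rate:

    beta  ~ Gamma(3, 1)      (mean 3)
    r0    ~ Gamma(55, 0.75)  (mean ~73.3, near the task's typical rewards)
    h     ~ Beta(3, 3)       (symmetric around 0.5; h = 1/alpha_init)
    b_das ~ Gamma(3, 0.1)    (mean 30)

The two-strength variant reuses the Beta(3, 3) prior for both h_das and
h_other.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .models import MODEL_PARAM_NAMES, ModelParams

PRIORS = {
    "beta": stats.gamma(a=3, scale=1.0),
    "r0": stats.gamma(a=55, scale=1 / 0.75),
    "h": stats.beta(3, 3),
    "h_das": stats.beta(3, 3),
    "h_other": stats.beta(3, 3),
    "b_das": stats.gamma(a=3, scale=10.0),
}

#: Bijections to the unconstrained scale used by the optimizer and sampler.
_LOG_PARAMS = ("beta", "r0", "b_das")
_LOGIT_PARAMS = ("h", "h_das", "h_other")


def prior_logpdf(params: ModelParams) -> float:
    """Sum of prior log-densities over the model's active parameters."""
    total = 0.0
    for name in params.active:
        lp = PRIORS[name].logpdf(getattr(params, name))
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return float(total)


def prior_sd(name: str) -> float:
    return float(PRIORS[name].std())


def sample_prior(model_id: str, rng: np.random.Generator) -> dict[str, float]:
    return {
        name: float(PRIORS[name].rvs(random_state=rng))
        for name in MODEL_PARAM_NAMES[model_id]
    }


def to_unconstrained(values: dict[str, float], names: tuple[str, ...]) -> np.ndarray:
    z = []
    for name in names:
        v = values[name]
        z.append(np.log(v) if name in _LOG_PARAMS else logit(v))
    return np.array(z)


def from_unconstrained(z: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    out = {}
    for name, zi in zip(names, z):
        out[name] = float(np.exp(zi)) if name in _LOG_PARAMS else float(expit(zi))
    return out


def log_jacobian(z: np.ndarray, names: tuple[str, ...]) -> float:
    """log |d theta / d z| for the componentwise bijection."""
    total = 0.0
    for name, zi in zip(names, z):
        if name in _LOG_PARAMS:
            total += zi  # d exp(z)/dz = exp(z)
        else:
            p = expit(zi)
            total += np.log(p) + np.log1p(-p)
    return float(total)


def shrinkage(prior_sd_value: float, posterior_sd_value: float) -> float:
    """1 - (posterior SD / prior SD)^2; near 1 means data dominate."""
    if prior_sd_value <= 0:
        raise ValueError("prior_sd must be positive")
    return 1.0 - (posterior_sd_value / prior_sd_value) ** 2
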