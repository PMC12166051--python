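"""Per-participant model fitting: the `ChoiceModel` / `ChoiceModelResults` pair.

`ChoiceModel` binds one participant's trial records to an experiment
design and a model id; `fit()` returns a `ChoiceModelResults` carrying
point estimates or posterior draws, per-trial pointwise log-likelihoods
(the input to PSIS-LOO), convergence diagnostics, and a `summary()`
table. Fits are per-participant and independent — no hierarchical
pooling.

Two estimators are provided:

* ``method="map"`` — multi-start bounded maximization of
  log-likelihood + log-prior on transformed parameters (log for
  beta/r0/b_das, logit for the bias strengths). Fast and deterministic;
  the workhorse for recovery studies.
* ``method="mcmc"`` — affine-invariant ensemble MCMC (emcee) on the same
  transformed posterior (with the change-of-variables Jacobian), default
  4 chains x 1000 retained draws after 1000 warm-up; split-Rhat is
  reported and Rhat > 1.01 surfaces as a diagnostic warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import ExperimentDesign
from .likelihood import TrialFeatures, build_features, dataset_loglik, pointwise_loglik
from .models import MODEL_PARAM_NAMES, ModelParams
from .priors import (
    from_unconstrained,
    log_jacobian,
    prior_logpdf,
    sample_prior,
    to_unconstrained,
)
from .task import TrialRecord


class ChoiceModel:
    """One participant's choices under one member of the model family."""

    def __init__(
        self,
        records: Sequence[TrialRecord],
        design: ExperimentDesign,
        model_id: str = "EVPRM",
    ):
        if model_id not in MODEL_PARAM_NAMES:
            raise ValueError(f"unknown model_id {model_id!r}")
        self.model_id = model_id
        self.design = design
        self.records = list(records)
        self.features: TrialFeatures = build_features(self.records, design)
        if self.features.n_trials < 1:
            raise ValueError("need at least one completed trial")
        self.param_names = MODEL_PARAM_NAMES[model_id]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        design: ExperimentDesign,
        model_id: str = "EVPRM",
        participant: str | None = None,
    ) -> "ChoiceModel":
        from .io import frame_to_records

        per_participant = frame_to_records(df, design)
        if participant is None:
            if len(per_participant) != 1:
                raise ValueError(
                    "frame holds several participants; pass participant="
                )
            participant = next(iter(per_participant))
        return cls(per_participant[participant], design, model_id)

    @property
    def n_trials(self) -> int:
        return self.features.n_trials

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    def _params(self, values: dict[str, float]) -> ModelParams:
        return ModelParams(model_id=self.model_id, **values)

    def loglike(self, params: ModelParams) -> float:
        return dataset_loglik(params, self.features)

    def pointwise(self, params: ModelParams) -> np.ndarray:
        return pointwise_loglik(params, self.features)

    def logpost_unconstrained(self, z: np.ndarray, with_jacobian: bool) -> float:
        values = from_unconstrained(z, self.param_names)
        try:
            params = self._params(values)
        except ValueError:
            return -np.inf
        lp = prior_logpdf(params)
        if not np.isfinite(lp):
            return -np.inf
        out = self.loglike(params) + lp
        if with_jacobian:
            out += log_jacobian(z, self.param_names)
        return out

    # ------------------------------------------------------------------ fit

    def fit(self, method: str = "map", **config) -> "ChoiceModelResults":
        if method == "map":
            return self._fit_map(**config)
        if method == "mcmc":
            return self._fit_mcmc(**config)
        raise ValueError(f"unknown method {method!r}; use 'map' or 'mcmc'")

    def _fit_map(
        self, n_starts: int = 8, seed: int = 0, maxiter: int = 300
    ) -> "ChoiceModelResults":
        if self.k_params == 0:
            params = ModelParams(model_id=self.model_id)
            pw = self.pointwise(params)
            return ChoiceModelResults(
                model=self,
                method="map",
                params=params,
                pointwise_loglik=pw[None, :],
                loglike=float(pw.sum()),
                diagnostics={"converged": True, "n_starts": 0},
            )
        rng = np.random.default_rng(seed)
        # one central start at the prior medians, the rest prior draws
        from .priors import PRIORS

        starts = [
            {name: float(PRIORS[name].median()) for name in self.param_names}
        ]
        while len(starts) < n_starts:
            starts.append(sample_prior(self.model_id, rng))

        best = None
        n_ok = 0
        for start in starts:
            z0 = to_unconstrained(start, self.param_names)
            res = minimize(
                lambda z: -self.logpost_unconstrained(z, with_jacobian=False),
                z0,
                method="L-BFGS-B",
                options={"maxiter": maxiter},
            )
            if np.isfinite(res.fun):
                n_ok += 1
                if best is None or res.fun < best.fun:
                    best = res
        if best is None:
            raise RuntimeError(
                f"all {n_starts} optimization starts failed for {self.model_id}"
            )
        values = from_unconstrained(best.x, self.param_names)
        params = self._params(values)
        pw = self.pointwise(params)
        return ChoiceModelResults(
            model=self,
            method="map",
            params=params,
            pointwise_loglik=pw[None, :],
            loglike=float(pw.sum()),
            diagnostics={
                "converged": bool(best.success),
                "n_starts": n_starts,
                "n_starts_ok": n_ok,
                "neg_logpost": float(best.fun),
            },
        )

    def _fit_mcmc(
        self,
        chains: int = 4,
        draws: int = 1000,
        warmup: int = 1000,
        thin: int = 4,
        seed: int = 0,
        map_seed: int = 0,
    ) -> "ChoiceModelResults":
        import emcee

        if self.k_params == 0:
            return self._fit_map()
        ndim = self.k_params
        nwalkers = max(2 * ndim + 2, 2 * chains)
        nwalkers += nwalkers % 2
        retained_steps = int(np.ceil(chains * draws / nwalkers))
        warmup_steps = int(np.ceil(chains * warmup / nwalkers))

        rng = np.random.default_rng(seed)
        # initialize walkers in a tight ball around the MAP mode
        map_res = self._fit_map(seed=map_seed)
        z_map = to_unconstrained(map_res.params.as_dict(), self.param_names)
        p0 = z_map[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))

        sampler = emcee.EnsembleSampler(
            nwalkers,
            ndim,
            lambda z: self.logpost_unconstrained(z, with_jacobian=True),
        )
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2**31))
        ).get_state()
        state = sampler.run_mcmc(p0, warmup_steps * thin, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, retained_steps, thin_by=thin, progress=False)

        chain = sampler.get_chain()  # (steps, walkers, ndim)
        rhat = _split_rhat(chain)
        diagnostics = {
            "rhat": {n: float(r) for n, r in zip(self.param_names, rhat)},
            "acceptance_fraction": float(sampler.acceptance_fraction.mean()),
            "n_walkers": nwalkers,
            "n_steps": retained_steps,
        }
        if np.any(rhat > 1.01):
            diagnostics["warning"] = (
                f"split-Rhat above 1.01 for "
                f"{[n for n, r in zip(self.param_names, rhat) if r > 1.01]}"
            )
            warnings.warn(
                f"{self.model_id}: {diagnostics['warning']}", RuntimeWarning
            )

        flat = chain.reshape(-1, ndim)[: chains * draws]
        theta = np.array(
            [
                [from_unconstrained(z, self.param_names)[n] for n in self.param_names]
                for z in flat
            ]
        )
        draws_df = pd.DataFrame(theta, columns=list(self.param_names))
        pw = np.array(
            [
                self.pointwise(self._params(dict(zip(self.param_names, row))))
                for row in theta
            ]
        )
        post_mean = self._params(
            {n: float(draws_df[n].mean()) for n in self.param_names}
        )
        return ChoiceModelResults(
            model=self,
            method="mcmc",
            params=post_mean,
            draws=draws_df,
            pointwise_loglik=pw,
            loglike=float(self.loglike(post_mean)),
            diagnostics=diagnostics,
        )


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-Rhat per parameter from an (steps, walkers, ndim) chain."""
    import arviz as az

    steps, walkers, ndim = chain.shape
    # arviz expects (chain, draw, ...) — walkers act as chains
    posterior = {
        f"p{i}": np.moveaxis(chain[..., i], 0, 1) for i in range(ndim)
    }
    idata = az.from_dict(posterior=posterior)
    rh = az.rhat(idata)
    return np.array([float(rh[f"p{i}"].values) for i in range(ndim)])


@dataclass
class ChoiceModelResults:
    """Estimates, draws, pointwise log-likelihoods and diagnostics."""

    model: ChoiceModel
    method: str
    params: ModelParams
    pointwise_loglik: np.ndarray  # (n_draws_or_1, n_trials)
    loglike: float
    draws: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def model_id(self) -> str:
        return self.model.model_id

    @property
    def n_trials(self) -> int:
        return self.model.n_trials

    @property
    def k_params(self) -> int:
        return self.model.k_params

    def posterior_sd(self, name: str) -> float:
        if self.draws is None:
            raise ValueError("posterior SDs need MCMC draws")
        return float(self.draws[name].std(ddof=1))

    def shrinkage(self, name: str) -> float:
        """1 - (posterior SD / prior SD)^2 for one parameter."""
        from .priors import prior_sd, shrinkage

        return shrinkage(prior_sd(name), self.posterior_sd(name))

    def loo(self):
        """PSIS-LOO of this fit (penalized point approximation for MAP)."""
        from .loo import loo_from_results

        return loo_from_results(self)

    def sample_params(self, rng: np.random.Generator) -> ModelParams:
        """Draw one parameter set from the posterior (or the mode for MAP)."""
        if self.draws is None or len(self.draws) == 0:
            return self.params
        row = self.draws.iloc[int(rng.integers(len(self.draws)))]
        return self.model._params({n: float(row[n]) for n in self.model.param_names})

    def summary(self) -> str:
        lines = [
            f"{self.model_id} fit ({self.method}), "
            f"{self.n_trials} completed trials",
            f"log-likelihood: {self.loglike:.2f}",
            "-" * 46,
            f"{'param':<10}{'estimate':>10}{'post. sd':>12}{'rhat':>8}",
        ]
        rhat = self.diagnostics.get("rhat", {})
        for name in self.model.param_names:
            est = getattr(self.params, name)
            sd = (
                f"{self.posterior_sd(name):>12.4f}"
                if self.draws is not None
                else f"{'--':>12}"
            )
            rh = f"{rhat[name]:>8.3f}" if name in rhat else f"{'--':>8}"
            lines.append(f"{name:<10}{est:>10.4f}{sd}{rh}")
        if not self.model.param_names:
            lines.append("(no free parameters)")
        if "warning" in self.diagnostics:
            lines.append(f"WARNING: {self.diagnostics['warning']}")
        return "\n".join(lines)
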