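"""Predictive-accuracy estimation and model comparison.

Leave-one-out cross-validation is approximated from posterior draws by
Pareto-smoothed importance sampling (PSIS-LOO): per-trial importance
ratios are the reciprocal likelihoods, their right tail is replaced by
quantiles of a generalized Pareto distribution fitted to the tail (the
Zhang-Stephens posterior-mean estimator), and the expected log pointwise
predictive density (elpd) is accumulated per trial. Results are reported
on the deviance scale too (LOOIC = -2 elpd; lower is better). The tail
shape k-hat flags unreliable trials (k-hat > 0.7).

Fits without posterior draws (MAP point estimates) are handled by a
penalized point approximation: elpd ~= sum of pointwise log-likelihood at
the mode minus the number of free parameters — the classic
information-criterion penalty — so MAP-based pipelines can reuse the same
comparison machinery. The source is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

PARETO_K_WARN = 0.7


@dataclass
class LooResult:
    """elpd and friends for one participant x model fit."""

    elpd_loo: float
    se: float
    p_loo: float
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray
    n_draws: int
    method: str = "psis"  # or "map_penalized"

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def n_trials(self) -> int:
        return len(self.pointwise_elpd)

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Empirical-Bayes estimate of GPD shape k and scale sigma
    (Zhang & Stephens 2009 profile-posterior recipe).

    ``x`` are the sorted, positive exceedances over the tail threshold.
    """
    prior_bs, prior_k = 3.0, 10.0
    n = len(x)
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1, dtype=float) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        len_scale = n * (np.log(-(b / k)) - k - 1.0)
        w = 1.0 / np.exp(len_scale - len_scale[:, None]).sum(axis=1)
    keep = w >= 10 * np.finfo(float).eps
    w, b = w[keep], b[keep]
    w /= w.sum()
    b_post = float(np.sum(b * w))
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _psis_smooth_column(lw: np.ndarray) -> tuple[np.ndarray, float]:
    """Smooth one trial's log importance weights; return (lw, k-hat).

    The tail is the ceil(min(S/5, 3*sqrt(S))) largest weights; their
    exceedances over the cutoff get replaced by expected order statistics
    of a fitted generalized Pareto, capped at the maximum raw weight.
    """
    S = len(lw)
    lw = lw - lw.max()
    if np.ptp(lw) < 1e-12:
        # constant weights (e.g. a parameter-free model): nothing to smooth
        return lw, -np.inf
    tail_guess = int(np.ceil(min(S / 5.0, 3 * np.sqrt(S))))
    order = np.argsort(lw)
    cutoff = max(lw[order[-tail_guess - 1]], np.log(np.finfo(float).tiny))
    tail_ids = np.where(lw > cutoff)[0]
    tail_len = len(tail_ids)
    if tail_len <= 4:
        return lw, np.inf
    exp_cutoff = np.exp(cutoff)
    tail_order = np.argsort(lw[tail_ids])
    exceed_sorted = np.exp(lw[tail_ids[tail_order]]) - exp_cutoff
    k, sigma = _gpd_fit(exceed_sorted)
    if np.isfinite(k) and sigma > 0:
        p = np.arange(0.5, tail_len) / tail_len
        if abs(k) < np.finfo(float).eps:
            q = -np.log1p(-p) * sigma
        else:
            q = sigma * np.expm1(-k * np.log1p(-p)) / k
        lw = lw.copy()
        lw[tail_ids[tail_order]] = np.log(q + exp_cutoff)
        np.minimum(lw, 0.0, out=lw)
    return lw, float(k)


def psis_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a (draws x trials) pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be a (draws, trials) matrix")
    if not np.all(np.isfinite(ll)):
        bad = int(np.argwhere(~np.isfinite(ll).all(axis=0))[0][0])
        raise ValueError(f"non-finite log-likelihood at trial {bad}")
    S, n = ll.shape
    elpd_i = np.empty(n)
    k_i = np.empty(n)
    for i in range(n):
        lw, k = _psis_smooth_column(-ll[:, i])
        lw = lw - logsumexp(lw)
        elpd_i[i] = logsumexp(ll[:, i] + lw)
        k_i[i] = k
    lpd_i = logsumexp(ll, axis=0) - np.log(S)
    p_loo = float(np.sum(lpd_i - elpd_i))
    elpd = float(elpd_i.sum())
    se = float(np.sqrt(n * np.var(elpd_i)))
    return LooResult(
        elpd_loo=elpd,
        se=se,
        p_loo=p_loo,
        pointwise_elpd=elpd_i,
        pareto_k=k_i,
        n_draws=S,
        method="psis",
    )


def map_penalized_loo(pointwise_loglik_at_mode: np.ndarray, k_params: int) -> LooResult:
    """Information-criterion approximation for point (MAP) fits.

    The per-parameter penalty is spread uniformly over trials so that
    pointwise differences remain meaningful for d_se.
    """
    ll = np.asarray(pointwise_loglik_at_mode, dtype=float).ravel()
    n = len(ll)
    elpd_i = ll - k_params / n
    return LooResult(
        elpd_loo=float(elpd_i.sum()),
        se=float(np.sqrt(n * np.var(elpd_i))),
        p_loo=float(k_params),
        pointwise_elpd=elpd_i,
        pareto_k=np.full(n, -np.inf),
        n_draws=1,
        method="map_penalized",
    )


def loo_from_results(results) -> LooResult:
    """Dispatch on a :class:`~ynat.model.ChoiceModelResults`."""
    if results.draws is not None and len(results.pointwise_loglik) > 1:
        return psis_loo(results.pointwise_loglik)
    return map_penalized_loo(results.pointwise_loglik, results.k_params)


def compare_models(
    per_participant: dict[str, dict[str, LooResult]]
) -> "pd.DataFrame":
    """Group-level comparison table from per-participant LooResults.

    ``per_participant`` maps participant id -> model id -> LooResult; each
    participant's models must share an identical trial set. Returns a
    table with one row per model: looic, se, p_loo, d_looic and d_se
    relative to the best (lowest-LOOIC) model from pointwise differences,
    and the number of participants best fitted. Ties within 1e-9 at the
    participant level are recorded as ties and assigned to no model.
    """
    import pandas as pd

    model_ids = None
    for pid, loos in per_participant.items():
        ids = tuple(sorted(loos))
        if model_ids is None:
            model_ids = ids
        elif ids != model_ids:
            raise ValueError(f"participant {pid} has a different model set")
        n_trials = {m: loos[m].n_trials for m in ids}
        if len(set(n_trials.values())) != 1:
            raise ValueError(
                f"participant {pid}: models computed on different trial sets "
                f"({n_trials})"
            )

    # group pointwise elpd per model, concatenated over participants
    pointwise = {
        m: np.concatenate(
            [per_participant[p][m].pointwise_elpd for p in per_participant]
        )
        for m in model_ids
    }
    elpd = {m: float(pointwise[m].sum()) for m in model_ids}
    best = max(model_ids, key=lambda m: elpd[m])

    rows = []
    n_best = {m: 0 for m in model_ids}
    n_ties = 0
    for pid, loos in per_participant.items():
        looics = {m: loos[m].looic for m in model_ids}
        lo = min(looics.values())
        winners = [m for m in model_ids if looics[m] - lo < 1e-9]
        if len(winners) == 1:
            n_best[winners[0]] += 1
        else:
            n_ties += 1
    for m in model_ids:
        diff = pointwise[best] - pointwise[m]
        n = len(diff)
        d_looic = 2.0 * float(diff.sum())
        d_se = 2.0 * float(np.sqrt(n * np.var(diff)))
        se = float(
            2.0
            * np.sqrt(
                n * np.var(pointwise[m])
            )
        )
        p_loo = float(
            sum(per_participant[p][m].p_loo for p in per_participant)
        )
        rows.append(
            {
                "model": m,
                "looic": -2.0 * elpd[m],
                "se": se,
                "p_loo": p_loo,
                "d_looic": d_looic,
                "d_se": d_se,
                "n_best_fit": n_best[m],
                "n_ties": n_ties,
            }
        )
    df = pd.DataFrame(rows).sort_values("looic").reset_index(drop=True)
    return df
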