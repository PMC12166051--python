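"""Choice models: expected value combined with a count-based repetition bias.

Every model assigns a categorical probability distribution over the 36
valid action sequences on each trial. The family shares one value
component — a precision-weighted function of expected rewards,

    p(R | pi) = (R_pi / sum_pi' R_pi')**beta

— and differs in how expected rewards R_pi are formed and whether a prior
over policies multiplies in:

* EVPRM  — proxy rewards plus a repetition prior. Sequences observed in
  the current block carry the reward implied by their observed point sum
  and the current goal; unobserved sequences carry an approximated reward
  R0. The choice probability is the normalized product of the value term
  and a Dirichlet-count prior p(pi) = alpha_pi / sum alpha, with
  alpha_pi = alpha_init + gamma_pi and gamma_pi counting how often pi was
  chosen so far in the whole session. The repetition bias strength is
  h = 1 / alpha_init in (0, 1]: h near 1 means each past use strongly
  inflates a sequence's prior.
* EVPRM2 — as EVPRM but with separate bias strengths for the default
  sequence (h_das) and all other sequences (h_other).
* EVPBM  — proxy rewards plus a constant bias b_das added to the default
  sequence's expected reward; no repetition prior.
* EVPM   — proxy rewards only.
* EVM    — exact expected rewards for every sequence (noiseless point
  sums), no proxy, no prior.
* UNIFORM — 1/36 everywhere, the random-responding baseline.

The default action sequence (DAS) counts as observed on every trial (its
mean points are communicated), and its expected reward is raised by 5 on
bonus trials (a +20 bonus at probability 0.25). Rewards are clamped below
at a small floor so that a reward of exactly zero cannot make an observed
choice impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import ExperimentDesign
from .task import TrialRecord, TrialSpec, sequence_points, trial_reward

MODEL_IDS = ("EVPRM", "EVPRM2", "EVPBM", "EVPM", "EVM", "UNIFORM")

#: Floor applied to expected-reward entries (a zero reward would zero the
#: choice probability and send an observed choice's log-likelihood to -inf).
REWARD_CLAMP = 0.01

#: Expected DAS reward increment on bonus trials: 0.25 * 20.
BONUS_EXPECTED_INCREMENT = 5.0

#: Which parameters each model consults.
MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "EVPRM": ("beta", "r0", "h"),
    "EVPRM2": ("beta", "r0", "h_das", "h_other"),
    "EVPBM": ("beta", "r0", "b_das"),
    "EVPM": ("beta", "r0"),
    "EVM": ("beta",),
    "UNIFORM": (),
}


@dataclass(frozen=True)
class ModelParams:
    """Free parameters; only the fields relevant to ``model_id`` are used.

    beta    precision over expected rewards, >= 0
    r0      approximated reward for unobserved sequences, > 0
    h       repetition bias strength, h = 1/alpha_init, in (0, 1]
    h_das / h_other   as h, for the two-strength variant
    b_das   constant bias added to the default sequence's reward, >= 0
    """

    model_id: str
    beta: float = 1.0
    r0: float = 70.0
    h: float = 0.5
    h_das: float = 0.5
    h_other: float = 0.5
    b_das: float = 0.0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        active = MODEL_PARAM_NAMES[self.model_id]
        if "beta" in active and not self.beta >= 0:
            raise ValueError("beta must be >= 0")
        if "r0" in active and not self.r0 > 0:
            raise ValueError("r0 must be > 0")
        for name in ("h", "h_das", "h_other"):
            if name in active and not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if "b_das" in active and not self.b_das >= 0:
            raise ValueError("b_das must be >= 0")

    @property
    def active(self) -> tuple[str, ...]:
        return MODEL_PARAM_NAMES[self.model_id]

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.active}

    def with_values(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class BeliefState:
    """What the agent carries between trials.

    gamma          per-sequence usage counts over the whole session
    observed_sums  point sums observed during the *current block*; the DAS
                   is always present (its mean points are communicated)
    """

    design: ExperimentDesign
    gamma: np.ndarray
    observed_sums: dict[str, int]
    current_block: int = 0

    @property
    def das_label(self) -> str:
        return self.design.das.label

    def copy(self) -> "BeliefState":
        return BeliefState(
            design=self.design,
            gamma=self.gamma.copy(),
            observed_sums=dict(self.observed_sums),
            current_block=self.current_block,
        )


def init_beliefs(design: ExperimentDesign) -> BeliefState:
    """Fresh beliefs: zero counts; only the DAS point sum is known."""
    n = len(design.sequence_space)
    return BeliefState(
        design=design,
        gamma=np.zeros(n, dtype=int),
        observed_sums={design.das.label: design.das_expected_sum},
        current_block=0,
    )


def observe_trial(beliefs: BeliefState, record: TrialRecord) -> BeliefState:
    """Update beliefs after a completed trial (in place; also returned).

    The chosen sequence's count rises by one and its observed point sum is
    stored (latest observation wins). Counts persist across blocks;
    observed sums reset to the DAS alone at each block boundary. Timed-out
    trials must not be passed here.
    """
    if record.timeout:
        raise ValueError("timed-out trials do not update beliefs")
    space = beliefs.design.sequence_space
    label = record.chosen.label
    if label not in space:
        raise KeyError(f"chosen sequence {label!r} not in the sequence space")
    if record.spec.block_index != beliefs.current_block:
        beliefs.observed_sums = {
            beliefs.das_label: beliefs.design.das_expected_sum
        }
        beliefs.current_block = record.spec.block_index
    beliefs.gamma[space.index[label]] += 1
    beliefs.observed_sums[label] = int(record.total_points)
    return beliefs


def reward_structure(
    params: ModelParams, beliefs: BeliefState, trial: TrialSpec
) -> np.ndarray:
    """Expected-reward vector R_hat over the sequence space for one trial."""
    design = beliefs.design
    space = design.sequence_space
    n = len(space)
    das_idx = space.index[beliefs.das_label]

    if params.model_id == "EVM":
        grid = design.blocks[trial.block_index].grid
        r_hat = np.array(
            [
                float(trial_reward(trial.goal, sequence_points(grid, s)))
                for s in space
            ]
        )
    else:
        r_hat = np.full(n, float(params.r0))
        for label, pts in beliefs.observed_sums.items():
            r_hat[space.index[label]] = float(trial_reward(trial.goal, pts))
        if params.model_id == "EVPBM":
            r_hat[das_idx] += params.b_das

    if trial.bonus_trial:
        r_hat[das_idx] += BONUS_EXPECTED_INCREMENT
    return np.maximum(r_hat, REWARD_CLAMP)


def reward_term(r_hat: np.ndarray, beta: float) -> np.ndarray:
    """(R_pi / sum R)**beta, elementwise; not renormalized."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return (r_hat / r_hat.sum()) ** beta


def policy_prior(gamma: np.ndarray, alpha_init) -> np.ndarray:
    """Normalized Dirichlet counts: (alpha_init + gamma) / sum."""
    alpha = np.asarray(alpha_init, dtype=float) + gamma
    return alpha / alpha.sum()


def _alpha_init_vector(params: ModelParams, beliefs: BeliefState) -> np.ndarray:
    n = len(beliefs.design.sequence_space)
    if params.model_id == "EVPRM":
        return np.full(n, 1.0 / params.h)
    # EVPRM2: separate initial counts for the DAS and everything else
    alpha = np.full(n, 1.0 / params.h_other)
    alpha[beliefs.design.sequence_space.index[beliefs.das_label]] = (
        1.0 / params.h_das
    )
    return alpha


def choice_probabilities(
    params: ModelParams, beliefs: BeliefState, trial: TrialSpec
) -> np.ndarray:
    """Categorical choice distribution over the sequence space for one trial."""
    n = len(beliefs.design.sequence_space)
    if params.model_id == "UNIFORM":
        return np.full(n, 1.0 / n)
    r_hat = reward_structure(params, beliefs, trial)
    # log-space keeps large beta stable
    log_w = params.beta * (np.log(r_hat) - np.log(r_hat.sum()))
    if params.model_id in ("EVPRM", "EVPRM2"):
        prior = policy_prior(beliefs.gamma, _alpha_init_vector(params, beliefs))
        log_w = log_w + np.log(prior)
    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.sum()
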