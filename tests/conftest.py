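import numpy as np
import pytest

from ynat import ModelParams, build_default_design, simulate_agent


@pytest.fixture(scope="session")
def design():
    return build_default_design()


@pytest.fixture(scope="session")
def space(design):
    return design.sequence_space


@pytest.fixture(scope="session")
def evprm_records(design):
    """One strongly repetitive simulated participant, reused across tests."""
    params = ModelParams(model_id="EVPRM", beta=5.0, r0=70.0, h=0.9)
    return simulate_agent(params, design, rng_seed=11, participant_id="p_evprm")


@pytest.fixture(scope="session")
def evpm_records(design):
    params = ModelParams(model_id="EVPM", beta=8.0, r0=70.0)
    return simulate_agent(params, design, rng_seed=12, participant_id="p_evpm")


# ---------------------------------------------------------------- oracle

def oracle_choice_probs(
    model_id: str,
    params: dict,
    labels: list[str],
    gamma: dict,
    observed_sums: dict,
    goal: int,
    bonus_trial: bool,
    das_label: str,
    das_expected_sum: int,
    true_sums: dict | None = None,
    clamp: float = 0.01,
):
    """Naive, loop-based transcription of the choice equations.

    Kept deliberately free of any package internals (plain dicts and
    Python floats) so it can serve as an independent oracle for the
    vectorized implementation.
    """
    # expected rewards
    r_hat = {}
    for lbl in labels:
        if model_id == "EVM":
            r = max(0, 100 - 2 * abs(goal - true_sums[lbl]))
        elif lbl in observed_sums or lbl == das_label:
            pts = observed_sums.get(lbl, das_expected_sum)
            r = max(0, 100 - 2 * abs(goal - pts))
        else:
            r = params["r0"]
        if model_id == "EVPBM" and lbl == das_label:
            r = r + params["b_das"]
        if bonus_trial and lbl == das_label:
            r = r + 5.0
        r_hat[lbl] = max(r, clamp)
    total_r = sum(r_hat.values())
    reward_term = {lbl: (r_hat[lbl] / total_r) ** params["beta"] for lbl in labels}

    if model_id == "UNIFORM":
        return {lbl: 1.0 / len(labels) for lbl in labels}

    if model_id in ("EVPRM", "EVPRM2"):
        alpha = {}
        for lbl in labels:
            if model_id == "EVPRM":
                a0 = 1.0 / params["h"]
            else:
                a0 = 1.0 / (params["h_das"] if lbl == das_label else params["h_other"])
            alpha[lbl] = a0 + gamma.get(lbl, 0)
        total_a = sum(alpha.values())
        unnorm = {lbl: reward_term[lbl] * alpha[lbl] / total_a for lbl in labels}
    else:
        unnorm = reward_term
    z = sum(unnorm.values())
    return {lbl: unnorm[lbl] / z for lbl in labels}
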