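"""Choice-model family: belief tracking, nesting, and oracle equivalence."""

import numpy as np
import pytest

from conftest import oracle_choice_probs
from ynat.models import (
    BeliefState,
    ModelParams,
    choice_probabilities,
    init_beliefs,
    observe_trial,
    policy_prior,
    reward_structure,
    reward_term,
)
from ynat.task import TrialRecord, TrialSpec


def make_record(design, label, block=0, trial=0, total=120, timeout=False):
    spec = TrialSpec(
        block_index=block,
        trial_index=trial,
        goal=design.das_expected_sum,
        bonus_trial=design.blocks[block].bonus_block,
    )
    seq = design.sequence_space.sequences[design.sequence_space.index[label]]
    return TrialRecord(
        participant_id="t",
        spec=spec,
        chosen=None if timeout else seq,
        move_points=(30, 30, 30, 30),
        total_points=total,
        reward=100,
        bonus_received=False,
        timeout=timeout,
    )


def random_beliefs(design, rng):
    """A randomized but internally consistent belief state."""
    beliefs = init_beliefs(design)
    n = len(design.sequence_space)
    beliefs.gamma = rng.integers(0, 15, size=n)
    labels = design.sequence_space.labels
    for lbl in rng.choice(labels, size=rng.integers(0, 8), replace=False):
        beliefs.observed_sums[lbl] = int(rng.integers(-50, 250))
    return beliefs


class TestBeliefs:
    def test_initial_state(self, design):
        b = init_beliefs(design)
        assert b.gamma.sum() == 0
        assert b.observed_sums == {"DDRR": design.das_expected_sum}
        prior = policy_prior(b.gamma, 1.0)
        assert np.allclose(prior, 1 / 36)

    def test_gamma_counts_choices_and_persists_across_blocks(self, design):
        b = init_beliefs(design)
        observe_trial(b, make_record(design, "DDRR", block=0))
        observe_trial(b, make_record(design, "DDRR", block=1))
        observe_trial(b, make_record(design, "LLDD", block=1, trial=1))
        assert b.gamma.sum() == 3
        assert b.gamma[design.sequence_space.index["DDRR"]] == 2

    def test_latest_observation_wins(self, design):
        b = init_beliefs(design)
        observe_trial(b, make_record(design, "LLDD", total=88))
        observe_trial(b, make_record(design, "LLDD", trial=1, total=92))
        assert b.observed_sums["LLDD"] == 92

    def test_observed_sums_reset_at_block_boundary(self, design):
        b = init_beliefs(design)
        observe_trial(b, make_record(design, "LLDD", block=0, total=88))
        observe_trial(b, make_record(design, "RRDD", block=1))
        assert "LLDD" not in b.observed_sums
        assert b.observed_sums["DDRR"] == design.das_expected_sum  # always known

    def test_timeout_rejected(self, design):
        b = init_beliefs(design)
        with pytest.raises(ValueError):
            observe_trial(b, make_record(design, "DDRR", timeout=True))


class TestRewardStructure:
    def test_unobserved_get_r0(self, design):
        params = ModelParams(model_id="EVPM", beta=1, r0=55.0)
        trial = TrialSpec(0, 0, design.das_expected_sum, bonus_trial=False)
        r = reward_structure(params, init_beliefs(design), trial)
        das_idx = design.sequence_space.index["DDRR"]
        assert r[das_idx] == 100  # goal equals the communicated DAS sum
        others = np.delete(r, das_idx)
        assert np.all(others == 55.0)

    def test_bonus_trial_adds_five_to_das(self, design):
        params = ModelParams(model_id="EVPM", beta=1, r0=55.0)
        das_idx = design.sequence_space.index["DDRR"]
        base = reward_structure(
            params, init_beliefs(design),
            TrialSpec(0, 0, 120, bonus_trial=False),
        )
        bonus = reward_structure(
            params, init_beliefs(design),
            TrialSpec(0, 0, 120, bonus_trial=True),
        )
        assert bonus[das_idx] - base[das_idx] == 5.0
        assert np.all(np.delete(bonus, das_idx) == np.delete(base, das_idx))

    def test_clamp_floor(self, design):
        # a goal 80 points away drives the DAS reward to 0 -> clamped
        params = ModelParams(model_id="EVPM", beta=1, r0=55.0)
        r = reward_structure(
            params, init_beliefs(design), TrialSpec(0, 0, 120 + 80, False)
        )
        assert r.min() == pytest.approx(0.01)

    def test_evm_exact_reward_hits_100(self, design):
        from ynat.task import sequence_points

        grid = design.blocks[0].grid
        lbl = design.sequence_space.labels[3]
        goal = sequence_points(grid, lbl)
        r = reward_structure(
            ModelParams(model_id="EVM", beta=1),
            init_beliefs(design),
            TrialSpec(0, 0, goal, False),
        )
        assert r[design.sequence_space.index[lbl]] == 100


class TestRewardTermAndPrior:
    def test_beta_zero_gives_ones(self):
        assert np.allclose(reward_term(np.array([10.0, 50.0, 90.0]), 0.0), 1.0)

    def test_beta_one_proportional(self):
        r = np.array([10.0, 30.0, 60.0])
        assert np.allclose(reward_term(r, 1.0), r / r.sum())

    def test_prior_hand_values_alpha_one(self):
        gamma = np.zeros(36)
        gamma[0] = 1
        p = policy_prior(gamma, 1.0)
        assert p[0] == pytest.approx(2 / 37)
        assert p[1] == pytest.approx(1 / 37)

    def test_prior_hand_values_alpha_hundred(self):
        gamma = np.zeros(36)
        gamma[0] = 1
        p = policy_prior(gamma, 100.0)
        assert p[0] == pytest.approx(101 / 3601)
        assert p[1] == pytest.approx(100 / 3601)


class TestChoiceProbabilities:
    def trial(self, design, bonus=False, goal=None):
        return TrialSpec(0, 0, goal or design.das_expected_sum, bonus)

    def test_uniform_is_one_over_36(self, design):
        p = choice_probabilities(
            ModelParams(model_id="UNIFORM"), init_beliefs(design), self.trial(design)
        )
        assert np.allclose(p, 1 / 36)

    def test_sums_to_one(self, design):
        rng = np.random.default_rng(0)
        for model_id in ("EVPRM", "EVPRM2", "EVPBM", "EVPM", "EVM"):
            params = ModelParams(
                model_id=model_id, beta=float(rng.uniform(0, 10)),
                r0=60.0, h=0.7, h_das=0.9, h_other=0.3, b_das=15.0,
            )
            p = choice_probabilities(
                params, random_beliefs(design, rng), self.trial(design)
            )
            assert abs(p.sum() - 1) < 1e-10
            assert np.all(p >= 0)

    def test_evprm_small_h_approaches_evpm(self, design):
        rng = np.random.default_rng(1)
        beliefs = random_beliefs(design, rng)
        trial = self.trial(design)
        p_evprm = choice_probabilities(
            ModelParams(model_id="EVPRM", beta=4, r0=70, h=1e-7), beliefs, trial
        )
        p_evpm = choice_probabilities(
            ModelParams(model_id="EVPM", beta=4, r0=70), beliefs, trial
        )
        assert np.abs(p_evprm - p_evpm).max() < 1e-6

    def test_evpbm_zero_bias_equals_evpm(self, design):
        rng = np.random.default_rng(2)
        beliefs = random_beliefs(design, rng)
        trial = self.trial(design)
        p_evpbm = choice_probabilities(
            ModelParams(model_id="EVPBM", beta=4, r0=70, b_das=0.0), beliefs, trial
        )
        p_evpm = choice_probabilities(
            ModelParams(model_id="EVPM", beta=4, r0=70), beliefs, trial
        )
        assert np.allclose(p_evpbm, p_evpm)

    def test_evpm_fully_observed_true_sums_equals_evm(self, design):
        from ynat.task import sequence_points

        beliefs = init_beliefs(design)
        grid = design.blocks[0].grid
        for lbl in design.sequence_space.labels:
            beliefs.observed_sums[lbl] = sequence_points(grid, lbl)
        trial = self.trial(design, goal=100)
        p_evpm = choice_probabilities(
            ModelParams(model_id="EVPM", beta=3, r0=70), beliefs, trial
        )
        p_evm = choice_probabilities(
            ModelParams(model_id="EVM", beta=3), beliefs, trial
        )
        assert np.allclose(p_evpm, p_evm)

    def test_beta_zero_evprm_is_pure_prior(self, design):
        rng = np.random.default_rng(3)
        beliefs = random_beliefs(design, rng)
        p = choice_probabilities(
            ModelParams(model_id="EVPRM", beta=0.0, r0=70, h=0.5),
            beliefs,
            self.trial(design),
        )
        assert np.allclose(p, policy_prior(beliefs.gamma, 2.0))

    def test_repetition_strictly_increases_evprm_probability(self, design):
        params = ModelParams(model_id="EVPRM", beta=4, r0=70, h=0.8)
        beliefs = init_beliefs(design)
        trial = self.trial(design)
        i = design.sequence_space.index["LLDD"]
        p0 = choice_probabilities(params, beliefs, trial)[i]
        beliefs.gamma[i] += 1
        p1 = choice_probabilities(params, beliefs, trial)[i]
        assert p1 > p0

    def test_oracle_equivalence_randomized(self, design):
        """Vectorized probabilities match the naive loop transcription."""
        rng = np.random.default_rng(42)
        labels = design.sequence_space.labels
        from ynat.task import sequence_points

        true_sums_cache = {
            b: {lbl: sequence_points(design.blocks[b].grid, lbl) for lbl in labels}
            for b in range(3)
        }
        for _ in range(250):
            model_id = rng.choice(["EVPRM", "EVPRM2", "EVPBM", "EVPM", "EVM", "UNIFORM"])
            params = ModelParams(
                model_id=model_id,
                beta=float(rng.uniform(0, 12)),
                r0=float(rng.uniform(5, 120)),
                h=float(rng.uniform(0.05, 1.0)),
                h_das=float(rng.uniform(0.05, 1.0)),
                h_other=float(rng.uniform(0.05, 1.0)),
                b_das=float(rng.uniform(0, 40)),
            )
            block = int(rng.integers(0, 3))
            beliefs = random_beliefs(design, rng)
            beliefs.current_block = block
            goal = int(rng.integers(60, 180))
            bonus = bool(rng.integers(0, 2))
            trial = TrialSpec(block, 0, goal, bonus)
            got = choice_probabilities(params, beliefs, trial)
            want = oracle_choice_probs(
                model_id,
                {k: getattr(params, k) for k in
                 ("beta", "r0", "h", "h_das", "h_other", "b_das")},
                labels,
                {lbl: int(beliefs.gamma[i]) for i, lbl in enumerate(labels)},
                dict(beliefs.observed_sums),
                goal,
                bonus,
                "DDRR",
                design.das_expected_sum,
                true_sums=true_sums_cache[block],
            )
            want_vec = np.array([want[lbl] for lbl in labels])
            assert np.abs(got - want_vec).max() < 1e-10
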