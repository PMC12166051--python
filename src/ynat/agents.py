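"""Simulated cohorts: model-driven agents playing the full 320-trial session.

Each agent holds a :class:`~ynat.models.ModelParams` and samples every
trial's sequence from its model's categorical choice distribution given
its current beliefs, then observes noisy realized points and updates its
beliefs exactly as the likelihood assumes. Simulated agents never time
out; the timeout flag exists only so real participant logs can be
ingested through the same table schema.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .models import ModelParams, choice_probabilities, init_beliefs, observe_trial
from .task import TrialRecord, realized_points, trial_reward

TABLE_COLUMNS = [
    "participant_id", "block", "trial", "trajectory_id", "bonus_block",
    "goal", "sequence", "pts1", "pts2", "pts3", "pts4", "points_total",
    "reward", "bonus_received", "timeout", "rt_ms",
]


def simulate_agent(
    params: ModelParams,
    design: ExperimentDesign,
    rng_seed: int | np.random.Generator,
    participant_id: str = "agent_0",
    noise_sd: float | None = None,
) -> list[TrialRecord]:
    """Play one full session; return one TrialRecord per trial.

    On bonus trials, choosing the DAS yields +20 with probability 0.25;
    the realized bonus enters the reward but never the learned point sum.
    ``noise_sd`` overrides the per-move point noise (None = task default).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    space = design.sequence_space
    beliefs = init_beliefs(design)
    records: list[TrialRecord] = []
    for spec in design.trials():
        probs = choice_probabilities(params, beliefs, spec)
        idx = rng.choice(len(space), p=probs)
        chosen = space.sequences[idx]
        grid = design.blocks[spec.block_index].grid
        kwargs = {} if noise_sd is None else {"noise_sd": noise_sd}
        move_pts, total = realized_points(grid, chosen, rng, **kwargs)
        reward = trial_reward(spec.goal, total)
        bonus = bool(
            spec.bonus_trial
            and chosen.label == design.das.label
            and rng.random() < design.bonus_probability
        )
        if bonus:
            reward += design.bonus_amount
        rec = TrialRecord(
            participant_id=participant_id,
            spec=spec,
            chosen=chosen,
            move_points=tuple(move_pts),
            total_points=total,
            reward=reward,
            bonus_received=bonus,
            timeout=False,
            rt_ms=None,
        )
        observe_trial(beliefs, rec)
        records.append(rec)
    return records


def records_to_frame(
    records: list[TrialRecord], design: ExperimentDesign
) -> pd.DataFrame:
    rows = []
    for r in records:
        block = design.blocks[r.spec.block_index]
        rows.append(
            {
                "participant_id": r.participant_id,
                "block": r.spec.block_index,
                "trial": r.spec.trial_index,
                "trajectory_id": block.trajectory.trajectory_id,
                "bonus_block": block.bonus_block,
                "goal": r.spec.goal,
                "sequence": "" if r.chosen is None else r.chosen.label,
                "pts1": None if r.move_points is None else r.move_points[0],
                "pts2": None if r.move_points is None else r.move_points[1],
                "pts3": None if r.move_points is None else r.move_points[2],
                "pts4": None if r.move_points is None else r.move_points[3],
                "points_total": r.total_points,
                "reward": r.reward,
                "bonus_received": r.bonus_received,
                "timeout": r.timeout,
                "rt_ms": r.rt_ms,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def simulate_cohort(
    cohort_spec: list[tuple[ModelParams, int]],
    design: ExperimentDesign,
    rng_seed: int,
) -> pd.DataFrame:
    """Simulate groups of agents; one tidy table row per trial.

    ``cohort_spec`` is a list of (params, n_agents); per-agent seeds are
    spawned deterministically from the master seed.
    """
    master = np.random.SeedSequence(int(rng_seed))
    frames = []
    agent_no = 0
    for params, n_agents in cohort_spec:
        if n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        for _ in range(n_agents):
            child = np.random.default_rng(master.spawn(1)[0])
            pid = f"{params.model_id.lower()}_{agent_no:03d}"
            recs = simulate_agent(params, design, child, participant_id=pid)
            frames.append(records_to_frame(recs, design))
            agent_no += 1
    return pd.concat(frames, ignore_index=True)
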