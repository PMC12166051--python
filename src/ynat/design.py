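"""Canonical experiment designs for the Y-navigation task.

The full session has 16 blocks of 20 trials (320 trials). A grid layout of
point circles is constant within a block and changes between blocks. One
default action sequence (DAS) is highlighted on every trial; its four
circle values differ across blocks but always sum to the same constant, so
its expected point total is known to the subject throughout.

Goals are stored as offsets from the DAS expected sum. Four goal
trajectories of 20 offsets each are shipped; they differ in the maximum
absolute offset they reach (12, 16, 20 and 24 points) and in its time
course across the block. Every trajectory starts within 5 points of the
DAS sum, and across the whole design exactly 43.75% of trials (140/320)
keep the goal within 5 points of the DAS sum — the window in which the DAS
is among the highest-expected-reward sequences, because circle values
differ by at least 10 points.

Blocks are grouped into 4 segments of 4 blocks; within each segment every
trajectory appears exactly once, no trajectory repeats in consecutive
blocks, and 8 of the 16 blocks carry a probabilistic bonus (+20 with
p = 0.25 when the DAS is chosen), two per trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .task import (
    ALLOWED_CELL_VALUES,
    DEFAULT_START,
    ActionSequence,
    GridLayout,
    SequenceSpace,
    TrialSpec,
    enumerate_sequences,
    path_cells,
    sequence_points,
)

N_BLOCKS = 16
TRIALS_PER_BLOCK = 20
N_SEGMENTS = 4
BLOCKS_PER_SEGMENT = 4
BONUS_AMOUNT = 20
BONUS_PROBABILITY = 0.25
DEFAULT_DAS_LABEL = "DDRR"
DEFAULT_DAS_EXPECTED_SUM = 120

# Goal - DAS offsets per trajectory. Maxima: 24, 16, 20, 12. First two
# entries of each are within +-5. In-window (|offset| <= 5) counts are
# 7, 7, 7 and 14, so four presentations of each give 4*35 = 140 of the
# 320 trials in the window (43.75%).
_TRAJECTORIES: dict[int, tuple[int, ...]] = {
    1: (0, 2, 3, 5, 4, 5, 6, 8, 10, 13, 16, 20, 24, 22, 19, 16, 13, 10, 7, 4),
    2: (1, 3, 5, 5, 9, 11, 13, 15, 16, 16, 15, 14, 13, 12, 11, 9, 7, 5, 3, 2),
    3: (-2, -4, -5, -8, -11, -14, -17, -20, -20, -18, -16, -14, -12, -10,
        -8, -6, -5, -4, -2, 0),
    4: (0, 1, -2, 3, -3, 4, 5, 7, 9, 12, 10, 8, 6, 5, 3, -1, 2, -4, 1, 0),
}

# Trajectory order per segment: each a permutation of 1..4, chosen so no
# id repeats across any block boundary (segment boundaries included).
_SEGMENT_ORDERS = ((1, 2, 3, 4), (2, 4, 1, 3), (4, 3, 2, 1), (3, 1, 4, 2))

# Bonus blocks: two per trajectory id.
_BONUS_BLOCKS = frozenset({0, 11, 4, 15, 2, 9, 5, 14})

# Per-block DAS circle values for the default sum of 120; each quadruple
# sums to 120 and uses only allowed circle values. Cycled twice over the
# 16 blocks, so the DAS circles differ across blocks at constant sum.
_DAS_VALUE_SETS_120 = (
    (30, 30, 30, 30),
    (10, 30, 40, 40),
    (20, 20, 30, 50),
    (60, 10, 40, 10),
    (50, 20, 40, 10),
    (10, 60, 20, 30),
    (40, 40, 20, 20),
    (50, 30, 30, 10),
)


def _das_value_sets(das_expected_sum: int) -> tuple[tuple[int, ...], ...]:
    """Eight DAS-circle quadruples summing to the target, allowed values only."""
    if das_expected_sum == DEFAULT_DAS_EXPECTED_SUM:
        return _DAS_VALUE_SETS_120
    import itertools

    feasible = sorted(
        {
            q
            for q in itertools.product(ALLOWED_CELL_VALUES, repeat=4)
            if sum(q) == das_expected_sum
        }
    )
    if not feasible:
        raise ValueError(
            f"DAS sum {das_expected_sum} not reachable with 4 allowed circle values"
        )
    # spread picks evenly over the sorted feasible list, deterministic
    picks = [feasible[(i * len(feasible)) // 8] for i in range(8)]
    return tuple(picks)


@dataclass(frozen=True)
class GoalTrajectory:
    """20 goal offsets (goal minus DAS expected sum) for one block."""

    trajectory_id: int
    goal_offsets: tuple[int, ...]

    def __post_init__(self):
        if len(self.goal_offsets) != TRIALS_PER_BLOCK:
            raise ValueError("a trajectory holds exactly 20 goal offsets")

    @property
    def max_abs_offset(self) -> int:
        return max(abs(o) for o in self.goal_offsets)

    def goals(self, das_expected_sum: int) -> list[int]:
        return [das_expected_sum + o for o in self.goal_offsets]


def build_goal_trajectory(
    trajectory_id: int, das_expected_sum: int = DEFAULT_DAS_EXPECTED_SUM
) -> GoalTrajectory:
    """Return the shipped canonical trajectory for ``trajectory_id`` (1-4)."""
    if trajectory_id not in _TRAJECTORIES:
        raise ValueError(f"unknown trajectory id {trajectory_id}; expected 1-4")
    return GoalTrajectory(trajectory_id, _TRAJECTORIES[trajectory_id])


def build_grid_layout(
    block_index: int,
    das: ActionSequence | str,
    das_cell_values: tuple[int, int, int, int],
    rng_seed: int,
    start_cell: tuple[int, int] = DEFAULT_START,
    goals: list[int] | None = None,
    das_expected_sum: int | None = None,
    max_attempts: int = 200,
) -> GridLayout:
    """Build a block grid whose DAS-path cells carry the given values.

    Non-DAS cells are drawn uniformly from the allowed circle values with a
    generator seeded by (rng_seed, block_index), so each block gets a
    different but reproducible layout.

    If ``goals`` (the block's 20 trial goals) and ``das_expected_sum`` are
    given, the layout is resampled until every goal further than 5 points
    from the DAS sum admits at least one sequence strictly closer to the
    goal than the DAS — i.e., out-of-window trials always offer a better
    alternative, while in-window trials keep the DAS among the best (the
    latter is automatic because circle values differ in steps of 10).
    """
    if len(das_cell_values) != 4:
        raise ValueError("das_cell_values must hold 4 values")
    for v in das_cell_values:
        if v not in ALLOWED_CELL_VALUES:
            raise ValueError(f"DAS cell value {v} not in allowed set")
    rng = np.random.default_rng([int(rng_seed) % (2**31), int(block_index)])
    cells = path_cells(das, start_cell)
    space = enumerate_sequences(start_cell)
    for _ in range(max_attempts):
        grid = rng.choice(ALLOWED_CELL_VALUES, size=(5, 5))
        for cell, v in zip(cells[1:], das_cell_values):
            grid[cell] = v
        grid[start_cell] = 0
        layout = GridLayout.from_array(grid, start_cell)
        if goals is None:
            return layout
        sums = np.array([sequence_points(layout, s) for s in space])
        ok = all(
            (np.abs(g - sums) < abs(g - das_expected_sum)).any()
            for g in goals
            if abs(g - das_expected_sum) > 5
        )
        if ok:
            return layout
    raise RuntimeError(
        f"block {block_index}: no layout satisfying the better-alternative "
        f"constraint found in {max_attempts} attempts"
    )


@dataclass(frozen=True)
class BlockDesign:
    """Everything one block presents: grid, goals, bonus flag, the DAS."""

    block_index: int
    grid: GridLayout
    trajectory: GoalTrajectory
    bonus_block: bool
    das: ActionSequence
    das_cell_values: tuple[int, int, int, int]
    das_expected_sum: int

    def __post_init__(self):
        if sum(self.das_cell_values) != self.das_expected_sum:
            raise ValueError("DAS cell values must sum to the expected DAS sum")

    def goals(self) -> list[int]:
        return self.trajectory.goals(self.das_expected_sum)


@dataclass(frozen=True)
class ExperimentDesign:
    """The full 16-block session design, identical for every participant."""

    blocks: tuple[BlockDesign, ...]
    das_expected_sum: int
    bonus_probability: float = BONUS_PROBABILITY
    bonus_amount: int = BONUS_AMOUNT
    sequence_space: SequenceSpace = field(default=None, repr=False)

    def __post_init__(self):
        if self.sequence_space is None:
            object.__setattr__(
                self, "sequence_space", enumerate_sequences(self.start_cell)
            )

    @property
    def start_cell(self) -> tuple[int, int]:
        return self.blocks[0].grid.start_cell

    @property
    def das(self) -> ActionSequence:
        return self.blocks[0].das

    @property
    def n_trials(self) -> int:
        return len(self.blocks) * TRIALS_PER_BLOCK

    def segment_of(self, block_index: int) -> int:
        return block_index // BLOCKS_PER_SEGMENT

    def trials(self):
        """Iterate TrialSpec for all trials in session order."""
        for block in self.blocks:
            for t, goal in enumerate(block.goals()):
                yield TrialSpec(
                    block_index=block.block_index,
                    trial_index=t,
                    goal=goal,
                    bonus_trial=block.bonus_block,
                )

    def goal_offsets(self) -> np.ndarray:
        """|goal - DAS expected sum| is the design's central quantity."""
        return np.array(
            [spec.goal - self.das_expected_sum for spec in self.trials()]
        )

    def to_json(self) -> str:
        payload = {
            "das_expected_sum": self.das_expected_sum,
            "bonus_probability": self.bonus_probability,
            "bonus_amount": self.bonus_amount,
            "start_cell": list(self.start_cell),
            "blocks": [
                {
                    "block_index": b.block_index,
                    "trajectory_id": b.trajectory.trajectory_id,
                    "goal_offsets": list(b.trajectory.goal_offsets),
                    "bonus_block": b.bonus_block,
                    "das": b.das.label,
                    "das_cell_values": list(b.das_cell_values),
                    "grid": [list(row) for row in b.grid.cell_values],
                }
                for b in self.blocks
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        d = json.loads(text)
        start = tuple(d["start_cell"])
        blocks = tuple(
            BlockDesign(
                block_index=b["block_index"],
                grid=GridLayout.from_array(b["grid"], start),
                trajectory=GoalTrajectory(
                    b["trajectory_id"], tuple(b["goal_offsets"])
                ),
                bonus_block=b["bonus_block"],
                das=ActionSequence(b["das"]),
                das_cell_values=tuple(b["das_cell_values"]),
                das_expected_sum=d["das_expected_sum"],
            )
            for b in d["blocks"]
        )
        return cls(
            blocks=blocks,
            das_expected_sum=d["das_expected_sum"],
            bonus_probability=d["bonus_probability"],
            bonus_amount=d["bonus_amount"],
        )


def build_default_design(
    das_label: str = DEFAULT_DAS_LABEL,
    das_expected_sum: int = DEFAULT_DAS_EXPECTED_SUM,
    rng_seed: int = 2024,
    start_cell: tuple[int, int] = DEFAULT_START,
) -> ExperimentDesign:
    """Build the canonical 16-block design.

    Deterministic for a given seed and configuration — the same design is
    shown to every (simulated) participant, as in the original study. The
    seed only affects the non-DAS grid cells.
    """
    das = ActionSequence(das_label)
    path_cells(das, start_cell)  # validates the DAS for this start
    value_sets = _das_value_sets(das_expected_sum)
    blocks = []
    for b in range(N_BLOCKS):
        seg, pos = divmod(b, BLOCKS_PER_SEGMENT)
        traj_id = _SEGMENT_ORDERS[seg][pos]
        das_vals = value_sets[b % len(value_sets)]
        traj = build_goal_trajectory(traj_id, das_expected_sum)
        grid = build_grid_layout(
            b, das, das_vals, rng_seed, start_cell,
            goals=traj.goals(das_expected_sum),
            das_expected_sum=das_expected_sum,
        )
        blocks.append(
            BlockDesign(
                block_index=b,
                grid=grid,
                trajectory=traj,
                bonus_block=b in _BONUS_BLOCKS,
                das=das,
                das_cell_values=das_vals,
                das_expected_sum=das_expected_sum,
            )
        )
    return ExperimentDesign(blocks=tuple(blocks), das_expected_sum=das_expected_sum)
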