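"""Grid world, action-sequence space, point collection and the reward rule.

The task is played on a 5x5 grid of point circles. On every trial the player
executes a sequence of four moves drawn from three directions — diagonally
up-left, straight down, diagonally up-right — starting from a fixed start
cell. Moves may not leave the grid and may not revisit any cell (the start
cell included). The trial score is the sum of the four collected circle
values, and the trial reward decreases linearly with the absolute distance
between that score and a trial-specific goal.

Coordinate convention: rows 0-4 top to bottom, columns 0-4 left to right,
so "down" is +1 row. Sequence labels use the alphabet L (up-left),
D (down), R (up-right); the canonical ordering of the sequence space is the
plain ASCII sort of the 4-character labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

GRID_SIZE = 5
SEQ_LENGTH = 4
DEFAULT_START = (2, 2)

#: Allowed circle values: multiples of 10 in [-60, 60], zero excluded.
ALLOWED_CELL_VALUES = tuple(v for v in range(-60, 70, 10) if v != 0)

#: Gaussian noise SD applied to each collected circle's points.
POINT_NOISE_SD = 1.3


class Move(Enum):
    """One of the three permitted movement directions."""

    UP_LEFT = ("L", (-1, -1))
    DOWN = ("D", (1, 0))
    UP_RIGHT = ("R", (-1, 1))

    def __init__(self, letter: str, displacement: tuple[int, int]):
        self.letter = letter
        self.displacement = displacement

    @classmethod
    def from_letter(cls, letter: str) -> "Move":
        for m in cls:
            if m.letter == letter:
                return m
        raise ValueError(f"unknown move letter {letter!r}")


class InvalidSequenceError(ValueError):
    """Raised when a move sequence leaves the grid or revisits a cell."""

    def __init__(self, label: str, move_index: int, reason: str):
        self.label = label
        self.move_index = move_index
        super().__init__(
            f"sequence {label!r} invalid at move {move_index}: {reason}"
        )


@dataclass(frozen=True)
class ActionSequence:
    """An ordered 4-tuple of moves — the unit of choice (policy)."""

    label: str

    def __post_init__(self):
        if len(self.label) != SEQ_LENGTH or any(
            c not in "LDR" for c in self.label
        ):
            raise ValueError(f"label must be 4 chars over L/D/R, got {self.label!r}")

    @property
    def moves(self) -> tuple[Move, ...]:
        return tuple(Move.from_letter(c) for c in self.label)

    def __str__(self) -> str:
        return self.label


def path_cells(
    seq: ActionSequence | str, start_cell: tuple[int, int] = DEFAULT_START
) -> list[tuple[int, int]]:
    """Trace a sequence from ``start_cell``; return the 5 visited cells.

    Raises :class:`InvalidSequenceError` naming the offending move index
    (0-based) if the path leaves the grid or revisits a cell.
    """
    label = seq.label if isinstance(seq, ActionSequence) else seq
    r, c = start_cell
    cells = [(r, c)]
    visited = {(r, c)}
    for i, letter in enumerate(label):
        dr, dc = Move.from_letter(letter).displacement
        r, c = r + dr, c + dc
        if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
            raise InvalidSequenceError(label, i, f"cell ({r},{c}) out of bounds")
        if (r, c) in visited:
            raise InvalidSequenceError(label, i, f"cell ({r},{c}) revisited")
        visited.add((r, c))
        cells.append((r, c))
    return cells


def is_valid_sequence(
    label: str, start_cell: tuple[int, int] = DEFAULT_START
) -> bool:
    try:
        path_cells(label, start_cell)
    except (InvalidSequenceError, ValueError):
        return False
    return True


@dataclass(frozen=True)
class SequenceSpace:
    """All valid four-move sequences from a start cell, in canonical order.

    Canonical order is the ASCII sort of labels, so probability vectors over
    the space are comparable across runs and implementations.
    """

    start_cell: tuple[int, int]
    sequences: tuple[ActionSequence, ...]
    index: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ActionSequence]:
        return iter(self.sequences)

    def __contains__(self, item: ActionSequence | str) -> bool:
        label = item.label if isinstance(item, ActionSequence) else item
        return label in self.index

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sequences]


def enumerate_sequences(
    start_cell: tuple[int, int] = DEFAULT_START,
) -> SequenceSpace:
    """Enumerate every valid 4-move sequence from ``start_cell``.

    Scans all 3^4 = 81 raw move strings and keeps those that stay in bounds
    without revisiting any cell. From the grid center this yields exactly 36
    sequences.
    """
    labels = sorted(
        "".join(p)
        for p in itertools.product("DLR", repeat=SEQ_LENGTH)
        if is_valid_sequence("".join(p), start_cell)
    )
    seqs = tuple(ActionSequence(lbl) for lbl in labels)
    return SequenceSpace(
        start_cell=start_cell,
        sequences=seqs,
        index={lbl: i for i, lbl in enumerate(labels)},
    )


@dataclass(frozen=True)
class GridLayout:
    """A 5x5 matrix of circle point values plus the start cell.

    The start cell carries no collectible circle (no valid sequence can
    revisit it) and is stored as 0.
    """

    cell_values: tuple[tuple[int, ...], ...]
    start_cell: tuple[int, int] = DEFAULT_START

    def __post_init__(self):
        arr = np.asarray(self.cell_values)
        if arr.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"grid must be 5x5, got {arr.shape}")
        for (r, c), v in np.ndenumerate(arr):
            if (r, c) == tuple(self.start_cell):
                continue
            if int(v) not in ALLOWED_CELL_VALUES:
                raise ValueError(
                    f"cell ({r},{c}) value {v} not in allowed set "
                    f"(multiples of 10 in [-60,60], nonzero)"
                )

    @classmethod
    def from_array(cls, arr, start_cell=DEFAULT_START) -> "GridLayout":
        return cls(
            cell_values=tuple(tuple(int(v) for v in row) for row in arr),
            start_cell=tuple(start_cell),
        )

    def value_at(self, cell: tuple[int, int]) -> int:
        return self.cell_values[cell[0]][cell[1]]

    def to_array(self) -> np.ndarray:
        return np.asarray(self.cell_values, dtype=int)


def sequence_points(grid: GridLayout, seq: ActionSequence | str) -> int:
    """Noiseless point sum along a sequence's path (start cell excluded)."""
    cells = path_cells(seq, grid.start_cell)
    return int(sum(grid.value_at(c) for c in cells[1:]))


def realized_points(
    grid: GridLayout,
    seq: ActionSequence | str,
    rng: np.random.Generator | int,
    noise_sd: float = POINT_NOISE_SD,
) -> tuple[list[int], int]:
    """Collect points along a path with per-move Gaussian noise.

    Each move's points are the circle value plus a Normal(0, ``noise_sd``)
    draw rounded to the nearest integer (half away from zero). Returns the
    four per-move point values and their total.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    cells = path_cells(seq, grid.start_cell)
    pts = []
    for cell in cells[1:]:
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        v = grid.value_at(cell) + noise
        # round half away from zero — symmetric for pos/neg circle values
        pts.append(int(np.sign(v) * np.floor(abs(v) + 0.5)))
    return pts, int(sum(pts))


def trial_reward(goal: int, points: int) -> int:
    """Trial reward: max(0, 100 - 2*|goal - points|), in [0, 100]."""
    return max(0, 100 - 2 * abs(int(goal) - int(points)))


def is_das_optimal(goal: int, das_expected_sum: int) -> bool:
    """True iff the default sequence is within 5 points of the goal.

    Because circle values differ by at least 10 points, a goal within 5
    points of the default sequence's expected sum makes the default one of
    the highest-expected-reward sequences available.
    """
    return abs(int(goal) - int(das_expected_sum)) <= 5


class SequenceClass(str, Enum):
    DAS = "DAS"
    PARTIAL_DAS = "PARTIAL_DAS"
    INDEPENDENT = "INDEPENDENT"


def classify_sequence(
    seq: ActionSequence | str, das: ActionSequence | str
) -> SequenceClass:
    """Classify a chosen sequence relative to the default action sequence.

    DAS if identical; PARTIAL_DAS if it starts with the default's first
    move but differs somewhere; INDEPENDENT otherwise.
    """
    s = seq.label if isinstance(seq, ActionSequence) else seq
    d = das.label if isinstance(das, ActionSequence) else das
    if s == d:
        return SequenceClass.DAS
    if s[0] == d[0]:
        return SequenceClass.PARTIAL_DAS
    return SequenceClass.INDEPENDENT


@dataclass(frozen=True)
class TrialSpec:
    """What the subject faces on one trial."""

    block_index: int
    trial_index: int
    goal: int
    bonus_trial: bool


@dataclass
class TrialRecord:
    """One completed (or timed-out) trial of one participant."""

    participant_id: str
    spec: TrialSpec
    chosen: ActionSequence | None
    move_points: tuple[int, int, int, int] | None
    total_points: int | None
    reward: int
    bonus_received: bool
    timeout: bool = False
    rt_ms: float | None = None
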