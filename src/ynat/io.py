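"""Tabular and JSON file formats binding the pipeline together.

One tabular dialect: comma-separated, UTF-8, "." decimal. Participant
tables use the documented column schema (see ``agents.TABLE_COLUMNS``);
designs serialize to JSON; run configurations to YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .agents import TABLE_COLUMNS
from .design import ExperimentDesign
from .task import ActionSequence, TrialRecord, TrialSpec

REQUIRED_COLUMNS = [
    c for c in TABLE_COLUMNS if c not in ("rt_ms", "trajectory_id")
]


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    Path(path).write_text(design.to_json())


def read_design(path: str | Path) -> ExperimentDesign:
    return ExperimentDesign.from_json(Path(path).read_text())


def write_participant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def frame_to_records(
    df: pd.DataFrame, design: ExperimentDesign
) -> dict[str, list[TrialRecord]]:
    """Validate a participant table and split it into per-participant records.

    Rows are normalized to (participant, block, trial) order. Sequence
    labels are checked against the design's sequence space; timed-out rows
    may leave the sequence empty. Errors carry the offending row number
    (0-based, in the incoming frame).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    space = design.sequence_space
    out: dict[str, list[TrialRecord]] = {}
    df = df.reset_index().rename(columns={"index": "_row"})
    df = df.sort_values(["participant_id", "block", "trial"])
    for pid, sub in df.groupby("participant_id", sort=True):
        expected = [
            (b, t)
            for b in range(len(design.blocks))
            for t in range(len(design.blocks[0].trajectory.goal_offsets))
        ]
        got = list(zip(sub["block"].astype(int), sub["trial"].astype(int)))
        if got != expected:
            first_bad = next(
                (i for i, (g, e) in enumerate(zip(got, expected)) if g != e),
                min(len(got), len(expected)),
            )
            row = int(sub["_row"].iloc[min(first_bad, len(sub) - 1)])
            raise ValueError(
                f"participant {pid}: non-contiguous block/trial order near "
                f"input row {row}"
            )
        records = []
        for _, r in sub.iterrows():
            timeout = bool(r["timeout"])
            label = "" if pd.isna(r["sequence"]) else str(r["sequence"])
            if not timeout and label not in space:
                raise ValueError(
                    f"row {int(r['_row'])}: sequence {label!r} not in the "
                    f"sequence space"
                )
            spec = TrialSpec(
                block_index=int(r["block"]),
                trial_index=int(r["trial"]),
                goal=int(r["goal"]),
                bonus_trial=bool(r["bonus_block"]),
            )
            records.append(
                TrialRecord(
                    participant_id=str(pid),
                    spec=spec,
                    chosen=None if timeout else ActionSequence(label),
                    move_points=(
                        None
                        if timeout
                        else tuple(int(r[f"pts{i}"]) for i in range(1, 5))
                    ),
                    total_points=None if timeout else int(r["points_total"]),
                    reward=int(r["reward"]),
                    bonus_received=bool(r["bonus_received"]),
                    timeout=timeout,
                    rt_ms=(
                        float(r["rt_ms"])
                        if "rt_ms" in r and pd.notna(r["rt_ms"])
                        else None
                    ),
                )
            )
        out[str(pid)] = records
    return out


def read_participant_table(
    path: str | Path, design: ExperimentDesign
) -> dict[str, list[TrialRecord]]:
    return frame_to_records(pd.read_csv(path), design)
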