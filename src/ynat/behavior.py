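"""Summary behavioral measures and posterior predictive checks.

Works on the tidy participant table (one row per trial). All proportions
are computed over completed (non-timeout) trials. The session's 320
trials split into halves (trials 1-160 / 161-320 by session order) and
four segments of four blocks each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BLOCKS_PER_SEGMENT, ExperimentDesign
from .model import ChoiceModelResults
from .models import choice_probabilities, init_beliefs
from .task import SequenceClass, classify_sequence, is_das_optimal

#: A participant whose modal sequence exceeds this share of completed
#: trials is flagged for exclusion (insufficient behavioral variability).
EXCLUSION_MODAL_SHARE = 0.90


@dataclass
class ParticipantSummary:
    participant_id: str
    p_das: float
    p_das_per_half: tuple[float, float]
    p_das_per_segment: tuple[float, ...]
    p_das_bonus: float
    p_das_no_bonus: float
    p_das_optimal: float          # p(DAS) on trials where the DAS is optimal
    p_das_not_optimal: float
    p_partial_das_per_half: tuple[float, float]   # includes DAS trials
    p_partial_das_per_segment: tuple[float, ...]
    n_distinct_per_half: tuple[int, int]
    n_distinct_per_segment: tuple[int, ...]
    mean_reward_per_half: tuple[float, float]
    n_timeouts: int
    excluded: bool
    extras: dict = field(default_factory=dict)


def _prop(mask: pd.Series, universe: pd.Series) -> float:
    n = int(universe.sum())
    return float((mask & universe).sum() / n) if n else float("nan")


def summarize_participant(
    df: pd.DataFrame, design: ExperimentDesign
) -> ParticipantSummary:
    """Compute one participant's summary measures from their trial table."""
    pid = df["participant_id"].iloc[0]
    df = df.sort_values(["block", "trial"]).reset_index(drop=True)
    if len(df) != design.n_trials:
        raise ValueError(
            f"participant {pid}: expected {design.n_trials} rows, got {len(df)}"
        )
    das = design.das.label
    done = ~df["timeout"].astype(bool)
    is_das = (df["sequence"] == das) & done
    cls = df["sequence"].where(done, None).map(
        lambda s: classify_sequence(s, das) if s else None
    )
    partial_incl = cls.isin([SequenceClass.DAS, SequenceClass.PARTIAL_DAS]) & done

    session_pos = np.arange(len(df))
    half = session_pos >= design.n_trials // 2
    segment = df["block"].values // BLOCKS_PER_SEGMENT
    das_opt = df["goal"].map(
        lambda g: is_das_optimal(g, design.das_expected_sum)
    )
    bonus = df["bonus_block"].astype(bool)

    def halves(mask):
        return (
            _prop(mask, done & ~half),
            _prop(mask, done & half),
        )

    def segments(mask):
        return tuple(_prop(mask, done & (segment == s)) for s in range(4))

    def distinct(universe):
        vals = df.loc[universe & done, "sequence"].unique()
        return int(len(vals))

    counts = df.loc[done, "sequence"].value_counts()
    modal_share = float(counts.iloc[0] / counts.sum()) if len(counts) else 0.0

    return ParticipantSummary(
        participant_id=pid,
        p_das=_prop(is_das, done),
        p_das_per_half=halves(is_das),
        p_das_per_segment=segments(is_das),
        p_das_bonus=_prop(is_das, done & bonus),
        p_das_no_bonus=_prop(is_das, done & ~bonus),
        p_das_optimal=_prop(is_das, done & das_opt),
        p_das_not_optimal=_prop(is_das, done & ~das_opt),
        p_partial_das_per_half=halves(partial_incl),
        p_partial_das_per_segment=segments(partial_incl),
        n_distinct_per_half=(distinct(~half), distinct(half)),
        n_distinct_per_segment=tuple(
            distinct(segment == s) for s in range(4)
        ),
        mean_reward_per_half=(
            float(df.loc[done & ~half, "reward"].mean()),
            float(df.loc[done & half, "reward"].mean()),
        ),
        n_timeouts=int(df["timeout"].astype(bool).sum()),
        excluded=modal_share > EXCLUSION_MODAL_SHARE,
    )


def summaries_frame(
    table: pd.DataFrame, design: ExperimentDesign
) -> pd.DataFrame:
    """Tidy per-participant summary table (one row per participant)."""
    rows = []
    for pid, sub in table.groupby("participant_id", sort=True):
        s = summarize_participant(sub, design)
        rows.append(
            {
                "participant_id": pid,
                "p_das": s.p_das,
                "p_das_h1": s.p_das_per_half[0],
                "p_das_h2": s.p_das_per_half[1],
                **{f"p_das_seg{i+1}": v for i, v in enumerate(s.p_das_per_segment)},
                "p_das_bonus": s.p_das_bonus,
                "p_das_no_bonus": s.p_das_no_bonus,
                "p_das_optimal": s.p_das_optimal,
                "p_das_not_optimal": s.p_das_not_optimal,
                "p_partial_h1": s.p_partial_das_per_half[0],
                "p_partial_h2": s.p_partial_das_per_half[1],
                "n_distinct_h1": s.n_distinct_per_half[0],
                "n_distinct_h2": s.n_distinct_per_half[1],
                "mean_reward_h1": s.mean_reward_per_half[0],
                "mean_reward_h2": s.mean_reward_per_half[1],
                "n_timeouts": s.n_timeouts,
                "excluded": s.excluded,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PpcReport:
    participant_id: str
    n_agents: int
    match_overall: float
    match_das_trials: float
    match_non_das_trials: float
    chance_level: float


def ppc_match(
    fit: ChoiceModelResults,
    records,
    design: ExperimentDesign,
    n_agents: int = 1000,
    rng_seed: int = 0,
) -> PpcReport:
    """Posterior predictive check: proportion of correctly predicted choices.

    For each simulated agent, parameters are drawn from the fit's
    posterior (the mode for point fits) and a choice is sampled on every
    completed trial from the model's distribution given the participant's
    own history up to that trial. A predicted choice is "correct" iff its
    4-move label equals the observed one. Rates are reported overall and
    separately for observed-DAS vs other trials, next to the 1/36 chance
    level.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    rng = np.random.default_rng(rng_seed)
    space = design.sequence_space
    beliefs = init_beliefs(design)
    das = design.das.label

    from .models import observe_trial

    probs_rows, observed = [], []
    for rec in sorted(records, key=lambda r: (r.spec.block_index, r.spec.trial_index)):
        if rec.timeout:
            continue
        observed.append(rec.chosen.label)
        probs_rows.append((beliefs.copy(), rec.spec))
        observe_trial(beliefs, rec)

    n_trials = len(observed)
    matches = np.zeros((n_agents, n_trials), dtype=bool)
    for a in range(n_agents):
        params = fit.sample_params(rng)
        for t, (bel, spec) in enumerate(probs_rows):
            p = choice_probabilities(params, bel, spec)
            pick = space.sequences[rng.choice(len(space), p=p)].label
            matches[a, t] = pick == observed[t]

    obs = np.array(observed)
    das_mask = obs == das
    return PpcReport(
        participant_id=records[0].participant_id,
        n_agents=n_agents,
        match_overall=float(matches.mean()),
        match_das_trials=(
            float(matches[:, das_mask].mean()) if das_mask.any() else float("nan")
        ),
        match_non_das_trials=(
            float(matches[:, ~das_mask].mean()) if (~das_mask).any() else float("nan")
        ),
        chance_level=1.0 / len(space),
    )
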