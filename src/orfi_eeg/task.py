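"""Deterministic reversal-learning task: schedules, simulated agents, scoring.

Each block has 240 trials in which one of two squares hides the target
object.  The outcome behind the chosen square is SAME (the anticipated
target), SIMI (a semantically similar object) or DIFF (an unrelated
object).  SIMI/DIFF outcomes occur after every 2–6 consecutive SAME trials
(180 SAME, 30 SIMI, 30 DIFF per block).  Behavioral meaning depends on the
condition: DIFF always signals a switch of the correct square on the next
trial; SIMI signals a switch only in the "identical" condition (where the
target is one specific object), not in the "semantical" condition (where
any object of the category counts).

An error trial reveals the unrelated DIFF object ("the target failed to
appear"), which acts as a switch signal for the state machine; scheduled
SIMI/DIFF slots are attached to the correct square and are not consumed by
error reveals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("identical", "semantical")
OUTCOMES = ("SAME", "SIMI", "DIFF")

N_TRIALS = 240
N_SAME, N_SIMI, N_DIFF = 180, 30, 30
RUN_RANGE = (2, 6)

#: The six object triplets (principal target, similar object, unrelated object).
OBJECT_TRIPLETS = (
    ("crown", "crown'", "lettuce"),
    ("drum", "drum'", "pumpkin"),
    ("flower", "flower'", "tie"),
    ("hat", "hat'", "cake"),
    ("mushroom", "mushroom'", "stool"),
    ("owl", "owl'", "barrel"),
)


def is_switch_signal(outcome: str, condition: str) -> bool:
    """Does this outcome instruct a switch of square on the next trial?"""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    return outcome == "DIFF" or (outcome == "SIMI" and condition == "identical")


@dataclass
class TrialSchedule:
    """One 240-trial block: outcome category and correct square per trial."""

    condition: str
    outcomes: list[str]  # outcome behind the *correct* square, per trial
    correct_square: list[str]  # "left" | "right"
    block_id: int = 0
    object_triplet: tuple[str, str, str] = OBJECT_TRIPLETS[0]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.outcomes) != len(self.correct_square):
            raise ValueError("outcomes and correct_square must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.outcomes)

    def same_run_lengths(self) -> list[int]:
        """Lengths of consecutive-SAME runs before each non-SAME outcome."""
        runs, run = [], 0
        for out in self.outcomes:
            if out == "SAME":
                run += 1
            else:
                runs.append(run)
                run = 0
        return runs


def _sample_run_lengths(n_runs: int, total: int, rng: np.random.Generator) -> np.ndarray:
    """n_runs integers in [2, 6] summing to total, sampled uniformly then repaired."""
    lo, hi = RUN_RANGE
    runs = rng.integers(lo, hi + 1, size=n_runs)
    # repair the sum by unit moves that keep every run inside [lo, hi]
    while runs.sum() != total:
        delta = total - runs.sum()
        cand = np.flatnonzero(runs < hi) if delta > 0 else np.flatnonzero(runs > lo)
        runs[rng.choice(cand)] += int(np.sign(delta))
    return runs


def generate_block(
    condition: str,
    seed: int,
    block_id: int = 0,
    object_triplet: tuple[str, str, str] | None = None,
) -> TrialSchedule:
    """Generate one block satisfying the design's composition and run constraints."""
    rng = np.random.default_rng(seed)
    n_nonsame = N_SIMI + N_DIFF
    runs = _sample_run_lengths(n_nonsame, N_SAME, rng)
    nonsame = np.array(["SIMI"] * N_SIMI + ["DIFF"] * N_DIFF)
    rng.shuffle(nonsame)
    outcomes: list[str] = []
    for run, out in zip(runs, nonsame):
        outcomes.extend(["SAME"] * int(run))
        outcomes.append(str(out))
    assert len(outcomes) == N_TRIALS

    # correct square flips on the trial after every switch-signalling outcome
    square = "left" if rng.integers(2) else "right"
    correct = []
    for out in outcomes:
        correct.append(square)
        if is_switch_signal(out, condition):
            square = "right" if square == "left" else "left"
    if object_triplet is None:
        object_triplet = OBJECT_TRIPLETS[int(rng.integers(len(OBJECT_TRIPLETS)))]
    return TrialSchedule(condition, outcomes, correct, block_id, object_triplet)


@dataclass
class AgentPolicy:
    """Stochastic rule-follower standing in for a human subject.

    lapse_rate: probability of a uniformly random choice on any trial.
    perseveration_rate: probability of repeating the previous square when a
        switch was signalled (producing extinction errors).
    rt_lognormal: per previous-outcome-category (mean_ms, sd_ms) of a
        log-normal reaction-time model; the ``"none"`` entry covers the
        first trial of a block.
    """

    lapse_rate: float = 0.02
    perseveration_rate: float = 0.07
    rt_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SAME": (470.0, 140.0),
            "SIMI": (468.0, 150.0),
            "DIFF": (490.0, 160.0),
            "none": (600.0, 200.0),
        }
    )

    def __post_init__(self) -> None:
        for p in (self.lapse_rate, self.perseveration_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("policy probabilities must be in [0, 1]")


def _lognormal_ms(mean: float, sd: float, rng: np.random.Generator) -> float:
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(s2)))


def simulate_agent(schedule: TrialSchedule, policy: AgentPolicy, seed: int) -> pd.DataFrame:
    """Simulate choices/RTs for one block.

    Returns a behavior log with one row per trial: ``trial, block, condition,
    outcome`` (shown outcome), ``choice, correct, rt_ms``.  The shown outcome
    is the scheduled one when the choice is correct and DIFF (absence of the
    target) otherwise.
    """
    rng = np.random.default_rng(seed)
    cond = schedule.condition
    rows = []
    prev_choice: str | None = None
    prev_shown: str | None = None
    for t in range(schedule.n_trials):
        if prev_choice is None:
            choice = "left" if rng.integers(2) else "right"
        else:
            switch = is_switch_signal(prev_shown, cond)
            if switch:
                choice = (
                    prev_choice
                    if rng.random() < policy.perseveration_rate
                    else ("right" if prev_choice == "left" else "left")
                )
            else:
                choice = prev_choice
            if rng.random() < policy.lapse_rate:
                choice = "left" if rng.integers(2) else "right"
        correct = choice == schedule.correct_square[t]
        shown = schedule.outcomes[t] if correct else "DIFF"
        mean, sd = policy.rt_lognormal.get(prev_shown or "none", policy.rt_lognormal["none"])
        rows.append(
            dict(
                trial=t,
                block=schedule.block_id,
                condition=cond,
                outcome=shown,
                choice=choice,
                correct=correct,
                rt_ms=_lognormal_ms(mean, sd, rng),
            )
        )
        prev_choice, prev_shown = choice, shown
    return pd.DataFrame(rows)


@dataclass
class BehaviorSummary:
    """Accuracy and error decomposition for one block's (or condition's) log."""

    condition: str
    pct_correct: float
    #: % of stay-opportunity trials (previous outcome correct and signalling
    #: "stay") on which the subject switched squares anyway
    association_error_rate: float
    #: % of switch-opportunity trials (previous outcome signalled a reversal)
    #: on which the subject kept the old, now incorrect square
    extinction_error_rate: float
    n_trials: int
    n_extinction: int
    n_association: int
    n_switch_opportunities: int
    n_stay_opportunities: int
    rt_by_cell: pd.DataFrame | None = None  # per previous-outcome RT (correct trials only)


def score_behavior(schedule: TrialSchedule, log: pd.DataFrame) -> BehaviorSummary:
    """Score one block's log with the task's error definitions.

    Extinction error: the subject continued to choose the (now incorrect)
    previous square after a reversal was signalled.  Association error: the
    subject switched squares although the previous outcome was correct and
    signalled "stay".  Error rates are expressed relative to their
    opportunity trials (reversal-signalled and stay-signalled trials,
    respectively); with near-ceiling accuracy an all-trials denominator
    could not produce extinction rates several times the total error rate.
    """
    if len(log) != schedule.n_trials:
        raise ValueError(f"log has {len(log)} rows but schedule has {schedule.n_trials} trials")
    cond = schedule.condition
    correct = log["correct"].to_numpy(dtype=bool)
    choice = log["choice"].to_numpy()
    shown = log["outcome"].to_numpy()
    n = len(log)
    n_ext = n_assoc = n_switch_opp = n_stay_opp = 0
    for t in range(1, n):
        prev_switch = is_switch_signal(shown[t - 1], cond)
        stayed = choice[t] == choice[t - 1]
        if prev_switch:
            n_switch_opp += 1
            if stayed and not correct[t]:
                n_ext += 1
        elif correct[t - 1]:
            n_stay_opp += 1
            if not stayed and not correct[t]:
                n_assoc += 1

    # RT per previous-outcome category, correct trials only
    prev_out = np.r_[["none"], shown[:-1]]
    mask = correct & (prev_out != "none")
    rt = pd.DataFrame({"prev_outcome": prev_out[mask], "rt_ms": log["rt_ms"].to_numpy()[mask]})
    rt_cells = rt.groupby("prev_outcome")["rt_ms"].agg(["mean", "std", "count"]).reset_index()
    rt_cells.insert(0, "condition", cond)

    return BehaviorSummary(
        condition=cond,
        pct_correct=100.0 * correct.mean(),
        association_error_rate=100.0 * n_assoc / max(n_stay_opp, 1),
        extinction_error_rate=100.0 * n_ext / max(n_switch_opp, 1),
        n_trials=n,
        n_extinction=n_ext,
        n_association=n_assoc,
        n_switch_opportunities=n_switch_opp,
        n_stay_opportunities=n_stay_opp,
        rt_by_cell=rt_cells,
    )


def write_log_tsv(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, sep="\t", index=False)


def read_log_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
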