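"""Behavioral scoring and compliance testing.

Task C (counting): the answer is the number of targets.
Task A (arithmetic): add ten per target and one per distractor.
Task M (memory): the answer is the list of target grid positions.

Compliance with the instructions is assessed per participant and condition
by comparing observed answer accuracy against a randomization null:
distances between correct and entered numbers versus distances under
shuffled pairings (C, A), and position accuracies versus accuracies with
targets moved to random grid cells (M); both compared with one-sided
Mann-Whitney U tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import StimulusEvent

logger = logging.getLogger(__name__)

Position = tuple[int, int]


@dataclass
class BehavioralRecord:
    """One answered task repetition."""

    condition: str
    repetition_index: int
    correct: int | list[Position]
    entered: int | list[Position]

    @property
    def distance(self) -> float:
        return distance(self.correct, self.entered, self.condition)


def score_correct(events: list[StimulusEvent], condition: str) -> int | list[Position]:
    """Correct answer for one repetition's stimulus sequence.

    C -> number of targets; A -> 10 * targets + 1 * distractors; M ->
    target grid positions in order of appearance.
    """
    n_targets = sum(ev.is_target for ev in events)
    if condition == "C":
        return n_targets
    if condition == "A":
        return 10 * n_targets + (len(events) - n_targets)
    if condition == "M":
        return [(ev.grid_row, ev.grid_col) for ev in events if ev.is_target]
    raise ValueError(f"unknown condition {condition!r}")


def distance(correct, entered, condition: str) -> float:
    """Answer error: |correct - entered| for C and A; for M, 1 - accuracy
    where accuracy is the fraction of true target positions matched
    (unordered set overlap, denominator = number of true targets)."""
    if condition in ("C", "A"):
        return abs(float(correct) - float(entered))
    if condition == "M":
        return 1.0 - position_accuracy(correct, entered)
    raise ValueError(f"unknown condition {condition!r}")


def position_accuracy(correct: list[Position], entered: list[Position],
                      denominator: str = "targets") -> float:
    """Fraction of correct target positions selected.

    ``denominator='targets'`` (default) divides the overlap by the number of
    true targets; ``'entered'`` divides by the number of entered positions.
    """
    correct_set = {tuple(p) for p in correct}
    entered_set = {tuple(p) for p in entered}
    if denominator == "targets":
        denom = len(correct_set)
    elif denominator == "entered":
        denom = len(entered_set)
    else:
        raise ValueError("denominator must be 'targets' or 'entered'")
    if denom == 0:
        return 1.0 if not entered_set else 0.0
    return len(correct_set & entered_set) / denom


def _null_distances_numeric(correct: np.ndarray, entered: np.ndarray,
                            n_shuffles: int, rng: np.random.Generator) -> np.ndarray:
    """Distances after shuffling the pairing between correct and entered."""
    out = np.empty((n_shuffles, correct.size))
    for s in range(n_shuffles):
        out[s] = np.abs(correct - rng.permutation(entered))
    return out.ravel()


def _null_accuracies_positions(records: list[BehavioralRecord], grid_size: int,
                               n_shuffles: int, rng: np.random.Generator) -> np.ndarray:
    """Accuracies of the entered positions against targets moved to random
    grid cells (uniform without replacement within a repetition)."""
    cells = [(r, c) for r in range(1, grid_size + 1) for c in range(1, grid_size + 1)]
    cells = np.array(cells)
    out = np.empty((n_shuffles, len(records)))
    for s in range(n_shuffles):
        for i, rec in enumerate(records):
            k = min(len(rec.correct), len(cells))
            idx = rng.choice(len(cells), size=k, replace=False)
            random_targets = [tuple(cells[j]) for j in idx]
            out[s, i] = position_accuracy(random_targets, rec.entered)
    return out.ravel()


def permutation_null_test(
    records: list[BehavioralRecord],
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    grid_size: int = 5,
) -> dict:
    """Test whether answers beat a randomization null (one participant,
    one condition).

    For C and A, observed |correct - entered| distances are compared against
    distances under ``n_shuffles`` random re-pairings of correct and entered
    numbers (one-sided Mann-Whitney U: observed smaller).  For M, observed
    position accuracies are compared against accuracies with targets placed
    at random grid cells (one-sided: observed greater).

    Returns a dict with the p-value, U statistic, observed and null means.
    """
    if len(records) < 2:
        raise ValueError("at least two answered repetitions are required")
    conditions = {r.condition for r in records}
    if len(conditions) != 1:
        raise ValueError("records must come from a single condition")
    condition = conditions.pop()
    if n_shuffles < 50:
        logger.warning(
            "n_shuffles=%d gives an unreliable null distribution", n_shuffles
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if condition in ("C", "A"):
        correct = np.array([float(r.correct) for r in records])
        entered = np.array([float(r.entered) for r in records])
        observed = np.abs(correct - entered)
        null = _null_distances_numeric(correct, entered, n_shuffles, rng)
        alternative = "less"
    else:
        observed = np.array([position_accuracy(r.correct, r.entered) for r in records])
        null = _null_accuracies_positions(records, grid_size, n_shuffles, rng)
        alternative = "greater"

    if np.ptp(observed) == 0 and np.ptp(null) == 0 and observed[0] == null[0]:
        # degenerate: identical constant samples, no evidence either way
        return {
            "condition": condition, "p_value": 1.0, "statistic": np.nan,
            "observed_mean": float(observed.mean()), "null_mean": float(null.mean()),
            "n_observed": observed.size, "n_null": null.size,
        }
    res = stats.mannwhitneyu(observed, null, alternative=alternative)
    return {
        "condition": condition,
        "p_value": float(res.pvalue),
        "statistic": float(res.statistic),
        "observed_mean": float(observed.mean()),
        "null_mean": float(null.mean()),
        "n_observed": observed.size,
        "n_null": null.size,
    }


def evaluate_answers(
    answers: list[BehavioralRecord],
    n_shuffles: int = 1000,
    seed: int = 0,
    grid_size: int = 5,
) -> dict[str, dict]:
    """Run the permutation null test per condition over a participant's records."""
    out: dict[str, dict] = {}
    for condition in sorted({r.condition for r in answers}):
        recs = [r for r in answers if r.condition == condition]
        out[condition] = permutation_null_test(
            recs, n_shuffles=n_shuffles, seed=seed, grid_size=grid_size
        )
    return out
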