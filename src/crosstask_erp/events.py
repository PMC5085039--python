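"""Stimulus sequences of the color-oddball task.

Each task repetition presents 47-50 colored squares one by one in a 5x5
grid (500 ms flash + 500 ms blank, i.e. 1000 ms stimulus-onset asynchrony).
Five colors are equiprobable; one color, drawn afresh per repetition, is the
target.  Color assignments are rejection-sampled until the number of targets
falls in the printed range of 8-13.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONDITIONS: tuple[str, ...] = ("C", "A", "M")

#: Display color names, index 0-4.  Magenta is index 0 (the worked example's
#: target color).
COLOR_NAMES: tuple[str, ...] = ("magenta", "yellow", "red", "blue", "green")

SOA_MS = 1000  # 500 ms flash + 500 ms blank


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent design parameters."""


@dataclass(frozen=True)
class StimulusEvent:
    """One flashed square."""

    onset_ms: int
    color_index: int
    grid_row: int
    grid_col: int
    is_target: bool
    condition: str
    repetition_index: int
    within_repetition_index: int


@dataclass(frozen=True)
class SequenceDesign:
    """Constraints of one stimulus sequence (a task repetition)."""

    n_colors: int = 5
    n_stimuli_range: tuple[int, int] = (47, 50)
    target_count_range: tuple[int, int] = (8, 13)
    n_repetitions_per_condition: int = 20
    grid_size: int = 5

    def validate(self) -> None:
        lo, hi = self.n_stimuli_range
        tlo, thi = self.target_count_range
        if self.n_colors < 2:
            raise ConfigurationError(
                "at least two colors are required (one target, one distractor)"
            )
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid stimulus-count range {self.n_stimuli_range}")
        if not (0 <= tlo <= thi):
            raise ConfigurationError(f"invalid target-count range {self.target_count_range}")
        if tlo > hi:
            raise ConfigurationError(
                "minimum target count exceeds maximum sequence length; "
                f"{self.target_count_range} is infeasible for {self.n_stimuli_range}"
            )
        if self.grid_size < 1:
            raise ConfigurationError("grid_size must be >= 1")
        if self.n_repetitions_per_condition < 1:
            raise ConfigurationError("n_repetitions_per_condition must be >= 1")


def generate_sequence(
    design: SequenceDesign,
    condition: str,
    repetition_index: int,
    seed: int | np.random.Generator,
    start_ms: int = 0,
) -> list[StimulusEvent]:
    """Draw one pseudo-random stimulus sequence.

    Sequence length is uniform over ``n_stimuli_range``; colors are i.i.d.
    uniform over the ``n_colors`` colors and redrawn until the count of the
    repetition's (uniformly drawn) target color lies in
    ``target_count_range``; grid cells are drawn uniformly per stimulus.
    Onsets are spaced by the 1000 ms stimulus-onset asynchrony starting at
    ``start_ms``.
    """
    design.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(rng.integers(design.n_stimuli_range[0], design.n_stimuli_range[1] + 1))
    target_color = int(rng.integers(design.n_colors))
    tlo, thi = design.target_count_range
    for _ in range(100_000):
        colors = rng.integers(design.n_colors, size=n)
        n_targets = int(np.sum(colors == target_color))
        if tlo <= n_targets <= thi:
            break
    else:  # pragma: no cover - requires pathological ranges that validate() admits
        raise ConfigurationError(
            f"could not satisfy target count {design.target_count_range} "
            f"with {n} stimuli of {design.n_colors} colors"
        )

    rows = rng.integers(1, design.grid_size + 1, size=n)
    cols = rng.integers(1, design.grid_size + 1, size=n)
    return [
        StimulusEvent(
            onset_ms=start_ms + i * SOA_MS,
            color_index=int(colors[i]),
            grid_row=int(rows[i]),
            grid_col=int(cols[i]),
            is_target=bool(colors[i] == target_color),
            condition=condition,
            repetition_index=repetition_index,
            within_repetition_index=i + 1,
        )
        for i in range(n)
    ]


def example_sequence(condition: str = "C") -> list[StimulusEvent]:
    """The short six-stimulus worked example: magenta targets at grid cells
    (row 1, col 3) and (row 3, col 5) among four distractors.

    Scoring it yields 2 in the counting task, 1+1+10+1+1+10 = 24 in the
    arithmetic task, and the position set {(1,3), (3,5)} in the memory task.
    """
    magenta = COLOR_NAMES.index("magenta")
    spec = [  # (color, row, col) in presentation order: D D T D D T
        (1, 2, 2),
        (3, 4, 1),
        (magenta, 1, 3),
        (2, 5, 4),
        (4, 2, 5),
        (magenta, 3, 5),
    ]
    return [
        StimulusEvent(
            onset_ms=i * SOA_MS,
            color_index=color,
            grid_row=row,
            grid_col=col,
            is_target=color == magenta,
            condition=condition,
            repetition_index=1,
            within_repetition_index=i + 1,
        )
        for i, (color, row, col) in enumerate(spec)
    ]
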