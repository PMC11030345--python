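"""Number-comparison task designs.

Two-alternative forced choice: children judge which side of the screen
shows the larger quantity, presented either as dot arrays (nonsymbolic
format) or Arabic numerals (symbolic format).  The design is a 2x2
factorial crossing pair *size* (little: digit sum < 10; big: digit sum
> 10) with numerical *distance* (near: |a-b| = 1; far: |a-b| = 5).
Digits run 1-9 with 5 excluded, so that near pairs never straddle the
midpoint ambiguously.  Each run holds 64 trials, 16 per cell, with the
larger number appearing equally often on the left and right.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

DIGITS: tuple[int, ...] = (1, 2, 3, 4, 6, 7, 8, 9)
SIZES: tuple[str, str] = ("little", "big")
DISTANCES: tuple[str, str] = ("near", "far")
FORMATS: tuple[str, str] = ("nonsymbolic", "symbolic")
TRIALS_PER_CELL: int = 16
TRIALS_PER_RUN: int = 64

_DISTANCE_GAP = {"near": 1, "far": 5}


@dataclass(frozen=True)
class Trial:
    """One comparison trial: format, design cell, digit pair, correct side."""

    format: str
    size: str
    distance: str
    pair: tuple[int, int]  # (a, b) with a < b
    larger_side: str  # "left" or "right"

    @property
    def condition(self) -> str:
        return f"{self.size}_{self.distance}"

    @property
    def left(self) -> int:
        return self.pair[1] if self.larger_side == "left" else self.pair[0]

    @property
    def right(self) -> int:
        return self.pair[1] if self.larger_side == "right" else self.pair[0]


@dataclass
class TrialDesign:
    """An ordered run of comparison trials for one task format."""

    run_id: str
    format: str
    trials: list[Trial]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_id": self.run_id,
                "format": self.format,
                "trial": np.arange(1, len(self.trials) + 1),
                "size": [t.size for t in self.trials],
                "distance": [t.distance for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "pair_left": [t.left for t in self.trials],
                "pair_right": [t.right for t in self.trials],
                "larger_side": [t.larger_side for t in self.trials],
            }
        )


def admissible_pairs(size: str, distance: str) -> list[tuple[int, int]]:
    """Enumerate digit pairs satisfying a size x distance cell's constraints."""
    if size not in SIZES:
        raise ValueError(f"unknown size {size!r}")
    gap = _DISTANCE_GAP[distance]
    out = []
    for a, b in combinations(DIGITS, 2):
        if b - a != gap:
            continue
        total = a + b
        if (size == "little" and total < 10) or (size == "big" and total > 10):
            out.append((a, b))
    return out


def generate_task_design(
    seed: int, n_runs: int = 1, task: str = "nonsymbolic"
) -> list[TrialDesign]:
    """Generate pseudorandomized comparison-task runs.

    Each run has 64 trials, 16 per size x distance cell.  The few
    admissible pairs per cell (2-3) are filled to 16 by balanced
    repetition; the larger number's side is balanced 8/8 within each
    cell; trial order is shuffled deterministically from ``seed``.

    Parameters
    ----------
    seed : int
        Seed for the pseudorandomization.
    n_runs : int
        Number of runs to generate (>= 1).
    task : str
        "nonsymbolic" or "symbolic".
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if task not in FORMATS:
        raise ValueError(f"unknown task format {task!r}")
    rng = np.random.default_rng(seed)
    runs: list[TrialDesign] = []
    for r in range(n_runs):
        trials: list[Trial] = []
        for size in SIZES:
            for distance in DISTANCES:
                pairs = admissible_pairs(size, distance)
                reps = [pairs[i % len(pairs)] for i in range(TRIALS_PER_CELL)]
                sides = np.array(
                    ["left"] * (TRIALS_PER_CELL // 2) + ["right"] * (TRIALS_PER_CELL // 2)
                )
                rng.shuffle(sides)
                trials.extend(
                    Trial(task, size, distance, pair, side)
                    for pair, side in zip(reps, sides)
                )
        order = rng.permutation(len(trials))
        trials = [trials[i] for i in order]
        runs.append(TrialDesign(run_id=f"{task}_run{r + 1}", format=task, trials=trials))
    return runs
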