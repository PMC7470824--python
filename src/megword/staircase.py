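"""1-up-3-down adaptive staircase for stimulus calibration.

The transformed up-down rule lowers the stimulus level (making the task
harder) only after three consecutive correct responses and raises it after
any error, converging on the level where p(correct)^3 = 0.5, i.e. ~79.4 %
correct.  The calibration task is a 2-alternative judgement, so observers
fold a 0.5 guessing floor into their psychometric function.

Step sizes halve once after the first two reversals (a common refinement; the
exact schedule is configurable) and the converged level is the mean of the
last ``n_converge`` reversal levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "StaircaseTrack",
    "target_probability",
    "logistic_observer",
    "run_staircase",
]


def target_probability(n_down: int) -> float:
    """Convergence point of a 1-up-n-down staircase: p with p**n_down = 0.5."""
    if n_down < 1:
        raise ValueError(f"n_down must be >= 1, got {n_down}")
    return float(0.5 ** (1.0 / n_down))


def logistic_observer(
    midpoint: float, slope: float, guess: float = 0.5, lapse: float = 0.0
) -> Callable[[float], float]:
    """Psychometric function p(correct | level) with guessing floor and lapse."""

    def p_correct(level: float) -> float:
        core = 1.0 / (1.0 + np.exp(-(level - midpoint) * slope))
        return guess + (1.0 - guess - lapse) * core

    return p_correct


@dataclass
class StaircaseTrack:
    levels: np.ndarray
    correct: np.ndarray
    reversal: np.ndarray  # bool per trial
    converged_level: float

    @property
    def n_reversals(self) -> int:
        return int(self.reversal.sum())


def _check_monotone(observer: Callable[[float], float], start: float, step: float) -> None:
    probes = start + step * np.arange(-20, 21)
    p = np.array([observer(x) for x in probes])
    if np.any(np.diff(p) < -1e-9):
        raise ValueError("observer psychometric function must be non-decreasing in level")


def run_staircase(
    observer: Callable[[float], float],
    start_level: float,
    step: float,
    n_down: int = 3,
    n_reversals: int | None = 14,
    n_trials: int | None = None,
    halve_after: int = 2,
    n_converge: int = 6,
    seed: int = 0,
) -> StaircaseTrack:
    """Simulate the adaptive track until ``n_reversals`` reversals (or ``n_trials``).

    The level decreases by the current step only after ``n_down`` consecutive
    correct responses and increases after any error; a reversal is a change of
    movement direction.  The converged level is the mean of the last
    ``n_converge`` reversal levels.
    """
    if n_reversals is None and n_trials is None:
        raise ValueError("one of n_reversals or n_trials must be set")
    _check_monotone(observer, start_level, step)
    rng = np.random.default_rng(seed)

    levels, correct, reversal_flags, reversal_levels = [], [], [], []
    level = float(start_level)
    cur_step = float(step)
    streak = 0
    direction = 0  # -1 down, +1 up, 0 before first move
    trial = 0
    while True:
        if n_trials is not None and trial >= n_trials:
            break
        if n_reversals is not None and len(reversal_levels) >= n_reversals:
            break
        ok = rng.random() < observer(level)
        levels.append(level)
        correct.append(ok)
        move = 0
        if ok:
            streak += 1
            if streak >= n_down:
                move = -1
                streak = 0
        else:
            move = +1
            streak = 0
        is_reversal = False
        if move != 0:
            if direction != 0 and move != direction:
                is_reversal = True
                reversal_levels.append(level)
                if len(reversal_levels) == halve_after:
                    cur_step /= 2.0
            direction = move
            level += move * cur_step
        reversal_flags.append(is_reversal)
        trial += 1

    tail = reversal_levels[-n_converge:] if reversal_levels else [level]
    return StaircaseTrack(
        levels=np.array(levels),
        correct=np.array(correct, dtype=bool),
        reversal=np.array(reversal_flags, dtype=bool),
        converged_level=float(np.mean(tail)),
    )
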