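"""1-up/2-down (Levitt) adaptive staircase with reversal-driven step
shrinkage and threshold estimation from the last reversals.

The 1-up/2-down rule — two consecutive correct responses make the task
harder, any error makes it easier — converges on the level where the
probability of a correct response p satisfies p^2 = 0.5, i.e. p ~ 70.7%.
The step magnitude walks forward through a fixed schedule, advancing one
entry at each reversal and staying at the final entry thereafter. The
threshold is the arithmetic mean of the last ``reversals_for_threshold``
reversal levels; its spread is their sample standard deviation.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StaircaseProtocol",
    "StaircaseState",
    "ThresholdEstimate",
    "StaircaseError",
    "TooFewReversalsError",
    "staircase_update",
    "estimate_threshold",
    "run_staircase",
]


class StaircaseError(ValueError):
    pass


class TooFewReversalsError(StaircaseError):
    def __init__(self, n_observed: int, n_required: int):
        self.n_observed = n_observed
        self.n_required = n_required
        super().__init__(
            f"threshold needs {n_required} reversals but only {n_observed} were recorded"
        )


@dataclass(frozen=True)
class StaircaseProtocol:
    """Staircase configuration.

    ``harder`` says which way the level moves when the task gets harder:
    "decrease" for the coherence task (less coherence is harder), "increase"
    for an external-noise staircase (more noise is harder). Levels are
    clamped to ``level_bounds``. The run stops at ``min_total_reversals``
    reversals or ``max_trials`` trials, whichever comes first; set
    ``min_total_reversals`` to None for fixed-length blocks.
    """

    initial_level: float = 50.0
    step_schedule: tuple = (25.0, 20.0, 15.0, 10.0, 5.0, 2.0, 1.0)
    level_bounds: tuple = (1.0, 100.0)
    harder: str = "decrease"
    max_trials: int = 300
    reversals_for_threshold: int = 14
    min_total_reversals: Optional[int] = 21

    def __post_init__(self):
        if any(s <= 0 for s in self.step_schedule):
            raise StaircaseError(f"step_schedule must be positive, got {self.step_schedule}")
        lo, hi = self.level_bounds
        if not lo <= self.initial_level <= hi:
            raise StaircaseError(
                f"initial_level {self.initial_level} outside bounds {self.level_bounds}"
            )
        if self.reversals_for_threshold < 1:
            raise StaircaseError("reversals_for_threshold must be >= 1")
        if self.harder not in ("decrease", "increase"):
            raise StaircaseError(f"harder must be 'decrease' or 'increase', got {self.harder!r}")

    @property
    def harder_sign(self) -> float:
        return -1.0 if self.harder == "decrease" else 1.0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["step_schedule"] = list(self.step_schedule)
        d["level_bounds"] = list(self.level_bounds)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StaircaseProtocol":
        d = yaml.safe_load(text)
        d["step_schedule"] = tuple(d["step_schedule"])
        d["level_bounds"] = tuple(d["level_bounds"])
        return cls(**d)


@dataclass
class StaircaseState:
    """Mutable track bookkeeping. ``last_move`` is None until the first level
    change; no reversal can be recorded before a direction exists."""

    current_level: float
    consecutive_correct: int = 0
    last_move: Optional[str] = None  # "harder" | "easier"
    reversal_levels: list = field(default_factory=list)
    schedule_index: int = 0
    trial_count: int = 0
    terminated: bool = False

    @classmethod
    def from_protocol(cls, protocol: StaircaseProtocol) -> "StaircaseState":
        return cls(current_level=protocol.initial_level)

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels)


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float
    spread: float
    n_reversals_used: int


def staircase_update(
    state: StaircaseState, correct: bool, protocol: StaircaseProtocol
) -> StaircaseState:
    """Apply one response to the track (in place; the state is returned for
    convenience). Two consecutive corrects step harder, any error steps
    easier; a direction change records a reversal at the pre-move level and
    advances the step schedule (capped at its last entry)."""
    if state.terminated:
        raise StaircaseError("staircase_update called after termination")
    state.trial_count += 1

    move: Optional[str] = None
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= 2:
            move = "harder"
            state.consecutive_correct = 0
    else:
        move = "easier"
        state.consecutive_correct = 0

    if move is None:
        return state

    step = protocol.step_schedule[state.schedule_index]
    if state.last_move is not None and move != state.last_move:
        # reversal: recorded at the pre-move level; the shrunken step takes
        # effect from the NEXT move (advancing it before the current move
        # slows the recovery out of reversals and biases thresholds low)
        state.reversal_levels.append(state.current_level)
        state.schedule_index = min(
            state.schedule_index + 1, len(protocol.step_schedule) - 1
        )
    sign = protocol.harder_sign if move == "harder" else -protocol.harder_sign
    lo, hi = protocol.level_bounds
    state.current_level = float(np.clip(state.current_level + sign * step, lo, hi))
    state.last_move = move
    return state


def estimate_threshold(
    state: StaircaseState, protocol: StaircaseProtocol
) -> ThresholdEstimate:
    """Mean of the last ``reversals_for_threshold`` reversal levels; spread is
    their sample SD (ddof=1)."""
    k = protocol.reversals_for_threshold
    if state.n_reversals < k:
        raise TooFewReversalsError(state.n_reversals, k)
    used = np.asarray(state.reversal_levels[-k:], dtype=float)
    spread = float(used.std(ddof=1)) if k > 1 else 0.0
    return ThresholdEstimate(threshold=float(used.mean()), spread=spread, n_reversals_used=k)


def run_staircase(
    protocol: StaircaseProtocol,
    observer: Callable[[float], bool],
    rng=None,
) -> tuple[StaircaseState, pd.DataFrame]:
    """Drive a staircase with ``observer(level) -> correct`` until the
    protocol's stopping rule fires. Returns the final state and a per-trial
    log (trial, level, correct, reversal, step_size). ``rng`` is accepted for
    interface symmetry with observers that close over their own source."""
    state = StaircaseState.from_protocol(protocol)
    log = []
    while state.trial_count < protocol.max_trials:
        level = state.current_level
        step = protocol.step_schedule[state.schedule_index]
        n_rev_before = state.n_reversals
        correct = bool(observer(level))
        staircase_update(state, correct, protocol)
        log.append(
            (state.trial_count, level, correct, state.n_reversals > n_rev_before, step)
        )
        if (
            protocol.min_total_reversals is not None
            and state.n_reversals >= protocol.min_total_reversals
        ):
            break
    state.terminated = True
    return state, pd.DataFrame(
        log, columns=["trial", "level", "correct", "reversal", "step_size"]
    )
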