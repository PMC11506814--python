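"""Simulated observers and the full study protocol.

This is the synthetic-data generator: stochastic observers with known ground
truth (internal noise sigma_int, sampling efficiency eta, Weibull coherence
thresholds, power-law learning) are run through the same staircases a human
participant would face, producing tidy trial tables with the statistical
structure the downstream analysis assumes.

The emulated design: 10 participants; a pre-test of four 300-trial tasks
(coherence and equivalent-noise, each with dynamic Glass patterns and with
mRDKs); eight training sessions of two 300-trial coherence blocks with Glass
patterns; and a post-test mirroring the pre-test. Coherence thresholds
improve across sessions following a power law a * x^(-b) with defaults
a = 33.89, b = 0.20.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import equivalent_noise as en
from .staircase import (
    StaircaseProtocol,
    ThresholdEstimate,
    TooFewReversalsError,
    estimate_threshold,
    run_staircase,
)

__all__ = [
    "ENObserver",
    "CoherenceObserver",
    "LearningTrajectory",
    "StudyConfig",
    "SimulatedStudy",
    "en_observer_respond",
    "coherence_observer_respond",
    "simulate_en_measurement",
    "simulate_study",
    "coherence_protocol",
]

#: Convergence point of the 1-up/2-down rule: p^2 = 1/2.
P_CONVERGENCE: float = math.sqrt(0.5)


@dataclass(frozen=True)
class ENObserver:
    """Pooling observer for the orientation/direction-mean task: its estimate
    of the mean tilt carries Gaussian error with
    SD sqrt((sigma_int^2 + sigma_ext^2) / eta), and it responds with the
    estimate's sign."""

    sigma_int: float
    eta: float
    lapse_rate: float = 0.0

    def __post_init__(self):
        if self.sigma_int < 0:
            raise ValueError(f"sigma_int must be >= 0, got {self.sigma_int}")
        if self.eta < 1:
            raise ValueError(f"eta must be >= 1, got {self.eta}")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError(f"lapse_rate must be in [0, 0.5), got {self.lapse_rate}")

    def sigma_eff(self, sigma_ext: float) -> float:
        return math.sqrt((self.sigma_int**2 + sigma_ext**2) / self.eta)

    def p_correct(self, mean_offset: float, sigma_ext: float) -> float:
        """True psychometric function (closed form)."""
        s = self.sigma_eff(sigma_ext)
        if s == 0:
            p = 1.0 if mean_offset != 0 else 0.5
        else:
            p = float(stats.norm.cdf(abs(mean_offset) / s))
        return self.lapse_rate * 0.5 + (1 - self.lapse_rate) * p


@dataclass(frozen=True)
class CoherenceObserver:
    """Weibull observer for the 2IFC coherence task, parameterised by its
    70.7%-correct threshold (coherence %):

        p(c) = 0.5 + (0.5 - lapse) * (1 - exp(-(c / alpha)^slope))

    with alpha chosen so p(threshold_c) = sqrt(1/2)."""

    threshold_c: float
    slope: float = 3.0
    lapse_rate: float = 0.0

    def __post_init__(self):
        if not 0 < self.threshold_c <= 100:
            raise ValueError(f"threshold_c must lie in (0, 100], got {self.threshold_c}")
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError(f"lapse_rate must be in [0, 0.5), got {self.lapse_rate}")
        if P_CONVERGENCE - 0.5 >= 0.5 - self.lapse_rate:
            raise ValueError(
                f"lapse_rate {self.lapse_rate} puts the 70.7% point out of reach"
            )

    @property
    def alpha(self) -> float:
        q = (P_CONVERGENCE - 0.5) / (0.5 - self.lapse_rate)
        return self.threshold_c / (-math.log1p(-q)) ** (1.0 / self.slope)

    def p_correct(self, coherence: float) -> float:
        if not 0 <= coherence <= 100:
            raise ValueError(f"coherence must lie in [0, 100], got {coherence}")
        return 0.5 + (0.5 - self.lapse_rate) * (
            1.0 - math.exp(-((coherence / self.alpha) ** self.slope))
        )


def en_observer_respond(
    obs: ENObserver, mean_offset: float, sigma_ext: float, rng: np.random.Generator
) -> bool:
    """Single 2AFC tilt judgement: internal estimate = true offset + Gaussian
    error with SD sigma_eff; the response is the estimate's sign. A zero
    offset is credited at chance. Lapses replace the response with a coin."""
    if mean_offset == 0:
        true_sign = 1.0 if rng.random() < 0.5 else -1.0
        offset = 0.0
    else:
        true_sign = math.copysign(1.0, mean_offset)
        offset = mean_offset
    estimate = offset + rng.normal(0.0, obs.sigma_eff(sigma_ext))
    correct = (estimate > 0) == (true_sign > 0)
    if obs.lapse_rate and rng.random() < obs.lapse_rate:
        correct = rng.random() < 0.5
    return bool(correct)


def coherence_observer_respond(
    obs: CoherenceObserver, coherence: float, rng: np.random.Generator
) -> bool:
    """Single 2IFC coherence judgement: Bernoulli draw from the observer's
    Weibull psychometric function (the staircase only consumes correctness,
    so the two intervals need not be modelled explicitly)."""
    return bool(rng.random() < obs.p_correct(coherence))


def coherence_protocol(max_trials: int = 300,
                       min_total_reversals: int | None = None) -> StaircaseProtocol:
    """The coherence-task staircase: start 50 %, steps 25,20,15,10,5,2,1,
    bounds [1, 100] %."""
    return StaircaseProtocol(
        initial_level=50.0,
        step_schedule=(25.0, 20.0, 15.0, 10.0, 5.0, 2.0, 1.0),
        level_bounds=(1.0, 100.0),
        harder="decrease",
        max_trials=max_trials,
        min_total_reversals=min_total_reversals,
    )


@dataclass(frozen=True)
class LearningTrajectory:
    """Power-law learning: threshold_c(x) = a * x^(-b) for session x = 1..10,
    where a is the session-1 scale (coherence %) and b the learning rate."""

    a: float = 33.89
    b: float = 0.20

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")

    def threshold(self, session: int | np.ndarray) -> float | np.ndarray:
        return self.a * np.asarray(session, dtype=float) ** (-self.b)


# Group-level generator defaults for the equivalent-noise observers, by
# (stimulus, phase). eta cells are the reported group means; sigma_int cells
# solve the reported two-way margins (pre 0.62 / post 0.29; GP 0.22 / mRDK
# 0.70) since cell means are not reported.
DEFAULT_ETA = {
    ("gp", "pre"): 2.26,
    ("gp", "post"): 2.62,
    ("mrdk", "pre"): 3.38,
    ("mrdk", "post"): 1.1,
}
DEFAULT_SIGMA_INT = {
    ("gp", "pre"): 0.30,
    ("gp", "post"): 0.14,
    ("mrdk", "pre"): 0.94,
    ("mrdk", "post"): 0.44,
}


@dataclass(frozen=True)
class StudyConfig:
    """Layout and parameter distributions of the simulated study."""

    n_participants: int = 10
    n_training_sessions: int = 8
    blocks_per_training: int = 2
    trials_per_block: int = 300
    trajectory: LearningTrajectory = field(default_factory=LearningTrajectory)
    mrdk_scale: float = 1.5  # mRDK coherence thresholds relative to GP
    transfer: float = 1.0  # 0 = no mRDK transfer, 1 = full trajectory transfer
    coherence_slope: float = 3.0
    lapse_rate: float = 0.0
    jitter_sd: float = 0.2  # log-normal between-participant SD
    eta: dict = field(default_factory=lambda: dict(DEFAULT_ETA))
    sigma_int: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA_INT))
    calibration_k: float = en.K_GAUSSIAN
    master_seed: int = 0

    def __post_init__(self):
        for name in ("n_participants", "n_training_sessions", "blocks_per_training",
                     "trials_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.trials_per_block % 2:
            raise ValueError("trials_per_block must be even (EN blocks split in two)")

    @property
    def n_sessions(self) -> int:
        return self.n_training_sessions + 2

    @property
    def trials_per_participant(self) -> int:
        per_test = 4 * self.trials_per_block
        training = self.n_training_sessions * self.blocks_per_training * self.trials_per_block
        return 2 * per_test + training


@dataclass
class SimulatedStudy:
    """Generated study data: the tidy trial table, per-block threshold
    summaries and the ground-truth participant parameters."""

    trials: pd.DataFrame
    thresholds: pd.DataFrame
    participants: pd.DataFrame
    config: StudyConfig


def simulate_en_measurement(
    obs: ENObserver,
    rng: np.random.Generator,
    max_trials: int = 150,
    min_total_reversals: int | None = None,
    calibration_k: float = en.K_GAUSSIAN,
    tilt_high: float = en.SIGMA_OBS_HIGH_DEFAULT,
):
    """Run the two-point equivalent-noise measurement on one observer: a
    zero-noise tilt staircase and a high-noise external-noise staircase (tilt
    fixed at +/- tilt_high), then fit the decomposition.

    Returns (results, zero_estimate, high_estimate, zero_log, high_log).
    """
    proto0 = en.zero_noise_protocol(max_trials, min_total_reversals)
    state0, log0 = run_staircase(
        proto0,
        lambda level: en_observer_respond(
            obs, level * (1.0 if rng.random() < 0.5 else -1.0), 0.0, rng
        ),
    )
    protoH = en.high_noise_protocol(max_trials, min_total_reversals)
    stateH, logH = run_staircase(
        protoH,
        lambda level: en_observer_respond(
            obs, tilt_high * (1.0 if rng.random() < 0.5 else -1.0), level, rng
        ),
    )
    est0 = estimate_threshold(state0, proto0)
    estH = estimate_threshold(stateH, protoH)
    results = en.EquivalentNoiseModel.from_thresholds(
        est0, estH, calibration_k=calibration_k, tilt_high=tilt_high
    ).fit()
    return results, est0, estH, log0, logH


def _jitter(rng: np.random.Generator, sd: float) -> float:
    return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0


def _draw_participants(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for p in range(1, config.n_participants + 1):
        row = {
            "participant": p,
            "a": config.trajectory.a * _jitter(rng, config.jitter_sd),
            "b": config.trajectory.b,
            "mrdk_scale": config.mrdk_scale,
        }
        j_sigma = _jitter(rng, config.jitter_sd)
        j_eta = _jitter(rng, config.jitter_sd)
        for (stim, phase), value in config.sigma_int.items():
            row[f"sigma_int_{stim}_{phase}"] = value * j_sigma
        for (stim, phase), value in config.eta.items():
            row[f"eta_{stim}_{phase}"] = max(1.0, value * j_eta)
        rows.append(row)
    return pd.DataFrame(rows)


def _coherence_threshold_true(config: StudyConfig, person: pd.Series,
                              stimulus: str, session: int) -> float:
    base = LearningTrajectory(a=person["a"], b=person["b"])
    if stimulus == "gp":
        return float(np.clip(base.threshold(session), 1.0, 100.0))
    # mRDK: higher scale; improvement only insofar as learning transfers
    x_eff = 1.0 + config.transfer * (session - 1)
    value = person["mrdk_scale"] * base.threshold(x_eff)
    return float(np.clip(value, 1.0, 100.0))


def simulate_study(config: StudyConfig | None = None, rng=None) -> SimulatedStudy:
    """Simulate the full study. Fully reproducible from config.master_seed
    (an explicit ``rng`` overrides it)."""
    config = config or StudyConfig()
    if rng is None:
        rng = np.random.default_rng(config.master_seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    participants = _draw_participants(config, rng)
    trial_rows: list[pd.DataFrame] = []
    summary_rows = []

    def log_block(participant, session, task, stimulus, block, measure, log, estimate):
        log = log.copy()
        log.insert(0, "stimulus", stimulus)
        log.insert(0, "task", task)
        log.insert(0, "session", session)
        log.insert(0, "participant", participant)
        log.insert(4, "block", block)
        trial_rows.append(log[
            ["participant", "session", "task", "stimulus", "block",
             "trial", "level", "correct", "reversal"]
        ])
        summary_rows.append(
            {
                "participant": participant,
                "session": session,
                "task": task,
                "stimulus": stimulus,
                "block": block,
                "measure": measure,
                "threshold": estimate.threshold if estimate else np.nan,
                "spread": estimate.spread if estimate else np.nan,
            }
        )

    def run_coherence_block(person, session, stimulus, block):
        true_t = _coherence_threshold_true(config, person, stimulus, session)
        obs = CoherenceObserver(true_t, config.coherence_slope, config.lapse_rate)
        proto = coherence_protocol(config.trials_per_block, min_total_reversals=None)
        state, log = run_staircase(
            proto, lambda level: coherence_observer_respond(obs, level, rng)
        )
        try:
            est = estimate_threshold(state, proto)
        except TooFewReversalsError:
            est = None
        log_block(int(person["participant"]), session, "coherence", stimulus,
                  block, "coherence", log, est)

    def run_en_block(person, session, stimulus):
        phase = "pre" if session == 1 else "post"
        obs = ENObserver(
            sigma_int=person[f"sigma_int_{stimulus}_{phase}"],
            eta=person[f"eta_{stimulus}_{phase}"],
            lapse_rate=config.lapse_rate,
        )
        half = config.trials_per_block // 2
        proto0 = en.zero_noise_protocol(half, min_total_reversals=None)
        state0, log0 = run_staircase(
            proto0,
            lambda level: en_observer_respond(
                obs, level * (1.0 if rng.random() < 0.5 else -1.0), 0.0, rng
            ),
        )
        protoH = en.high_noise_protocol(half, min_total_reversals=None)
        stateH, logH = run_staircase(
            protoH,
            lambda level: en_observer_respond(
                obs,
                en.SIGMA_OBS_HIGH_DEFAULT * (1.0 if rng.random() < 0.5 else -1.0),
                level,
                rng,
            ),
        )
        for state, proto, log, block, measure in (
            (state0, proto0, log0, 1, "tilt"),
            (stateH, protoH, logH, 2, "sigma_ext"),
        ):
            try:
                est = estimate_threshold(state, proto)
            except TooFewReversalsError:
                est = None
            log_block(int(person["participant"]), session, "equivalent_noise",
                      stimulus, block, measure, log, est)

    for _, person in participants.iterrows():
        # pre-test (session 1)
        for stimulus in ("gp", "mrdk"):
            run_coherence_block(person, 1, stimulus, block=1)
            run_en_block(person, 1, stimulus)
        # training (sessions 2 .. n_training_sessions + 1), GP coherence only
        for t in range(config.n_training_sessions):
            session = 2 + t
            for block in range(1, config.blocks_per_training + 1):
                run_coherence_block(person, session, "gp", block)
        # post-test (last session)
        for stimulus in ("gp", "mrdk"):
            run_coherence_block(person, config.n_sessions, stimulus, block=1)
            run_en_block(person, config.n_sessions, stimulus)

    trials = pd.concat(trial_rows, ignore_index=True)
    thresholds = pd.DataFrame(summary_rows)
    return SimulatedStudy(
        trials=trials, thresholds=thresholds, participants=participants, config=config
    )
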