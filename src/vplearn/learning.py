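"""Learning-curve fitting and model selection.

Coherence thresholds across practice sessions are fitted with three model
families —

    linear       y = a x + b
    power        y = a x^(-b)
    exponential  y = a e^(b x)

— by least squares in the untransformed y-space, and compared with
information criteria under the Gaussian-likelihood convention

    AIC  = n ln(RSS / n) + 2 k
    AICc = AIC + 2 k (k + 1) / (n - k - 1)
    BIC  = n ln(RSS / n) + k ln n

with k = 3 per family (two curve parameters plus the error variance). The
best model minimises AICc, with ties broken by BIC then AIC.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FAMILIES",
    "LearningSeries",
    "LearningModelFit",
    "LearningCurveModel",
    "LearningCurveResults",
    "fit_learning_model",
    "information_criteria",
    "select_best_model",
    "session_mean_series",
]

FAMILIES = ("linear", "power", "exponential")
N_PARAMS = 3  # a, b and the error variance


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every start."""


@dataclass(frozen=True)
class LearningSeries:
    """Threshold-versus-session series: x are strictly increasing positive
    session indices, y positive thresholds (coherence %)."""

    x: np.ndarray
    y: np.ndarray
    sem: Optional[np.ndarray] = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be one-dimensional and equally long")
        if np.any(x <= 0) or np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing and positive")
        if np.any(y <= 0):
            raise ValueError("y must be positive")
        if self.sem is not None:
            sem = np.asarray(self.sem, dtype=float)
            if sem.shape != y.shape:
                raise ValueError("sem must match y in length")
            object.__setattr__(self, "sem", sem)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class LearningModelFit:
    """One family's least-squares fit with its information criteria."""

    family: str
    a: float
    b: float
    rss: float
    n: int
    k: int
    aic: float
    aicc: float
    bic: float

    @property
    def params(self) -> tuple[float, float]:
        return (self.a, self.b)

    def predict(self, x) -> np.ndarray:
        return _MODEL_FUNCS[self.family](np.asarray(x, dtype=float), self.a, self.b)


def _linear(x, a, b):
    return a * x + b


def _power(x, a, b):
    return a * np.power(x, -b)


def _exponential(x, a, b):
    return a * np.exp(b * x)


_MODEL_FUNCS = {"linear": _linear, "power": _power, "exponential": _exponential}


def information_criteria(rss: float, n: int, k: int = N_PARAMS) -> tuple[float, float, float]:
    """(AIC, AICc, BIC) under the Gaussian-likelihood convention. A perfect
    fit (rss = 0) yields -inf sentinels with a warning."""
    if rss < 0:
        raise ValueError(f"rss must be >= 0, got {rss}")
    if n <= k + 1:
        raise ValueError(f"AICc needs n > k + 1 (n={n}, k={k})")
    if rss == 0:
        warnings.warn("rss = 0: information criteria are -inf", RuntimeWarning,
                      stacklevel=2)
        return (-math.inf, -math.inf, -math.inf)
    aic = n * math.log(rss / n) + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    bic = n * math.log(rss / n) + k * math.log(n)
    return (aic, aicc, bic)


def _starts(series: LearningSeries, family: str) -> list[tuple[float, float]]:
    """Data-driven starts plus perturbations (multi-start)."""
    x, y = series.x, series.y
    if family == "linear":
        a0, b0 = np.polyfit(x, y, 1)
        return [(a0, b0), (0.0, float(np.mean(y)))]
    if family == "power":
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        base = (float(np.exp(intercept)), float(-slope))
    else:  # exponential
        slope, intercept = np.polyfit(x, np.log(y), 1)
        base = (float(np.exp(intercept)), float(slope))
    a0, b0 = base
    return [base, (float(y[0]), b0), (a0, 0.0), (float(y[0]), 0.1), (float(y[0]), -0.1)]


def fit_learning_model(series: LearningSeries, family: str) -> LearningModelFit:
    """Least-squares fit of one family in the original y-space, multi-start
    nonlinear optimisation for power/exponential (linear is closed-form)."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if series.n < 4:
        raise ValueError(f"need at least 4 points, got {series.n}")
    x, y = series.x, series.y
    func = _MODEL_FUNCS[family]

    if family == "linear":
        a, b = np.polyfit(x, y, 1)
        best = (float(a), float(b))
        best_rss = float(np.sum((y - func(x, *best)) ** 2))
    else:
        best, best_rss, failures = None, math.inf, []
        for start in _starts(series, family):
            try:
                sol = least_squares(
                    lambda p: func(x, p[0], p[1]) - y, x0=start,
                    method="lm", max_nfev=10_000,
                )
            except Exception as exc:  # singular Jacobian at a bad start
                failures.append(f"start {start}: {exc}")
                continue
            rss = float(np.sum(sol.fun**2))
            if sol.success and rss < best_rss:
                best, best_rss = (float(sol.x[0]), float(sol.x[1])), rss
        if best is None:
            raise FitError(
                f"{family} fit did not converge from any start: {'; '.join(failures)}"
            )
    aic, aicc, bic = information_criteria(best_rss, series.n, N_PARAMS)
    return LearningModelFit(
        family=family, a=best[0], b=best[1], rss=best_rss,
        n=series.n, k=N_PARAMS, aic=aic, aicc=aicc, bic=bic,
    )


def select_best_model(fits: Sequence[LearningModelFit]) -> str:
    """Family with the lowest AICc (ties: BIC, then AIC). All fits must come
    from the same series (same n)."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fitted families")
    if len({f.n for f in fits}) != 1:
        raise ValueError("fits come from different series (unequal n)")
    return min(fits, key=lambda f: (f.aicc, f.bic, f.aic)).family


def session_mean_series(thresholds: pd.DataFrame, stimulus: str = "gp") -> LearningSeries:
    """Collapse a per-block threshold summary to per-session means across
    participants for the coherence task with one stimulus."""
    sub = thresholds[
        (thresholds["task"] == "coherence") & (thresholds["stimulus"] == stimulus)
    ]
    if sub.empty:
        raise ValueError(f"no coherence thresholds for stimulus {stimulus!r}")
    per_session = sub.groupby("session")["threshold"].agg(["mean", "sem"]).reset_index()
    return LearningSeries(
        x=per_session["session"].to_numpy(dtype=float),
        y=per_session["mean"].to_numpy(),
        sem=per_session["sem"].to_numpy(),
    )


class LearningCurveModel:
    """Threshold-versus-session model comparison.

    Parameters
    ----------
    y : array-like
        Session thresholds (coherence %), one per session.
    x : array-like, optional
        Session indices; defaults to 1..n.
    sem : array-like, optional
        Per-session SEMs (carried through for reporting only; fits are
        unweighted).
    """

    def __init__(self, y, x=None, sem=None):
        y = np.asarray(y, dtype=float)
        if x is None:
            x = np.arange(1, len(y) + 1, dtype=float)
        self.series = LearningSeries(x=np.asarray(x, dtype=float), y=y, sem=sem)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "session",
                       y: str = "threshold", sem: str | None = None) -> "LearningCurveModel":
        return cls(df[y].to_numpy(), df[x].to_numpy(),
                   df[sem].to_numpy() if sem and sem in df else None)

    @classmethod
    def from_study(cls, thresholds: pd.DataFrame, stimulus: str = "gp") -> "LearningCurveModel":
        series = session_mean_series(thresholds, stimulus)
        model = cls.__new__(cls)
        model.series = series
        return model

    def fit(self, families: Sequence[str] = FAMILIES) -> "LearningCurveResults":
        fits = {family: fit_learning_model(self.series, family) for family in families}
        return LearningCurveResults(self, fits)


class LearningCurveResults:
    """Per-family fits, their criterion table and the selected family."""

    def __init__(self, model: LearningCurveModel, fits: dict[str, LearningModelFit]):
        self.model = model
        self.fits = fits

    @property
    def selected(self) -> str:
        return select_best_model(list(self.fits.values()))

    @property
    def best(self) -> LearningModelFit:
        return self.fits[self.selected]

    def criterion_table(self) -> pd.DataFrame:
        rows = [
            {"family": f.family, "a": f.a, "b": f.b, "rss": f.rss,
             "aic": f.aic, "aicc": f.aicc, "bic": f.bic}
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows).set_index("family")

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "families": {
                name: {"a": f.a, "b": f.b, "rss": f.rss,
                       "aic": f.aic, "aicc": f.aicc, "bic": f.bic}
                for name, f in self.fits.items()
            },
        }

    def summary(self) -> str:
        table = self.criterion_table()
        best = self.best
        lines = [
            "Learning-curve model comparison",
            "=" * 60,
            table.to_string(float_format=lambda v: f"{v:.4f}"),
            "-" * 60,
            f"selected: {self.selected}  "
            f"(a = {best.a:.4f}, b = {best.b:.4f}, n = {best.n})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data with the three fitted curves (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.errorbar(s.x, s.y, yerr=s.sem, fmt="ko", capsize=3, label="thresholds")
        grid = np.linspace(s.x.min(), s.x.max(), 200)
        for name, fit in self.fits.items():
            style = "-" if name == self.selected else "--"
            ax.plot(grid, fit.predict(grid), style, label=f"{name} (AICc {fit.aicc:.1f})")
        ax.set_xlabel("session")
        ax.set_ylabel("coherence threshold (%)")
        ax.legend()
        return ax
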