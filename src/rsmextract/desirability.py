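"""Derringer-Suich desirability scoring, multi-response optimization and
validation of the predicted optimum.

Each response y is mapped to an individual desirability d(y) in [0, 1]
(a one- or two-sided ramp raised to an exponent s); the composite score
is the weighted geometric mean

    D = (d1^w1 d2^w2 ... dn^wn)^(1 / sum w_i)

which is 0 whenever any d_i is 0 and monotone nondecreasing in every
d_i.  The optimizer is a deterministic two-stage search over the coded
design region: a coarse grid, then a Nelder-Mead polish started from the
best grid cell.

Validation compares a confirmatory experimental value against the model
prediction via the relative standard deviation of the pair,

    RSD% = 100 * sd(experimental, predicted) / mean(experimental, predicted)

with RSD% < 10 conventionally taken as adequate agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .rsm import QuadraticFit, predict

__all__ = [
    "DesirabilityGoal",
    "OptimumResult",
    "ValidationRecord",
    "individual_desirability",
    "composite_D",
    "optimize",
    "validate",
]

RSD_PASS_THRESHOLD = 10.0  # percent


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal for one response.

    goal : {"maximize", "minimize", "target", "in_range"}
    lower, upper : the ramp bounds L < T.  For "maximize" d ramps 0 -> 1
        from L to T; "minimize" is the mirror; "target" ramps up to
        ``target`` (default midpoint) and back down; "in_range" is the
        0/1 indicator of [lower, upper].
    weight : relative weight w in the geometric mean (> 0).
    exponent : ramp exponent s (> 0); s > 1 demands values near T.
    """

    response_name: str
    goal: str
    lower: float
    upper: float
    weight: float = 1.0
    exponent: float = 1.0
    target: float | None = None

    def __post_init__(self) -> None:
        if self.goal not in {"maximize", "minimize", "target", "in_range"}:
            raise ValueError(f"unknown goal {self.goal!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.response_name}: lower {self.lower} must be < upper {self.upper}")
        if not self.weight > 0:
            raise ValueError("weight must be > 0")
        if not self.exponent > 0:
            raise ValueError("exponent must be > 0")
        if self.goal == "target" and self.target is None:
            object.__setattr__(self, "target", 0.5 * (self.lower + self.upper))


def individual_desirability(goal: DesirabilityGoal, y: float) -> float:
    """Desirability d(y) in [0, 1] for a single response value."""
    L, U, s = goal.lower, goal.upper, goal.exponent
    y = float(y)
    if goal.goal == "maximize":
        if y <= L:
            return 0.0
        if y >= U:
            return 1.0
        return ((y - L) / (U - L)) ** s
    if goal.goal == "minimize":
        if y >= U:
            return 0.0
        if y <= L:
            return 1.0
        return ((U - y) / (U - L)) ** s
    if goal.goal == "target":
        T = goal.target
        if y <= L or y >= U:
            return 0.0
        if y <= T:
            return ((y - L) / (T - L)) ** s
        return ((U - y) / (U - T)) ** s
    # in_range
    return 1.0 if L <= y <= U else 0.0


def composite_D(d: Sequence[float], w: Sequence[float] | None = None) -> float:
    """Weighted geometric mean of individual desirabilities."""
    d = np.asarray(d, dtype=float)
    w = np.ones_like(d) if w is None else np.asarray(w, dtype=float)
    if d.shape != w.shape:
        raise ValueError("d and w length mismatch")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("individual desirabilities must lie in [0, 1]")
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


@dataclass
class OptimumResult:
    """Location and scores of the desirability optimum."""

    natural: np.ndarray
    coded: np.ndarray
    predicted: dict
    individual: dict
    D: float
    factor_names: tuple = ()
    warning: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "natural": {n: float(v) for n, v in zip(self.factor_names, self.natural)},
            "coded": {n: float(v) for n, v in zip(self.factor_names, self.coded)},
            "predicted": {k: float(v) for k, v in self.predicted.items()},
            "individual_desirability": {k: float(v) for k, v in self.individual.items()},
            "D": float(self.D),
            "warning": self.warning,
        }


def _score(fits, goals, weights, x: np.ndarray) -> tuple:
    preds = [float(predict(f, x[None, :])[0]) for f in fits]
    ds = [individual_desirability(g, y) for g, y in zip(goals, preds)]
    return composite_D(ds, weights), preds, ds


def optimize(
    fits: Sequence[QuadraticFit],
    goals: Sequence[DesirabilityGoal],
    bounds: Sequence[tuple] | None = None,
    grid_points: int = 41,
) -> OptimumResult:
    """Maximize composite desirability over the coded design region.

    Deterministic two-stage search: dense grid (``grid_points`` per
    axis) followed by a Nelder-Mead polish from the best grid cell,
    clipped to the bounds.  ``bounds`` defaults to each factor's coded
    axial range taken from the first fit's design.
    """
    fits = list(fits)
    goals = list(goals)
    if len(fits) != len(goals):
        raise ValueError("need exactly one fit per goal")
    for f, g in zip(fits, goals):
        if f.response_name != g.response_name:
            raise ValueError(f"fit {f.response_name!r} paired with goal {g.response_name!r}")
    design = fits[0].design
    if bounds is None:
        if design is None:
            raise ValueError("no bounds given and fit carries no design")
        bounds = design.coded_bounds()
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    k = len(bounds)
    weights = np.array([g.weight for g in goals])

    # stage 1: vectorized grid evaluation
    axes = [np.linspace(lo, hi, grid_points) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    d_all = np.ones((len(pts), len(goals)))
    for j, (f, g) in enumerate(zip(fits, goals)):
        ys = predict(f, pts)
        d_all[:, j] = [individual_desirability(g, y) for y in ys]
    with np.errstate(divide="ignore"):
        logd = np.where(d_all > 0, np.log(np.maximum(d_all, 1e-300)), -np.inf)
        D_grid = np.exp((logd * weights).sum(axis=1) / weights.sum())
    D_grid = np.where(np.all(d_all > 0, axis=1), D_grid, 0.0)
    best_idx = int(np.argmax(D_grid))
    x0 = pts[best_idx]
    D_best_grid = float(D_grid[best_idx])

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def neg_D(x):
        return -_score(fits, goals, weights, np.clip(x, lo, hi))[0]

    res = minimize(neg_D, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    x_opt = np.clip(res.x, lo, hi)
    D_opt, preds, ds = _score(fits, goals, weights, x_opt)
    if D_opt < D_best_grid:  # polish never degrades the grid optimum
        x_opt = x0
        D_opt, preds, ds = _score(fits, goals, weights, x_opt)

    warning = None
    if D_opt == 0.0:
        warning = "composite desirability is 0 everywhere on the search grid; coordinates are best-effort"
        warnings.warn(warning)
    natural = (
        np.array([f.decode(c) for f, c in zip(design.factors, x_opt)]) if design is not None else x_opt.copy()
    )
    return OptimumResult(
        natural=natural,
        coded=x_opt,
        predicted={g.response_name: p for g, p in zip(goals, preds)},
        individual={g.response_name: d for g, d in zip(goals, ds)},
        D=D_opt,
        factor_names=tuple(design.factor_names) if design is not None else tuple(f"x{i+1}" for i in range(k)),
        warning=warning,
    )


@dataclass(frozen=True)
class ValidationRecord:
    """Agreement between a confirmatory experiment and the model prediction."""

    response_name: str
    experimental: float
    predicted: float
    std: float
    rsd_percent: float
    passed: bool


def validate(optimum: OptimumResult, experimental: dict) -> list:
    """RSD%-based validation of predicted responses at the optimum.

    For each response, std is the sample standard deviation of the
    (experimental, predicted) pair, |e - p| / sqrt(2), and
    RSD% = 100 * std / mean; RSD% < 10 passes.
    """
    records = []
    for name, pred in optimum.predicted.items():
        if name not in experimental:
            raise KeyError(f"no experimental value for response {name!r}")
        e = float(experimental[name])
        p = float(pred)
        std = abs(e - p) / np.sqrt(2.0)
        mean = 0.5 * (e + p)
        rsd = 100.0 * std / mean
        records.append(
            ValidationRecord(
                response_name=name,
                experimental=e,
                predicted=p,
                std=float(std),
                rsd_percent=float(rsd),
                passed=bool(rsd < RSD_PASS_THRESHOLD),
            )
        )
    return records
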