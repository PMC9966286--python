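"""Assay arithmetic: calibration curves, percent inhibition, IC50.

Colorimetric totals (phenolics as gallic-acid equivalents, flavonoids as
catechin equivalents) are read off linear calibration curves
y = slope * x + intercept fitted to standards.  Radical-scavenging and
enzyme-inhibition assays report

    % inhibition = 100 * (1 - Abs_sample / Abs_control)

which may legitimately go negative (pro-oxidant behaviour) and is never
silently capped.  IC50 -- the dose giving 50% inhibition -- is estimated
either by a four-parameter logistic (4PL) fit

    y(d) = bottom + (top - bottom) / (1 + (ic50 / d)^hill)

whose inflection dose is the IC50, or by linear interpolation in
log10-dose between the pair of doses bracketing 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationCurve",
    "DoseResponse",
    "IC50Estimate",
    "percent_inhibition",
    "to_equivalents",
    "four_pl",
    "estimate_ic50",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration ``absorbance = slope * concentration + intercept``."""

    slope: float
    intercept: float
    r2: float = 1.0
    analyte: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must lie in [0, 1]")

    def concentration(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope

    def absorbance(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    @classmethod
    def fit(cls, concentrations: Sequence[float], absorbances: Sequence[float], analyte: str = "", units: str = "") -> "CalibrationCurve":
        res = stats.linregress(concentrations, absorbances)
        return cls(slope=float(res.slope), intercept=float(res.intercept), r2=float(res.rvalue**2), analyte=analyte, units=units)


def percent_inhibition(abs_control: float, abs_sample: float) -> float:
    """100 * (1 - Abs_sample/Abs_control); negative values are reported as-is."""
    if abs_control <= 0:
        raise ValueError("control absorbance must be > 0")
    return 100.0 * (1.0 - abs_sample / abs_control)


def to_equivalents(curve: CalibrationCurve, absorbance: float) -> float:
    """Invert a calibration curve: concentration = (y - intercept) / slope."""
    return curve.concentration(absorbance)


@dataclass
class DoseResponse:
    """A dose--inhibition series (doses strictly increasing)."""

    doses: np.ndarray
    inhibition_percent: np.ndarray
    sd: np.ndarray | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.inhibition_percent = np.asarray(self.inhibition_percent, dtype=float)
        if self.doses.ndim != 1 or self.doses.shape != self.inhibition_percent.shape:
            raise ValueError("doses and inhibition must be 1-D and equal length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")


def four_pl(d, bottom, top, ic50, hill):
    """Four-parameter logistic in dose space; y(ic50) = (bottom+top)/2."""
    d = np.asarray(d, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / d) ** hill)


@dataclass(frozen=True)
class IC50Estimate:
    ic50: float
    method: str
    params: dict = field(default_factory=dict)
    rmse: float = float("nan")
    converged: bool = True


def _ic50_interpolate(dr: DoseResponse) -> IC50Estimate:
    y = dr.inhibition_percent
    d = dr.doses
    exact = np.where(y == 50.0)[0]
    if exact.size:
        return IC50Estimate(ic50=float(d[exact[0]]), method="interpolate")
    for i in range(len(d) - 1):
        lo, hi = y[i], y[i + 1]
        if (lo - 50.0) * (hi - 50.0) < 0:
            # linear in log10 dose between the bracketing pair
            f = (50.0 - lo) / (hi - lo)
            logc = np.log10(d[i]) + f * (np.log10(d[i + 1]) - np.log10(d[i]))
            return IC50Estimate(ic50=float(10**logc), method="interpolate")
    raise ValueError("50% inhibition not reached: no bracketing dose pair")


def _ic50_four_pl(dr: DoseResponse) -> IC50Estimate:
    d, y = dr.doses, dr.inhibition_percent
    if len(d) < 4:
        raise ValueError("4PL fitting needs at least 4 doses")
    # initialization from data quartiles: plateaus from extremes, ic50 from
    # the dose whose response is nearest the midpoint, hill sign from trend
    bottom0, top0 = float(y.min()), float(y.max())
    mid = 0.5 * (bottom0 + top0)
    ic50_0 = float(d[np.argmin(np.abs(y - mid))])
    increasing = y[-1] >= y[0]
    hill0 = 1.0 if increasing else -1.0
    span = max(top0 - bottom0, 1e-6)
    p0 = [bottom0, top0, ic50_0, hill0]
    lb = [bottom0 - span, top0 - span, d.min() / 1e3, -50.0]
    ub = [bottom0 + span, top0 + span, d.max() * 1e3, 50.0]
    try:
        popt, _ = curve_fit(four_pl, d, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"4PL fit did not converge: {exc}") from exc
    resid = y - four_pl(d, *popt)
    return IC50Estimate(
        ic50=float(popt[2]),
        method="four_pl",
        params={"bottom": float(popt[0]), "top": float(popt[1]), "ic50": float(popt[2]), "hill": float(popt[3])},
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_ic50(dr: DoseResponse, method: str = "four_pl") -> IC50Estimate:
    """Estimate IC50 from a dose--inhibition series.

    method : {"four_pl", "interpolate"}
        ``four_pl`` (default) falls back to log-dose interpolation if
        the logistic fit fails; ``interpolate`` raises if the series
        never crosses 50%.
    """
    if method == "interpolate":
        return _ic50_interpolate(dr)
    if method == "four_pl":
        try:
            return _ic50_four_pl(dr)
        except (RuntimeError, ValueError):
            est = _ic50_interpolate(dr)
            return IC50Estimate(ic50=est.ic50, method="interpolate_fallback", converged=False)
    raise ValueError(f"unknown method {method!r}")
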