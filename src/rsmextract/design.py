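"""Central composite designs (CCD) and factor coding.

A CCD for k factors consists of a full two-level factorial at the coded
levels ±1, two axial (star) points per factor, and replicated centre
points.  Factors are described in natural units by a centre and a step
(half the factorial range); coding is the affine map

    coded = (natural - center) / step

so the factorial levels land exactly on ±1.  Axial positions are given
directly in natural units, which permits a per-factor axial distance:
designs in the applied literature frequently place star points on round
natural values (0/100 % ethanol, 15/150 min, 40/80 degC) that code to
±2, ±1.8 and ±2 rather than a single rotatable alpha.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "CodedPoint",
    "CCDesign",
    "build_ccd",
    "code_point",
    "decode_point",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor in natural units.

    Parameters
    ----------
    name : str
        Column label, e.g. ``"ethanol"``.
    center : float
        Natural value that codes to 0.
    step : float
        Natural units per coded unit; half the factorial range. Must be > 0.
    axial_low, axial_high : float
        Natural positions of the star points; must lie strictly outside
        the factorial range ``center ± step``.
    units : str
        Free-text unit label (documentation only).
    """

    name: str
    center: float
    step: float
    axial_low: float
    axial_high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0, got {self.step}")
        if not (self.axial_low < self.center - self.step):
            raise ValueError(
                f"factor {self.name!r}: axial_low {self.axial_low} must lie below "
                f"the low factorial level {self.center - self.step}"
            )
        if not (self.axial_high > self.center + self.step):
            raise ValueError(
                f"factor {self.name!r}: axial_high {self.axial_high} must lie above "
                f"the high factorial level {self.center + self.step}"
            )

    def code(self, natural: float) -> float:
        return (natural - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + self.step * coded

    @property
    def coded_axial_low(self) -> float:
        return self.code(self.axial_low)

    @property
    def coded_axial_high(self) -> float:
        return self.code(self.axial_high)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "center": self.center,
            "step": self.step,
            "axial_low": self.axial_low,
            "axial_high": self.axial_high,
            "units": self.units,
        }


@dataclass(frozen=True)
class CodedPoint:
    """A point in coded (dimensionless) factor space."""

    values: tuple
    extrapolated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class CCDesign:
    """A central composite design: factors plus the run list in natural units.

    ``runs`` rows are in canonical order: the full factorial in standard
    order (first factor cycling fastest), then axial pairs factor by
    factor (low before high), then the centre replicates.
    """

    factors: tuple
    n_center: int
    runs: pd.DataFrame = field(compare=False)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_factorial(self) -> int:
        return 2 ** self.k

    @property
    def n_axial(self) -> int:
        return 2 * self.k

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def factor_names(self) -> list:
        return [f.name for f in self.factors]

    def coded_matrix(self, natural: np.ndarray | pd.DataFrame | None = None) -> np.ndarray:
        """Code a (n, k) natural-unit array; defaults to the design's own runs."""
        if natural is None:
            natural = self.runs[self.factor_names].to_numpy()
        elif isinstance(natural, pd.DataFrame):
            natural = natural[self.factor_names].to_numpy()
        natural = np.asarray(natural, dtype=float)
        centers = np.array([f.center for f in self.factors])
        steps = np.array([f.step for f in self.factors])
        return (natural - centers) / steps

    def coded_bounds(self) -> list:
        """Per-factor coded (low, high) spanning the axial points."""
        return [(f.coded_axial_low, f.coded_axial_high) for f in self.factors]

    def to_csv(self, path, responses: pd.DataFrame | None = None) -> None:
        """Write the run list (plus optional response columns) and a JSON sidecar."""
        frame = self.runs.copy()
        if responses is not None:
            frame = pd.concat([frame, responses.reset_index(drop=True)], axis=1)
        frame.to_csv(path, index=False)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(
                {"factors": [f.to_dict() for f in self.factors], "n_center": self.n_center},
                fh,
                indent=2,
            )

    @classmethod
    def from_sidecar(cls, sidecar_path) -> "CCDesign":
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        factors = [FactorSpec(**d) for d in meta["factors"]]
        return build_ccd(factors, meta["n_center"])


def build_ccd(factors: Sequence[FactorSpec], n_center: int) -> CCDesign:
    """Construct a face-general central composite design.

    Run count is ``2^k + 2k + n_center``.  Each factor takes exactly five
    distinct natural levels (axial_low, center-step, center, center+step,
    axial_high).

    Raises
    ------
    ValueError
        If fewer than two factors, ``n_center < 1``, or a factor's axial
        bounds fall inside its factorial range (checked by FactorSpec).
    """
    factors = tuple(factors)
    if len(factors) < 2:
        raise ValueError("a CCD needs at least two factors")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    k = len(factors)
    centers = np.array([f.center for f in factors])
    rows = []
    point_type = []
    # factorial portion, standard order: first factor cycles fastest
    for signs in itertools.product([-1.0, 1.0], repeat=k):
        signs = signs[::-1]
        rows.append([f.center + s * f.step for f, s in zip(factors, signs)])
        point_type.append("factorial")
    for i, f in enumerate(factors):
        for level in (f.axial_low, f.axial_high):
            row = centers.copy()
            row[i] = level
            rows.append(list(row))
            point_type.append("axial")
    for _ in range(n_center):
        rows.append(list(centers))
        point_type.append("center")
    runs = pd.DataFrame(rows, columns=[f.name for f in factors])
    runs["point_type"] = point_type
    return CCDesign(factors=factors, n_center=n_center, runs=runs)


def code_point(design: CCDesign, natural: Sequence[float]) -> CodedPoint:
    """Code a natural-unit point; flags extrapolation beyond the axial box."""
    natural = np.asarray(natural, dtype=float)
    if natural.shape != (design.k,):
        raise ValueError(f"expected {design.k} coordinates, got {natural.shape}")
    coded = [f.code(x) for f, x in zip(design.factors, natural)]
    extrap = any(
        c < f.coded_axial_low - 1e-12 or c > f.coded_axial_high + 1e-12
        for f, c in zip(design.factors, coded)
    )
    return CodedPoint(values=tuple(coded), extrapolated=extrap)


def decode_point(design: CCDesign, coded: CodedPoint | Sequence[float]) -> np.ndarray:
    """Exact inverse of :func:`code_point` (natural = center + step * coded)."""
    values = coded.as_array() if isinstance(coded, CodedPoint) else np.asarray(coded, dtype=float)
    if values.shape != (design.k,):
        raise ValueError(f"expected {design.k} coordinates, got {values.shape}")
    return np.array([f.decode(c) for f, c in zip(design.factors, values)])


def shuffle_runs(design: CCDesign, seed: int) -> pd.DataFrame:
    """Convenience seed-based randomization of the run order (rows only)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(design.n_runs)
    return design.runs.iloc[order].reset_index(drop=True)
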