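"""Seeded generators emulating the statistical structure of each analysis
stage: quadratic response surfaces with i.i.d. Gaussian noise over a CCD,
four-parameter-logistic dose--response curves, and sample x variable
activity matrices with a single-factor (equicorrelation) latent
structure.  Every generator is a pure function of its parameters and
seed; seeds are explicit arguments, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import DoseResponse, four_pl
from .design import CCDesign
from .rsm import RunTable, quadratic_matrix, quadratic_terms

__all__ = [
    "SurfaceTruth",
    "simulate_ccd_responses",
    "simulate_dose_response",
    "simulate_activity_matrix",
]


@dataclass(frozen=True)
class SurfaceTruth:
    """A known quadratic surface in coded units plus a noise level.

    ``coef`` maps canonical term names (as produced by
    :func:`rsmextract.rsm.quadratic_terms`) to coefficients; omitted
    terms are zero.
    """

    coef: tuple  # (term, value) pairs
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "coef", tuple((str(t), float(v)) for t, v in dict(self.coef).items()))

    def coef_vector(self, factor_names) -> pd.Series:
        terms = quadratic_terms(factor_names)
        lookup = dict(self.coef)
        unknown = set(lookup) - set(terms)
        if unknown:
            raise ValueError(f"truth has terms not in the quadratic model: {sorted(unknown)}")
        return pd.Series([lookup.get(t, 0.0) for t in terms], index=terms)

    def evaluate(self, coded: np.ndarray, factor_names) -> np.ndarray:
        beta = self.coef_vector(factor_names)
        X = quadratic_matrix(np.atleast_2d(coded), factor_names)
        return X.to_numpy() @ beta.to_numpy()


def simulate_ccd_responses(
    design: CCDesign,
    truth: SurfaceTruth,
    response_name: str = "Y",
) -> RunTable:
    """Draw one response per design run: surface value + N(0, sigma^2)."""
    coded = design.coded_matrix()
    mean = truth.evaluate(coded, design.factor_names)
    rng = np.random.default_rng(truth.seed)
    y = mean + rng.normal(0.0, truth.sigma, size=len(mean))
    data = design.runs[design.factor_names].copy()
    data[response_name] = y
    return RunTable(design=design, data=data, response_names=(response_name,))


def simulate_dose_response(
    ic50: float,
    hill: float,
    bottom: float,
    top: float,
    doses,
    sigma: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """4PL mean curve sampled at ``doses`` with Gaussian noise."""
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    mean = four_pl(doses, bottom, top, ic50, hill)
    rng = np.random.default_rng(seed)
    y = mean + rng.normal(0.0, sigma, size=len(doses))
    return DoseResponse(doses=doses, inhibition_percent=y)


def simulate_activity_matrix(
    n_samples: int,
    n_vars: int,
    latent_corr: float,
    seed: int = 0,
    var_prefix: str = "V",
) -> pd.DataFrame:
    """Single-latent-factor matrix with expected pairwise correlation
    ``latent_corr``: x_ij = sqrt(rho) z_i + sqrt(1-rho) e_ij with z and e
    standard normal, so corr(x_.j, x_.k) = rho and the population
    correlation matrix is equicorrelated (top eigenvalue 1+(p-1)rho).
    """
    if not 0 <= latent_corr < 1:
        raise ValueError("latent_corr must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_samples, 1))
    eps = rng.normal(size=(n_samples, n_vars))
    x = np.sqrt(latent_corr) * z + np.sqrt(1.0 - latent_corr) * eps
    return pd.DataFrame(
        x,
        index=[f"S{i+1}" for i in range(n_samples)],
        columns=[f"{var_prefix}{j+1}" for j in range(n_vars)],
    )
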