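"""Second-order response-surface fitting and ANOVA.

The full quadratic model for k coded factors x_1..x_k is

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

fitted by ordinary least squares on coded predictors.  The ANOVA
decomposition reports partial (Type-III-style) sums of squares per term
— the extra sum of squares of the term given all others; for a CCD the
linear columns are orthogonal to everything else so partial and
sequential SS coincide for them.  Replicated runs provide a pure-error
estimate and hence a lack-of-fit test:

    SS_residual = SS_lack_of_fit + SS_pure_error
    F_LOF = MS_LOF / MS_PE

Fit statistics follow response-surface software conventions:
R^2 = SS_model/SS_total, adjusted R^2 = 1-(1-R^2)(n-1)/(n-p),
CV% = 100 sqrt(MSE)/mean(y), and adequate precision (a signal-to-noise
ratio) = range of fitted values over the design points divided by
sqrt(p * MSE / n).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import CCDesign, CodedPoint

__all__ = [
    "RunTable",
    "QuadraticFit",
    "AnovaTable",
    "quadratic_terms",
    "quadratic_matrix",
    "fit_quadratic",
    "anova",
    "predict",
    "reduce_model",
    "surface_grid",
]


def quadratic_terms(factor_names: Sequence[str]) -> list:
    """Canonical term order: intercept, linear, interactions (i<j), squares."""
    names = list(factor_names)
    terms = ["Intercept"] + names
    terms += [f"{a}:{b}" for i, a in enumerate(names) for b in names[i + 1 :]]
    terms += [f"{n}^2" for n in names]
    return terms


def quadratic_matrix(coded: np.ndarray, factor_names: Sequence[str], terms: Sequence[str] | None = None) -> pd.DataFrame:
    """Model matrix for the quadratic polynomial on coded coordinates."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    names = list(factor_names)
    cols = {"Intercept": np.ones(len(coded))}
    for i, n in enumerate(names):
        cols[n] = coded[:, i]
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            cols[f"{a}:{names[j]}"] = coded[:, i] * coded[:, j]
    for i, n in enumerate(names):
        cols[f"{n}^2"] = coded[:, i] ** 2
    frame = pd.DataFrame(cols)
    if terms is not None:
        frame = frame[list(terms)]
    return frame


@dataclass
class RunTable:
    """A design together with measured responses, aligned row by row.

    ``data`` holds one column per factor (natural units) and one per
    response.  Rows may appear in any (e.g. randomized) order; they are
    matched to the design by factor settings, never by position, and the
    multiset of factor combinations must equal the design's.
    """

    design: CCDesign
    data: pd.DataFrame
    response_names: tuple
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.response_names = tuple(self.response_names)
        missing = [c for c in self.design.factor_names + list(self.response_names) if c not in self.data.columns]
        if missing:
            raise ValueError(f"run table missing columns: {missing}")
        if self.data[list(self.response_names)].isna().any().any():
            raise ValueError("run table has missing response values")
        self._check_matches_design()

    def _check_matches_design(self) -> None:
        fcols = self.design.factor_names
        key = lambda df: sorted(map(tuple, np.round(df[fcols].to_numpy(dtype=float), 9)))
        if key(self.data) != key(self.design.runs):
            raise ValueError("run table factor settings do not match the design's run list")

    @property
    def n_runs(self) -> int:
        return len(self.data)

    def coded(self) -> np.ndarray:
        return self.design.coded_matrix(self.data[self.design.factor_names])

    def response(self, name: str) -> np.ndarray:
        if name not in self.response_names:
            raise KeyError(f"unknown response {name!r}; have {list(self.response_names)}")
        return self.data[name].to_numpy(dtype=float)

    def replicate_groups(self) -> list:
        """Row-index groups sharing identical factor settings (>= 2 rows)."""
        fcols = self.design.factor_names
        keys = [tuple(np.round(r, 9)) for r in self.data[fcols].to_numpy(dtype=float)]
        groups: dict = {}
        for i, k in enumerate(keys):
            groups.setdefault(k, []).append(i)
        return [idx for idx in groups.values() if len(idx) >= 2]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design: CCDesign, response_names: Sequence[str], units: dict | None = None) -> "RunTable":
        data = pd.read_csv(path)
        return cls(design=design, data=data, response_names=tuple(response_names), units=units or {})


@dataclass
class QuadraticFit:
    """OLS fit of the (possibly reduced) quadratic model in coded units."""

    response_name: str
    factor_names: tuple
    terms: tuple
    coef: pd.Series
    residual_dof: int
    mse: float
    fitted_values: np.ndarray
    residuals: np.ndarray
    coef_se: pd.Series
    design: CCDesign | None = None

    @property
    def intercept(self) -> float:
        return float(self.coef.get("Intercept", 0.0))

    @property
    def linear(self) -> pd.Series:
        return self.coef.reindex([n for n in self.factor_names if n in self.coef.index])

    @property
    def quadratic(self) -> pd.Series:
        return self.coef[[t for t in self.coef.index if t.endswith("^2")]]

    @property
    def interactions(self) -> pd.Series:
        return self.coef[[t for t in self.coef.index if ":" in t]]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def natural_coefficients(self) -> pd.Series:
        """Re-express the polynomial in natural units (expanded form)."""
        if self.design is None:
            raise ValueError("fit carries no design; natural-unit form unavailable")
        centers = {f.name: f.center for f in self.design.factors}
        steps = {f.name: f.step for f in self.design.factors}
        out = dict.fromkeys(self.terms, 0.0)
        # substitute x_i = (X_i - c_i)/s_i and expand term by term
        for term, b in self.coef.items():
            if term == "Intercept":
                out["Intercept"] += b
            elif term.endswith("^2"):
                n = term[:-2]
                c, s = centers[n], steps[n]
                out[term] = out.get(term, 0.0) + b / s**2
                out[n] = out.get(n, 0.0) - 2 * b * c / s**2
                out["Intercept"] += b * c**2 / s**2
            elif ":" in term:
                a, bname = term.split(":")
                ca, sa, cb, sb = centers[a], steps[a], centers[bname], steps[bname]
                out[term] = out.get(term, 0.0) + b / (sa * sb)
                out[a] = out.get(a, 0.0) - b * cb / (sa * sb)
                out[bname] = out.get(bname, 0.0) - b * ca / (sa * sb)
                out["Intercept"] += b * ca * cb / (sa * sb)
            else:
                c, s = centers[term], steps[term]
                out[term] = out.get(term, 0.0) + b / s
                out["Intercept"] += -b * c / s
        return pd.Series(out)


def fit_quadratic(table: RunTable, response: str, terms: Sequence[str] | None = None) -> QuadraticFit:
    """Fit the full second-order model by OLS on coded predictors.

    Parameters
    ----------
    table : RunTable
    response : str
        Name of the response column to fit.
    terms : sequence of str, optional
        Subset of the canonical terms (used by :func:`reduce_model`).

    Raises
    ------
    ValueError
        If the model matrix is rank deficient; the message names the
        aliased terms.
    """
    y = table.response(response)
    all_terms = quadratic_terms(table.design.factor_names)
    terms = list(terms) if terms is not None else all_terms
    unknown = [t for t in terms if t not in all_terms]
    if unknown:
        raise ValueError(f"unknown model terms: {unknown}")
    X = quadratic_matrix(table.coded(), table.design.factor_names, terms)
    A = X.to_numpy(dtype=float)
    if len(y) < A.shape[1]:
        raise ValueError(f"need at least {A.shape[1]} runs for {A.shape[1]} terms, have {len(y)}")
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the aliased columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(A, pivoting=True)
        aliased = sorted(X.columns[i] for i in piv[rank:])
        raise ValueError(f"rank-deficient design: aliased terms {aliased}")
    res = sm.OLS(y, X).fit()
    dof = len(y) - A.shape[1]
    mse = float(res.ssr / dof) if dof > 0 else 0.0
    return QuadraticFit(
        response_name=response,
        factor_names=tuple(table.design.factor_names),
        terms=tuple(terms),
        coef=pd.Series(res.params, index=X.columns),
        residual_dof=dof,
        mse=mse,
        fitted_values=np.asarray(res.fittedvalues, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        coef_se=pd.Series(res.bse, index=X.columns) if dof > 0 else pd.Series(np.nan, index=X.columns),
        design=table.design,
    )


@dataclass
class AnovaTable:
    """Per-term ANOVA with model, lack-of-fit and pure-error rows."""

    table: pd.DataFrame  # index: term rows + Model/Lack of fit/Pure error/Residual/Total
    r2: float
    adj_r2: float
    cv_percent: float
    adeq_precision: float
    response_name: str
    pure_error_dof: int

    def __post_init__(self) -> None:
        if not self.adj_r2 <= self.r2 + 1e-12:
            raise ValueError("adjusted R^2 exceeds R^2")

    def significance(self, term: str) -> str:
        return str(self.table.loc[term, "signif"])

    def to_json_dict(self) -> dict:
        d = {
            "response": self.response_name,
            "R2": self.r2,
            "adj_R2": self.adj_r2,
            "CV_percent": self.cv_percent,
            "adeq_precision": self.adeq_precision,
            "rows": self.table.reset_index().rename(columns={"index": "source"}).to_dict("records"),
        }
        return d


def anova(fit: QuadraticFit, table: RunTable, alpha: float = 0.05) -> AnovaTable:
    """ANOVA decomposition of a quadratic fit.

    Per-term SS are partial (extra SS of the term given all others).
    Pure error comes from replicate groups; if none exist the
    lack-of-fit and pure-error rows are absent and flagged NaN.
    """
    y = table.response(fit.response_name)
    n = len(y)
    p = fit.n_terms
    X = quadratic_matrix(table.coded(), table.design.factor_names, fit.terms)
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_res = float(fit.residuals @ fit.residuals)
    ss_model = ss_total - ss_res
    dof_res = fit.residual_dof
    mse = fit.mse

    rows = []
    fdist = stats.f

    def row(source, ss, dof):
        ms = ss / dof if dof > 0 else np.nan
        if mse > 0 and dof_res > 0:
            F = ms / mse
            pval = float(fdist.sf(F, dof, dof_res))
        else:
            F, pval = np.nan, np.nan
        return {"source": source, "SS": ss, "dof": dof, "MS": ms, "F": F, "p": pval}

    rows.append(row("Model", ss_model, p - 1))
    A_full = X.to_numpy(dtype=float)
    for term in fit.terms:
        if term == "Intercept":
            continue
        A_red = X.drop(columns=term).to_numpy(dtype=float)
        beta_red, *_ = np.linalg.lstsq(A_red, y, rcond=None)
        ssr_red = float(((y - A_red @ beta_red) ** 2).sum())
        rows.append(row(term, ssr_red - ss_res, 1))

    groups = table.replicate_groups()
    if groups:
        ss_pe = 0.0
        dof_pe = 0
        for idx in groups:
            g = y[idx]
            ss_pe += float(((g - g.mean()) ** 2).sum())
            dof_pe += len(g) - 1
        ss_lof = ss_res - ss_pe
        dof_lof = dof_res - dof_pe
        ms_pe = ss_pe / dof_pe if dof_pe > 0 else np.nan
        ms_lof = ss_lof / dof_lof if dof_lof > 0 else np.nan
        if dof_pe > 0 and dof_lof > 0 and ms_pe > 0:
            F_lof = ms_lof / ms_pe
            p_lof = float(fdist.sf(F_lof, dof_lof, dof_pe))
        else:
            F_lof, p_lof = np.nan, np.nan
        rows.append({"source": "Lack of fit", "SS": ss_lof, "dof": dof_lof, "MS": ms_lof, "F": F_lof, "p": p_lof})
        rows.append({"source": "Pure error", "SS": ss_pe, "dof": dof_pe, "MS": ms_pe, "F": np.nan, "p": np.nan})
        pe_dof = dof_pe
    else:
        pe_dof = 0
    rows.append({"source": "Residual", "SS": ss_res, "dof": dof_res, "MS": mse if dof_res else np.nan, "F": np.nan, "p": np.nan})
    rows.append({"source": "Total", "SS": ss_total, "dof": n - 1, "MS": np.nan, "F": np.nan, "p": np.nan})

    frame = pd.DataFrame(rows).set_index("source")
    frame["signif"] = [
        ("Significant" if pv < alpha else "Nonsignificant") if np.isfinite(pv) else ""
        for pv in frame["p"]
    ]

    r2 = ss_model / ss_total if ss_total > 0 else np.nan
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - p) if n > p else np.nan
    cv = 100 * np.sqrt(mse) / y.mean() if y.mean() != 0 else np.nan
    yhat = fit.fitted_values
    adeq = (yhat.max() - yhat.min()) / np.sqrt(p * mse / n) if mse > 0 else np.inf
    return AnovaTable(
        table=frame,
        r2=float(r2),
        adj_r2=float(adj_r2),
        cv_percent=float(cv),
        adeq_precision=float(adeq),
        response_name=fit.response_name,
        pure_error_dof=pe_dof,
    )


def predict(fit: QuadraticFit, points) -> np.ndarray:
    """Evaluate the fitted polynomial at coded points.

    ``points`` may be a CodedPoint, a sequence of them, or an (n, k)
    array of coded coordinates.
    """
    if isinstance(points, CodedPoint):
        arr = points.as_array()[None, :]
    elif len(points) and isinstance(points[0], CodedPoint):
        arr = np.vstack([p.as_array() for p in points])
    else:
        arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.shape[1] != len(fit.factor_names):
        raise ValueError(f"expected {len(fit.factor_names)} coded coordinates per point")
    X = quadratic_matrix(arr, fit.factor_names, fit.terms)
    return X.to_numpy(dtype=float) @ fit.coef.to_numpy()


def _hierarchy_parents(term: str) -> list:
    """Lower-order terms protected while ``term`` is in the model."""
    if term == "Intercept":
        return []
    if term.endswith("^2"):
        return [term[:-2]]
    if ":" in term:
        return term.split(":")
    return []


def reduce_model(fit: QuadraticFit, table: RunTable, alpha: float = 0.05) -> QuadraticFit:
    """Backward elimination of non-significant terms, preserving hierarchy.

    At each step the removable term with the largest partial-F p-value
    above ``alpha`` is dropped (ties broken by canonical term order) and
    the model refitted.  A linear term is protected while any
    higher-order term containing its factor remains; the intercept is
    never removed.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    current = fit
    while True:
        tbl = anova(current, table)
        protected = {"Intercept"}
        for t in current.terms:
            protected.update(_hierarchy_parents(t))
        candidates = [
            (float(tbl.table.loc[t, "p"]), i, t)
            for i, t in enumerate(current.terms)
            if t not in protected and np.isfinite(tbl.table.loc[t, "p"]) and tbl.table.loc[t, "p"] > alpha
        ]
        if not candidates:
            return current
        # drop the largest p; ties by canonical order (smaller index first)
        candidates.sort(key=lambda c: (-c[0], c[1]))
        drop = candidates[0][2]
        current = fit_quadratic(table, fit.response_name, [t for t in current.terms if t != drop])


def surface_grid(
    fit: QuadraticFit,
    design: CCDesign,
    fixed: dict,
    resolution: int = 25,
) -> pd.DataFrame:
    """Prediction grid over two free factors for external surface plotting.

    ``fixed`` maps factor name -> natural value for all but exactly two
    factors; the free factors sweep their axial range.  Returns a
    (resolution^2)-row table of natural coordinates and predictions.
    """
    free = [f for f in design.factors if f.name not in fixed]
    if len(free) != 2:
        raise ValueError(f"exactly 2 factors must be free, got {len(free)}")
    axes = [np.linspace(f.axial_low, f.axial_high, resolution) for f in free]
    g1, g2 = np.meshgrid(axes[0], axes[1], indexing="ij")
    natural = {free[0].name: g1.ravel(), free[1].name: g2.ravel()}
    for name, val in fixed.items():
        natural[name] = np.full(resolution**2, float(val))
    nat = np.column_stack([natural[f.name] for f in design.factors])
    coded = design.coded_matrix(nat)
    preds = predict(fit, coded)
    out = pd.DataFrame({f.name: natural[f.name] for f in design.factors})
    out[fit.response_name] = preds
    return out
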