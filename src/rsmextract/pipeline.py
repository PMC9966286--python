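"""End-to-end orchestration: design/fit -> ANOVA -> desirability optimum
-> validation -> chemometrics -> MS annotation, from a single config.

The pipeline is deterministic and idempotent: rerunning an identical
config writes byte-identical JSON (no timestamps; fixed key order;
numbers rounded to 6 significant digits in the report, full precision in
the delimited outputs).  Any stage failure raises PipelineError tagged
with the stage name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .chemometrics import hca, pca, pearson_matrix
from .design import CCDesign, FactorSpec, build_ccd
from .desirability import DesirabilityGoal, optimize, validate
from .msannotate import annotate_peak
from .rsm import RunTable, anova, fit_quadratic, reduce_model

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Any path left ``None`` falls back to the packaged study fixture for
    that stage; a stage with no input and no fixture fallback is
    skipped.  ``goals`` entries may give explicit ``lower``/``upper``
    bounds or the string ``"observed"`` to use the response's min/max
    over the run table.
    """

    runs_path: str | None = None
    factors_path: str | None = None
    responses: tuple = ("TPC", "TFC")
    alpha: float = 0.05
    reduce: bool = False
    goals: list = field(default_factory=list)
    experimental: dict = field(default_factory=dict)
    activity_matrix_path: str | None = "packaged"
    peaks_path: str | None = "packaged"
    hca_linkage: str = "ward"
    annotation_tol_da: float = 0.05
    grid_points: int = 41
    out_dir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)


def _round_sig(x, sig=6):
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return None
        return float(f"{x:.{sig}g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _load_runs(config: PipelineConfig) -> RunTable:
    if config.runs_path is None:
        return datasets.load_extraction_runs()
    if config.factors_path is None:
        raise PipelineError("load", "runs_path given without factors_path sidecar")
    meta = json.loads(Path(config.factors_path).read_text())
    design = build_ccd([FactorSpec(**d) for d in meta["factors"]], meta["n_center"])
    data = pd.read_csv(config.runs_path)
    missing = [r for r in config.responses if r not in data.columns]
    if missing:
        raise PipelineError("load", f"responses not in run table: {missing}")
    return RunTable(design=design, data=data, response_names=tuple(config.responses))


def _build_goals(config: PipelineConfig, table: RunTable) -> list:
    if config.goals:
        entries = config.goals
    else:
        entries = [{"response": r, "goal": "maximize", "lower": "observed", "upper": "observed"} for r in config.responses]
    goals = []
    for e in entries:
        name = e["response"]
        y = table.response(name)
        lower = float(y.min()) if e.get("lower", "observed") == "observed" else float(e["lower"])
        upper = float(y.max()) if e.get("upper", "observed") == "observed" else float(e["upper"])
        goals.append(
            DesirabilityGoal(
                response_name=name,
                goal=e.get("goal", "maximize"),
                lower=lower,
                upper=upper,
                weight=float(e.get("weight", 1.0)),
                exponent=float(e.get("exponent", 1.0)),
            )
        )
    return goals


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns the combined report dict; writes per-stage delimited outputs
    and ``report.json`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {k: v for k, v in vars(config).items() if k != "out_dir"}
    report: dict = {"config": _round_sig(cfg)}
    report["config"]["responses"] = list(config.responses)
    report["config"]["goals"] = [dict(g) for g in config.goals]

    # ---- fit + ANOVA ----
    try:
        table = _load_runs(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    try:
        fits = {}
        anova_section = {}
        for resp in config.responses:
            fit = fit_quadratic(table, resp)
            if config.reduce:
                fit = reduce_model(fit, table, config.alpha)
            tbl = anova(fit, table, alpha=config.alpha)
            fits[resp] = fit
            tbl.table.to_csv(out / f"anova_{resp}.csv")
            fit.coef.rename("coefficient").to_csv(out / f"coefficients_{resp}.csv")
            anova_section[resp] = {
                "coefficients": fit.coef.to_dict(),
                "R2": tbl.r2,
                "adj_R2": tbl.adj_r2,
                "CV_percent": tbl.cv_percent,
                "adeq_precision": tbl.adeq_precision,
                "pure_error_SS": float(tbl.table.loc["Pure error", "SS"]) if "Pure error" in tbl.table.index else None,
                "lack_of_fit_p": float(tbl.table.loc["Lack of fit", "p"]) if "Lack of fit" in tbl.table.index else None,
            }
        report["anova"] = _round_sig(anova_section)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    # ---- desirability optimization ----
    try:
        goals = _build_goals(config, table)
        opt = optimize([fits[g.response_name] for g in goals], goals, grid_points=config.grid_points)
        report["optimum"] = _round_sig(opt.to_json_dict())
    except Exception as exc:
        raise PipelineError("optimize", str(exc)) from exc

    # ---- validation ----
    try:
        experimental = dict(config.experimental)
        if not experimental and config.runs_path is None:
            experimental = datasets.load_validation_pairs()["experimental"].to_dict()
            predicted = datasets.load_validation_pairs()["predicted"].to_dict()
            from .desirability import OptimumResult

            published_opt = OptimumResult(
                natural=opt.natural, coded=opt.coded, predicted=predicted,
                individual=opt.individual, D=opt.D, factor_names=opt.factor_names,
            )
            records = validate(published_opt, experimental)
        elif experimental:
            records = validate(opt, experimental)
        else:
            records = []
        if records:
            frame = pd.DataFrame([vars(r) for r in records])
            frame.to_csv(out / "validation.csv", index=False)
            report["validation"] = _round_sig(frame.to_dict("records"))
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc

    # ---- chemometrics ----
    if config.activity_matrix_path is not None:
        try:
            if config.activity_matrix_path == "packaged":
                matrix = datasets.load_activity_matrix()
            else:
                matrix = pd.read_csv(config.activity_matrix_path, index_col=0)
            rho, pval, flags = pearson_matrix(matrix)
            rho.to_csv(out / "pearson_rho.csv")
            pval.to_csv(out / "pearson_p.csv")
            res = pca(matrix)
            res.scores.to_csv(out / "pca_scores.csv")
            res.loadings.to_csv(out / "pca_loadings.csv")
            tree = hca(matrix, linkage=config.hca_linkage)
            (out / "hca.nwk").write_text(tree.to_newick() + "\n")
            report["chemometrics"] = _round_sig(
                {
                    "eigenvalues": list(res.eigenvalues),
                    "explained_percent": list(res.explained_percent),
                    "hca_linkage": config.hca_linkage,
                    "clusters_k3": tree.cut(3),
                }
            )
        except Exception as exc:
            raise PipelineError("chemometrics", str(exc)) from exc

    # ---- MS annotation ----
    if config.peaks_path is not None:
        try:
            if config.peaks_path == "packaged":
                peaks = datasets.load_peak_table()
            else:
                peaks = pd.read_csv(config.peaks_path)
            rows = []
            for _, r in peaks.iterrows():
                frags = [float(v) for v in str(r.get("fragments", "")).split(";") if v.strip()]
                pk = annotate_peak(
                    r["formula"], float(r["observed_mz"]), frags,
                    tol_da=config.annotation_tol_da, name=str(r.get("name", "")),
                )
                rows.append(
                    {
                        "name": pk.name,
                        "formula": str(pk.formula),
                        "observed_mz": pk.observed_mz,
                        "calculated_mz": round(pk.calculated_mz, 4),
                        "ppm_error": round(pk.ppm, 2),
                        "matched_losses": "; ".join(
                            f"{m.fragment_mz}<-{'|'.join(m.matched)}" for m in pk.precursor_losses if m.matched
                        ),
                    }
                )
            annotated = pd.DataFrame(rows)
            annotated.to_csv(out / "annotated_peaks.csv", index=False)
            report["annotation"] = {
                "n_peaks": len(annotated),
                "max_abs_ppm": _round_sig(float(annotated["ppm_error"].abs().max())),
                "n_fragments_matched": int(sum(bool(s) for s in annotated["matched_losses"])),
            }
        except Exception as exc:
            raise PipelineError("annotate", str(exc)) from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
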