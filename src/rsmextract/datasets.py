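"""Packaged study data for the unripe Ajwa date pulp (URADP) extraction
optimization: the 20-run central composite design with measured total
phenolic/flavonoid contents, the confirmatory validation pairs, the
negative-mode ESI-MS peak table, and a sample x activity matrix.

The run table, validation pairs and peak table transcribe published
experimental results.  Eight peak-table rows carry formula/mass pairs
that are internally inconsistent under exact-mass arithmetic
(transcription errors in the source table, e.g. a calculated 293.0216
for C18H30O3 where the formula implies 293.2117); these are flagged
``cm_consistent = False`` and preserved verbatim rather than corrected.

The activity matrix is a SYNTHETIC reconstruction: only one of its
seven rows (the optimized extract) and a handful of other cells were
ever published, so the remaining cells are plausible values chosen to
respect every published number and ordering.  Conclusions drawn from it
characterize the fixture, not the original experiment.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .assay import CalibrationCurve
from .design import CCDesign, FactorSpec, build_ccd
from .rsm import RunTable

__all__ = [
    "extraction_factors",
    "extraction_design",
    "load_extraction_runs",
    "load_validation_pairs",
    "load_peak_table",
    "load_activity_matrix",
    "TPC_CALIBRATION",
    "TFC_CALIBRATION",
]

# linear standard curves: absorbance = slope * concentration + intercept
TPC_CALIBRATION = CalibrationCurve(slope=0.0512, intercept=0.0018, r2=0.9835, analyte="gallic acid", units="mgGAE/g")
TFC_CALIBRATION = CalibrationCurve(slope=0.0140, intercept=0.0021, r2=0.9994, analyte="catechin", units="mgCAE/g")


def _data(name: str):
    return resources.files("rsmextract") / "data" / name


def extraction_factors() -> list:
    """The three extraction factors: ethanol %, time (min), temperature (degC)."""
    meta = json.loads(_data("extraction_factors.json").read_text())
    return [FactorSpec(**d) for d in meta["factors"]]


def extraction_design() -> CCDesign:
    """The 3-factor, 5-level, 20-run CCD (2^3 factorial + 6 axial + 6 center)."""
    meta = json.loads(_data("extraction_factors.json").read_text())
    return build_ccd([FactorSpec(**d) for d in meta["factors"]], meta["n_center"])


def load_extraction_runs() -> RunTable:
    """The 20 design runs with measured TPC (mgGAE/g) and TFC (mgCAE/g)."""
    meta = json.loads(_data("extraction_factors.json").read_text())
    with resources.as_file(_data("extraction_runs.csv")) as path:
        data = pd.read_csv(path)
    return RunTable(
        design=extraction_design(),
        data=data,
        response_names=tuple(meta["responses"]),
        units=dict(meta["responses"]),
    )


def load_validation_pairs() -> pd.DataFrame:
    """Confirmatory experimental means (+/- sd) vs model predictions at the optimum."""
    with resources.as_file(_data("validation_pairs.csv")) as path:
        return pd.read_csv(path, index_col="response")


def load_peak_table() -> pd.DataFrame:
    """The 67-row ESI-MS peak table (formula, observed/calculated [M-H]- m/z,
    semicolon-separated fragment m/z, and the ``cm_consistent`` flag)."""
    with resources.as_file(_data("peak_table.csv")) as path:
        return pd.read_csv(path)


def load_activity_matrix() -> pd.DataFrame:
    """Synthetic 7 extracts x 7 activity variables matrix (see module docstring)."""
    with resources.as_file(_data("activity_matrix_synthetic.csv")) as path:
        return pd.read_csv(path, index_col="sample")
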