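# rsmextract

A toolkit for response-surface optimization of natural-product
extraction and the downstream characterization of the optimized extract.
It was built around a complete worked study — maximizing the polyphenol
yield of unripe Ajwa date (*Phoenix dactylifera*) pulp over ethanol
concentration, extraction time and temperature — whose 20-run data set,
validation pairs and ESI-MS peak table ship with the package, but every
component is generic and works on any run table you supply.

Audience: analytical chemists and food/pharma scientists running
design-of-experiments extraction studies, and anyone who needs the
statistics behind a central-composite-design study to be reproducible
and testable rather than locked inside point-and-click software.

## What it computes

**Design** (`rsmextract.design`) — central composite designs for k
factors: a 2^k factorial at coded ±1, two star points per factor at
natural positions you choose (so per-factor axial distances such as
±2, ±1.8, ±2 are representable), and replicated center points. Coding
is `(natural − center)/step`.

**Response-surface fit** (`rsmextract.rsm`) — the full second-order
polynomial in coded units,

    y = β₀ + Σᵢ βᵢxᵢ + Σ_{i<j} βᵢⱼxᵢxⱼ + Σᵢ βᵢᵢxᵢ²,

by OLS, with partial-SS ANOVA, pure error from replicates, the
lack-of-fit F test, R², adjusted R², CV% and adequate precision, plus
hierarchy-preserving backward elimination and export of prediction
grids for surface plots.

**Desirability optimization** (`rsmextract.desirability`) — Derringer
scoring dᵢ ∈ [0,1] per response and the weighted geometric mean
`D = (∏ dᵢ^{wᵢ})^{1/Σwᵢ}`, maximized by a deterministic grid +
Nelder-Mead search over the design region; validation of the optimum by
the pairwise relative standard deviation (RSD% < 10 passes).

**Assays** (`rsmextract.assay`) — linear calibration curves,
`% inhibition = 100(1 − A_sample/A_control)`, and IC50 by
four-parameter-logistic fit or log-dose interpolation.

**Chemometrics** (`rsmextract.chemometrics`) — Pearson correlation with
significance flags, PCA on the correlation matrix (eigenvalues sum to
the number of variables), and Ward/average/complete hierarchical
clustering on z-scores with Newick export.

**MS annotation** (`rsmextract.msannotate`) — monoisotopic [M−H]⁻ m/z
from elemental formulas (hydrogen-atom convention), ppm errors, and
neutral-loss matching of fragment lists (hexose 162.05, galloyl 152.01,
water 18.01, ...).

**Synthetic data** (`rsmextract.synthdata`) — seeded generators for
quadratic surfaces + Gaussian noise on a CCD, 4PL dose-response curves
and latent-factor activity matrices, used to close the loop on every
estimator in the test suite.

## Worked example

```python
from rsmextract import DesirabilityGoal, fit_quadratic, optimize
from rsmextract.datasets import load_extraction_runs

table = load_extraction_runs()             # 20-run CCD, TPC + TFC measured
fits = [fit_quadratic(table, r) for r in ("TPC", "TFC")]
print(round(float(fits[0].coef["ethanol"]), 4))   # -0.3838

goals = [DesirabilityGoal(r, "maximize",
                          float(table.response(r).min()),
                          float(table.response(r).max()))
         for r in ("TPC", "TFC")]
opt = optimize(fits, goals)
print([round(float(v), 1) for v in opt.natural], round(opt.D, 4))
```

prints

```
-0.3838
[52.0, 82.5, 62.9] 0.9764
```

i.e. the ethanol linear effect on total phenolics is −0.38 mgGAE/g per
coded unit, and the joint optimum — 52% ethanol, 82.5 min, 62.9 °C —
achieves 97.6% of the best desirability attainable, with both responses
predicted near their observed maxima (TPC 24.1 mgGAE/g, TFC
23.4 mgCAE/g). The scripts in `examples/` walk through each capability
end to end (`python examples/01_design_and_fit.py`, ...), and
`rsmextract run` drives the whole pipeline from a YAML config or the
packaged study data.

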