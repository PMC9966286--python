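# Methods

This note records the statistical model, the conventions and defaults,
the synthetic-data generators, and the design choices made where the
problem left the design genuinely open.

## The design and its coding

A central composite design for k factors contains 2^k factorial runs,
2k axial (star) runs and n_center replicated center runs. Factors are
specified in natural units by a center and a step (half the factorial
range); coding is the affine map x = (natural − center)/step, so the
factorial levels are exactly ±1 and the center is 0.

Axial positions are specified **directly in natural units**, not
through a single axial distance α. The packaged study design places its
stars on round natural values — 0/100 % ethanol, 15/150 min, 40/80 °C —
which code to ±2, ±1.8 and ±2: a per-factor α. A single rotatable
α = 1.682 cannot represent that layout, so the per-factor form is the
primitive and any common-α design is a special case. Coded values are
always computed from natural values, never assumed to be ±2.

Canonical run order is standard order (factorial with the first factor
cycling fastest, then axial pairs factor by factor, then centers).
Randomized run tables are accepted on input by matching factor
settings as a multiset, never by row position.

## The quadratic model and ANOVA

The full second-order polynomial (intercept, k linear, k(k−1)/2
interaction, k quadratic terms) is fitted by OLS **in coded units**;
this is what makes printed coded-unit coefficient tables directly
comparable. A natural-unit re-expression is available
(`QuadraticFit.natural_coefficients`) but is not the default. Rank
deficiency is detected up front and reported with the names of the
aliased columns (pivoted QR).

ANOVA reports **partial** (Type-III-style) per-term sums of squares:
the extra SS of each term given all others, computed by refitting
without the term. On a CCD the linear columns are orthogonal to every
other column, so partial and sequential SS coincide for them; this is
asserted in the test suite rather than assumed. Pure error is the
within-group SS over replicated factor settings; lack of fit is the
residual remainder, tested as F = MS_LOF/MS_PE. When no replicates
exist the pure-error and lack-of-fit rows are absent and flagged.

Fit statistics follow response-surface-software conventions:
R² = SS_model/SS_total, adj R² = 1 − (1−R²)(n−1)/(n−p),
CV% = 100·√MSE/ȳ, and adequate precision =
(max ŷ − min ŷ over the design points)/√(p·MSE/n). The last formula is
the Design-Expert form; the quantity has no universal definition, so it
is documented here as the implemented choice (it reproduces the
flavonoid model's published value 15.9930 exactly).

Model reduction is backward elimination at level α: among removable
terms with p > α the largest p is dropped first (ties by canonical term
order), with a refit after every removal. Hierarchy is preserved — a
linear term stays while any interaction or quadratic term containing
its factor stays — and the intercept is never removed.

Significance labels use 0.05; the p-values come from the F
distribution with the full-model residual degrees of freedom. MSE is
the full-model residual mean square unless a reduced model is passed
explicitly.

## Desirability optimization and validation

Individual desirability is the Derringer ramp: for "maximize",
d = 0 below L, ((y−L)/(T−L))^s between, 1 above T; "minimize" is the
mirror, "target" the two-sided ramp, "in_range" the indicator. The
composite is the weighted geometric mean, which is 0 whenever any d is
0 and monotone nondecreasing in each d.

Defaults where the underlying study is silent: per-response bounds L/T
equal to the observed response minimum/maximum over the run table;
weights w = 1; exponents s = 1; search region = the full coded design
box including the axial levels. These defaults reproduce the study's
published optimum (D = 0.9764 at ≈52% ethanol, ≈82 min, ≈63 °C against
the published "D = 0.977 at 52%, 81 min, 63 °C"); the optimum is
interior, so including the axial shell is safe.

The optimizer is deterministic: a 41-points-per-axis grid (41³ ≈ 69k
evaluations for three factors, vectorized), then a Nelder-Mead polish
started from the best grid cell with tolerances 1e−8, clipped to the
region; the polished result is never allowed to fall below the best
grid value. No randomness, hence no seed sensitivity.

Validation treats the (experimental, predicted) pair as a two-point
sample: std = |e − p|/√2, RSD% = 100·std/mean, pass at RSD% < 10. On
the packaged validation pairs this reproduces the published 0.82% and
1.76% exactly.

## Assay conventions

Calibration curves are straight lines inverted analytically. Percent
inhibition may be negative and is never capped. The default IC50 method
is the 4PL fit (initialized from the data: plateaus from the observed
extremes, IC50 from the dose nearest the half-way response, Hill sign
from the trend; bounds keep IC50 within three decades of the measured
dose range), falling back to log10-dose linear interpolation between
the bracketing pair when the fit fails; interpolation alone raises an
explicit "not reached" error when the series never crosses 50%. Doses
are log-transformed base 10 for interpolation, standard dose-response
practice.

## Chemometrics

PCA is an eigendecomposition of the **correlation** matrix, not the
covariance matrix: the activity variables mix units (mg/g totals,
mg/mL IC50s), and the correlation form gives the unit-free reading in
which eigenvalues sum to the number of variables. Eigenvector signs are
fixed deterministically by making the largest-magnitude loading of each
component positive. Scores are the z-scored data projected on the
loadings.

HCA defaults to Euclidean distance on z-scored variables with Ward
linkage (the common default family in commercial chemometrics
software); average and complete linkage are available. Distance ties
are broken by scipy's deterministic scan order over the condensed
distance matrix, so identical inputs always give identical trees. Trees
export as Newick with branch lengths derived from merge heights.

## Mass annotation

Calculated [M−H]⁻ m/z subtracts the hydrogen **atom** mass (1.007825 u)
from the summed monoisotopic atomic masses. The physically complete
convention (proton mass, i.e. retaining the extra electron) differs by
0.00055 u and is available via `convention="proton"`; the atom
convention is the default because it is what common peak-table software
prints, and it reproduces the packaged table's calculated-mass column
on every internally consistent row. Neutral-loss matching uses a
default tolerance of 0.05 Da because fragment m/z values in such tables
are printed to two decimals. The annotator asserts mass arithmetic
only; compound names and confidence levels in the packaged table are
metadata and no structural identity is ever claimed.

The packaged peak table preserves all 67 printed rows verbatim. Eight
rows have formula/calculated-mass pairs that are mutually inconsistent
under exact-mass arithmetic (e.g. a calculated 293.0216 for C₁₈H₃₀O₃,
a digit slip from 293.2117; a glycoside whose printed formula is the
ion rather than the neutral). These carry `cm_consistent = False` and
are excluded from tolerance checks rather than silently corrected.

## Synthetic-data generators

Three generators close the loop on each estimator:

- **CCD surfaces**: y = quadratic(coded x; β) + N(0, σ²) i.i.d. over
  the design. Gaussian noise is used throughout because replicate
  scatter in such assays is routinely summarized as mean ± sd with no
  evidence of heavier tails.
- **Dose-response**: a 4PL mean curve sampled at given doses plus
  Gaussian noise.
- **Activity matrices**: a single latent factor with loading √ρ on all
  variables plus idiosyncratic noise, giving an equicorrelated
  population correlation matrix whose top eigenvalue 1 + (p−1)ρ is the
  closed-form oracle for the PCA tests.

All generators are pure functions of (parameters, seed); seeds are
explicit arguments, never global state. What they do **not** emulate:
extraction kinetics, heteroscedastic or correlated replicate noise,
plate effects, and mass-spectral peak shapes. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
assumptions, not robustness to real-world artifacts beyond them.

Test problem sizes were chosen to make sampling error negligible at
desk scale: 200 seeded replicates for coefficient-recovery bias (σ =
0.5 on the 20-run design gives a standard error ≈ σ/4 per replicate),
100 replicates for IC50 recovery at 5% noise, and 500-2000 rows for
latent-correlation checks.

## Known limitations and data caveats

- The packaged phenolic-response model carries a documented internal
  inconsistency in its source: the printed temperature linear
  coefficient (3.06) disagrees with the run table, whose own predicted
  values at the two temperature star runs imply (22.89 − 9.64)/4 =
  3.3125 — exactly what the refit returns. All other phenolic
  coefficients and the entire flavonoid model refit to the printed
  decimals. Consequences of the inconsistency (the phenolic model F and
  adequate precision) are reported as computed, not forced to match.
- The packaged activity matrix is a synthetic reconstruction around the
  few published cells (see `rsmextract/datasets.py`); analyses of it
  characterize the fixture. The published PCA eigenvalues for that
  matrix are therefore not reproducible from public data and are not
  treated as checks; closed-form PCA properties on synthetic data stand
  in for them.
- Uncertainty is not propagated into the desirability score, and no
  multi-objective (Pareto) search is offered; D is a scalarization.
- Box-Cox searches, studentized-residual and leverage diagnostics are
  out of scope.
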