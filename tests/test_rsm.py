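"""Quadratic response-surface fitting and ANOVA diagnostics."""

import numpy as np
import pytest

from rsmextract import (
    CodedPoint,
    FactorSpec,
    RunTable,
    SurfaceTruth,
    anova,
    build_ccd,
    fit_quadratic,
    predict,
    quadratic_matrix,
    quadratic_terms,
    reduce_model,
    simulate_ccd_responses,
    surface_grid,
)


def small_design(k=3, n_center=4):
    factors = [FactorSpec(f"f{i}", 0.0, 1.0, -2.0, 2.0) for i in range(k)]
    return build_ccd(factors, n_center)


def test_ols_equals_normal_equations_oracle(extraction_table, tpc_fit, tfc_fit):
    """The fitted coefficients solve (X'X) b = X'y exactly."""
    X = quadratic_matrix(extraction_table.coded(), extraction_table.design.factor_names).to_numpy()
    for fit, resp in [(tpc_fit, "TPC"), (tfc_fit, "TFC")]:
        y = extraction_table.response(resp)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coef.to_numpy(), beta_oracle, atol=1e-8)


def test_residuals_orthogonal_to_model_columns(extraction_table, tpc_fit):
    X = quadratic_matrix(extraction_table.coded(), tpc_fit.factor_names, tpc_fit.terms).to_numpy()
    for j in range(X.shape[1]):
        col = X[:, j]
        assert abs(col @ tpc_fit.residuals) < 1e-8 * np.linalg.norm(col)


def test_noise_free_synthetic_recovery():
    """With sigma = 0 the fit recovers the generating surface exactly."""
    ccd = small_design()
    truth = SurfaceTruth(
        coef={"Intercept": 5.0, "f0": 1.5, "f1": -2.0, "f0:f1": 0.7, "f0^2": -1.1, "f2^2": 0.4},
        sigma=0.0,
    )
    table = simulate_ccd_responses(ccd, truth)
    fit = fit_quadratic(table, "Y")
    expected = truth.coef_vector(ccd.factor_names)
    assert np.allclose(fit.coef.to_numpy(), expected.to_numpy(), atol=1e-9)
    assert np.allclose(predict(fit, ccd.coded_matrix()), truth.evaluate(ccd.coded_matrix(), ccd.factor_names))


def test_prediction_at_origin_is_intercept(tpc_fit):
    assert predict(tpc_fit, CodedPoint((0.0, 0.0, 0.0)))[0] == pytest.approx(tpc_fit.intercept)


def test_published_polynomial_evaluates_as_printed():
    """Direct evaluation of a quadratic with the published TPC coefficients."""
    terms = quadratic_terms(["x1", "x2", "x3"])
    coefs = dict(zip(terms, [23.39, -0.3838, 0.0612, 3.06, -0.5475, -1.61, 0.0825, -4.37, -4.10, -1.98]))
    X = quadratic_matrix(np.array([[0.0, 0.0, 0.0], [0.0788, -0.0299, 0.276]]), ["x1", "x2", "x3"])
    vals = X.to_numpy() @ np.array([coefs[t] for t in terms])
    assert vals[0] == pytest.approx(23.39)
    assert vals[1] == pytest.approx(23.99, abs=0.01)


def test_anova_additivity_identities(extraction_table, tpc_anova, tfc_anova):
    for tbl in (tpc_anova, tfc_anova):
        frame = tbl.table
        assert frame.loc["Model", "SS"] + frame.loc["Residual", "SS"] == pytest.approx(
            frame.loc["Total", "SS"], rel=1e-6
        )
        assert frame.loc["Lack of fit", "SS"] + frame.loc["Pure error", "SS"] == pytest.approx(
            frame.loc["Residual", "SS"], rel=1e-6
        )
        assert tbl.adj_r2 <= tbl.r2


def test_pure_error_from_center_replicates(extraction_table, tpc_anova):
    """Pure error equals the within-group SS of the six center runs."""
    y = extraction_table.response("TPC")
    center = np.all(extraction_table.coded() == 0, axis=1)
    ss = float(((y[center] - y[center].mean()) ** 2).sum())
    assert tpc_anova.table.loc["Pure error", "SS"] == pytest.approx(ss, rel=1e-9)
    assert tpc_anova.table.loc["Pure error", "dof"] == 5


def test_partial_equals_sequential_for_orthogonal_linear_terms(extraction_table, tfc_fit, tfc_anova):
    """Linear coded columns are orthogonal to the rest of the model on a
    CCD, so partial SS = b^2 * sum(x^2) for them."""
    coded = extraction_table.coded()
    for i, name in enumerate(extraction_table.design.factor_names):
        b = tfc_fit.coef[name]
        ss_direct = b**2 * float((coded[:, i] ** 2).sum())
        assert tfc_anova.table.loc[name, "SS"] == pytest.approx(ss_direct, rel=1e-8)


def test_no_replicates_flags_missing_pure_error():
    ccd = small_design(n_center=1)
    truth = SurfaceTruth(coef={"Intercept": 1.0, "f0": 0.5}, sigma=0.3, seed=11)
    table = simulate_ccd_responses(ccd, truth)
    tbl = anova(fit_quadratic(table, "Y"), table)
    assert "Pure error" not in tbl.table.index
    assert "Lack of fit" not in tbl.table.index
    assert tbl.pure_error_dof == 0


def test_noise_free_fit_has_unit_r2():
    """Data generated exactly on a quadratic surface are interpolated:
    R^2 = 1 and the residual SS vanishes."""
    ccd = small_design(k=2, n_center=2)
    truth = SurfaceTruth(coef={"Intercept": 2.0, "f0": 1.0, "f1": -1.0, "f0^2": -0.5}, sigma=0.0)
    table = simulate_ccd_responses(ccd, truth)
    tbl = anova(fit_quadratic(table, "Y"), table)
    assert tbl.r2 == pytest.approx(1.0, abs=1e-12)


def test_rank_deficient_design_names_aliased_terms():
    ccd = small_design(k=2, n_center=2)
    truth = SurfaceTruth(coef={"Intercept": 1.0}, sigma=0.1, seed=5)
    table = simulate_ccd_responses(ccd, truth)
    # collapse factor f1 onto f0 -> interaction and quadratic columns alias
    data = table.data.copy()
    data["f1"] = data["f0"]
    broken = RunTable.__new__(RunTable)
    broken.design = ccd
    broken.data = data
    broken.response_names = ("Y",)
    broken.units = {}
    with pytest.raises(ValueError, match="aliased"):
        fit_quadratic(broken, "Y")


def test_run_table_rejects_mismatched_rows(extraction_design, extraction_table):
    data = extraction_table.data.copy()
    data.loc[0, "ethanol"] = 33.0
    with pytest.raises(ValueError, match="do not match the design"):
        RunTable(design=extraction_design, data=data, response_names=("TPC", "TFC"))


def test_reduce_alpha_one_is_identity(extraction_table, tpc_fit):
    reduced = reduce_model(tpc_fit, extraction_table, alpha=1.0)
    assert reduced.terms == tpc_fit.terms


def test_reduce_drops_null_interaction_on_clean_data():
    """Backward elimination removes an interaction generated as zero."""
    ccd = small_design(n_center=6)
    truth = SurfaceTruth(
        coef={"Intercept": 10.0, "f0": 2.0, "f1": 1.0, "f2": 1.5, "f0^2": -1.0, "f1^2": -1.0, "f2^2": -1.0},
        sigma=0.01,
        seed=21,
    )
    table = simulate_ccd_responses(ccd, truth)
    reduced = reduce_model(fit_quadratic(table, "Y"), table, alpha=0.05)
    assert "f0:f1" not in reduced.terms


def test_reduce_preserves_hierarchy(extraction_table, tpc_fit):
    """The time linear term survives elimination (p = 0.66) because the
    significant time^2 and ethanol:time terms contain it."""
    reduced = reduce_model(tpc_fit, extraction_table, alpha=0.05)
    assert "time" in reduced.terms
    assert "time^2" in reduced.terms
    assert "time:temperature" not in reduced.terms  # p = 0.58, removable


def test_linear_coefficient_recovery_bias(extraction_design):
    """Over 200 seeded simulations at sigma = 0.5 on the study design the
    mean absolute bias of each linear coefficient stays below 0.05."""
    truth_coef = {"Intercept": 23.0, "ethanol": 1.0, "time": -0.6, "temperature": 1.7,
                  "ethanol^2": -3.8, "time^2": -4.3, "temperature^2": -2.8}
    errors = np.zeros((200, 3))
    for rep in range(200):
        truth = SurfaceTruth(coef=truth_coef, sigma=0.5, seed=10_000 + rep)
        table = simulate_ccd_responses(extraction_design, truth)
        fit = fit_quadratic(table, "Y")
        for i, name in enumerate(extraction_design.factor_names):
            errors[rep, i] = fit.coef[name] - truth_coef.get(name, 0.0)
    assert np.all(np.abs(errors.mean(axis=0)) < 0.05)


def test_surface_grid_counts_and_interior_maximum(tpc_fit, extraction_design):
    grid = surface_grid(tpc_fit, extraction_design, fixed={"time": 82.5}, resolution=3)
    assert len(grid) == 9
    # sweep temperature at center ethanol/time: response rises to an
    # interior maximum near 65 degC then falls
    sweep = surface_grid(tpc_fit, extraction_design, fixed={"time": 82.5}, resolution=41)
    line = sweep[np.isclose(sweep["ethanol"], 50.0)].sort_values("temperature")["TPC"].to_numpy()
    peak = np.argmax(line)
    assert 0 < peak < len(line) - 1
    assert np.all(np.diff(line[: peak + 1]) > 0) and np.all(np.diff(line[peak:]) < 0)


def test_surface_grid_of_linear_fit_is_planar():
    ccd = small_design()
    truth = SurfaceTruth(coef={"Intercept": 1.0, "f0": 2.0, "f1": -1.0}, sigma=0.0)
    table = simulate_ccd_responses(ccd, truth)
    fit = fit_quadratic(table, "Y")
    grid = surface_grid(fit, ccd, fixed={"f2": 0.0}, resolution=5)
    z = grid["Y"].to_numpy().reshape(5, 5)
    assert np.allclose(np.diff(z, n=2, axis=0), 0.0, atol=1e-9)
    assert np.allclose(np.diff(z, n=2, axis=1), 0.0, atol=1e-9)


def test_surface_grid_requires_two_free_factors(tpc_fit, extraction_design):
    with pytest.raises(ValueError, match="exactly 2"):
        surface_grid(tpc_fit, extraction_design, fixed={"time": 82.5, "ethanol": 50.0, "temperature": 60.0})


def test_natural_coefficients_reproduce_predictions(extraction_table, tfc_fit):
    """The natural-unit polynomial agrees with coded-unit prediction."""
    nat = extraction_table.data[list(tfc_fit.factor_names)].to_numpy()
    natural_coef = tfc_fit.natural_coefficients()
    X_nat = quadratic_matrix(nat, tfc_fit.factor_names)
    preds = X_nat.to_numpy() @ natural_coef.reindex(X_nat.columns).fillna(0.0).to_numpy()
    assert np.allclose(preds, tfc_fit.fitted_values, atol=1e-8)
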