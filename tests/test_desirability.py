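"""Derringer desirability scoring, optimization and RSD validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsmextract import (
    DesirabilityGoal,
    FactorSpec,
    SurfaceTruth,
    build_ccd,
    composite_D,
    fit_quadratic,
    individual_desirability,
    optimize,
    simulate_ccd_responses,
    validate,
)


def test_maximize_ramp_endpoints():
    g = DesirabilityGoal("y", "maximize", lower=2.0, upper=8.0, exponent=3.0)
    assert individual_desirability(g, 2.0) == 0.0
    assert individual_desirability(g, 8.0) == 1.0
    assert individual_desirability(g, 1.0) == 0.0
    assert individual_desirability(g, 9.0) == 1.0


def test_flavonoid_goal_scores_predicted_optimum():
    """With bounds at the observed response range, the predicted value
    23.39 scores (23.39-6.81)/(24.20-6.81) = 0.9534."""
    g = DesirabilityGoal("TFC", "maximize", lower=6.81, upper=24.20)
    assert individual_desirability(g, 23.39) == pytest.approx(0.9534, abs=5e-5)


def test_exponent_bends_the_ramp():
    g = DesirabilityGoal("y", "maximize", lower=0.0, upper=1.0, exponent=2.0)
    assert individual_desirability(g, 0.5) == pytest.approx(0.25)


def test_minimize_and_target_shapes():
    gmin = DesirabilityGoal("y", "minimize", lower=0.0, upper=10.0)
    assert individual_desirability(gmin, 0.0) == 1.0
    assert individual_desirability(gmin, 10.0) == 0.0
    gtar = DesirabilityGoal("y", "target", lower=0.0, upper=10.0, target=4.0)
    assert individual_desirability(gtar, 4.0) == pytest.approx(1.0)
    assert individual_desirability(gtar, 2.0) == pytest.approx(0.5)
    assert individual_desirability(gtar, 7.0) == pytest.approx(0.5)


def test_composite_is_weighted_geometric_mean():
    assert composite_D([1.0, 0.9534], [1.0, 1.0]) == pytest.approx(0.9764, abs=5e-5)
    assert composite_D([1.0, 1.0, 1.0]) == 1.0
    assert composite_D([0.5, 0.0, 0.9]) == 0.0
    with pytest.raises(ValueError, match="mismatch"):
        composite_D([0.5, 0.5], [1.0])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.0, 1.0), min_size=2, max_size=5),
    st.integers(0, 4),
    st.floats(0.001, 0.2),
)
def test_composite_bounded_and_monotone(d, idx, bump):
    """D lies between min(d) and max(d) and never decreases when any
    individual desirability increases."""
    w = [1.0] * len(d)
    D = composite_D(d, w)
    assert 0.0 <= D <= 1.0
    if all(x > 0 for x in d):
        assert min(d) - 1e-12 <= D <= max(d) + 1e-12
    idx = idx % len(d)
    d_up = list(d)
    d_up[idx] = min(1.0, d_up[idx] + bump)
    assert composite_D(d_up, w) >= D - 1e-12


def fitted_single_surface(coef, sigma=0.0, seed=0):
    factors = [FactorSpec(f"f{i}", 0.0, 1.0, -2.0, 2.0) for i in range(2)]
    ccd = build_ccd(factors, 3)
    table = simulate_ccd_responses(ccd, SurfaceTruth(coef=coef, sigma=sigma, seed=seed))
    return fit_quadratic(table, "Y"), ccd


def test_optimizer_finds_interior_stationary_point():
    """For one concave quadratic response the optimizer lands on the
    closed-form stationary point solving grad(y) = 0."""
    coef = {"Intercept": 5.0, "f0": 1.0, "f1": -0.5, "f0:f1": 0.2, "f0^2": -1.0, "f1^2": -0.8}
    fit, ccd = fitted_single_surface(coef)
    # stationary point: [2a, c; c, 2b] x = -[g0, g1]
    H = np.array([[2 * coef["f0^2"], coef["f0:f1"]], [coef["f0:f1"], 2 * coef["f1^2"]]])
    x_star = np.linalg.solve(H, -np.array([coef["f0"], coef["f1"]]))
    goal = DesirabilityGoal("Y", "maximize", lower=0.0, upper=10.0)  # upper above max(yhat)
    opt = optimize([fit], [goal], grid_points=21)
    assert np.allclose(opt.coded, x_star, atol=1e-4)


def test_plateau_when_target_below_surface_minimum():
    coef = {"Intercept": 50.0, "f0^2": -1.0, "f1^2": -1.0}
    fit, ccd = fitted_single_surface(coef)
    goal = DesirabilityGoal("Y", "maximize", lower=0.0, upper=5.0)  # attained everywhere relevant
    opt = optimize([fit], [goal], grid_points=11)
    assert opt.D == pytest.approx(1.0)
    assert opt.individual["Y"] == 1.0


def test_optimum_never_below_best_grid_value():
    coef = {"Intercept": 1.0, "f0": 0.3, "f1": 0.1, "f0^2": -0.7, "f1^2": -0.2}
    fit, ccd = fitted_single_surface(coef, sigma=0.05, seed=9)
    goal = DesirabilityGoal("Y", "maximize", lower=-1.0, upper=2.0)
    coarse = optimize([fit], [goal], grid_points=5)
    fine = optimize([fit], [goal], grid_points=41)
    assert fine.D >= coarse.D - 1e-12


def test_study_optimum_composite_desirability(extraction_table, tpc_fit, tfc_fit):
    """Joint maximization over the design region with observed-range
    bounds reproduces the published optimum: D ~ 0.977 at ~52% ethanol,
    ~81-83 min, ~63 degC."""
    goals = [
        DesirabilityGoal(r, "maximize", float(extraction_table.response(r).min()), float(extraction_table.response(r).max()))
        for r in ("TPC", "TFC")
    ]
    opt = optimize([tpc_fit, tfc_fit], goals)
    assert opt.D == pytest.approx(0.977, abs=0.002)
    assert opt.natural[0] == pytest.approx(52.0, abs=1.0)
    assert opt.natural[2] == pytest.approx(63.0, abs=1.0)
    assert min(opt.individual.values()) <= opt.D <= max(opt.individual.values())


def test_validation_reproduces_published_rsd(tpc_fit, tfc_fit, extraction_table):
    from rsmextract.desirability import OptimumResult

    opt = OptimumResult(
        natural=np.zeros(3), coded=np.zeros(3),
        predicted={"TPC": 23.97, "TFC": 23.39}, individual={}, D=1.0,
    )
    records = {r.response_name: r for r in validate(opt, {"TPC": 24.25, "TFC": 23.98})}
    assert records["TPC"].std == pytest.approx(0.20, abs=0.005)
    assert records["TPC"].rsd_percent == pytest.approx(0.82, abs=0.005)
    assert records["TFC"].rsd_percent == pytest.approx(1.76, abs=0.005)
    assert records["TPC"].passed and records["TFC"].passed


def test_validation_of_exact_agreement_is_zero():
    from rsmextract.desirability import OptimumResult

    opt = OptimumResult(natural=np.zeros(1), coded=np.zeros(1), predicted={"Y": 10.0}, individual={}, D=1.0)
    (rec,) = validate(opt, {"Y": 10.0})
    assert rec.std == 0.0 and rec.rsd_percent == 0.0


def test_goal_validation_errors():
    with pytest.raises(ValueError, match="lower"):
        DesirabilityGoal("y", "maximize", lower=5.0, upper=5.0)
    with pytest.raises(ValueError, match="goal"):
        DesirabilityGoal("y", "mximize", lower=0.0, upper=1.0)
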