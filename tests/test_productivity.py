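"""Productivity algebra, optimization/prediction drivers, sweeps."""

import dataclasses

import pytest

from fermenet import (
    make_toy_producer,
    maximize_productivity,
    predict_concentrations,
    productivity_on_substrate,
    region_convergence,
    relative_error,
    substrate_yield,
    sweep_grid,
    toy_closed_form,
)
from fermenet.productivity import build_from_cbm


@pytest.mark.parametrize(
    "flux_p, d, c_s, expected",
    [(1.0, 0.1, 10.0, 1.0), (0.0, 0.1, 10.0, 0.0), (0.5, 0.25, 10.0, 0.2)],
)
def test_substrate_yield(flux_p, d, c_s, expected):
    assert substrate_yield(flux_p, d, c_s) == pytest.approx(expected)


def test_substrate_yield_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        substrate_yield(1.0, 0.0, 10.0)


@pytest.mark.parametrize("vp, c_s, expected", [(2.0, 10.0, 0.2), (0.0, 10.0, 0.0)])
def test_productivity_on_substrate(vp, c_s, expected):
    assert productivity_on_substrate(vp, c_s) == pytest.approx(expected)
    assert productivity_on_substrate(vp, c_s) * c_s == pytest.approx(vp)


def test_productivity_on_substrate_rejects_nonpositive_feed():
    with pytest.raises(ValueError):
        productivity_on_substrate(1.0, 0.0)


@pytest.mark.parametrize(
    "observed, predicted, expected",
    [(1.79, 1.32, 35.60), (3.34, 3.55, -5.92), (2.5, 2.5, 0.0)],
)
def test_relative_error_convention(observed, predicted, expected):
    assert relative_error(observed, predicted) == pytest.approx(expected, abs=0.01)


def test_relative_error_zero_prediction():
    with pytest.raises(ZeroDivisionError):
        relative_error(1.0, 0.0)


# -----------------------------------------------------------------------------
# optimization driver


@pytest.fixture(scope="module")
def toy_opt():
    from fermenet import ToyProducerParams

    params = ToyProducerParams()
    model, spec = make_toy_producer(params)
    res = maximize_productivity(model, spec, n_regions=400)
    return params, model, spec, res


def test_toy_optimum_matches_closed_form(toy_opt):
    params, _, spec, res = toy_opt
    vp_star, _ = toy_closed_form(params, spec)
    assert res.status == "optimal"
    assert res.vp == pytest.approx(vp_star, rel=0.01)


def test_result_identities(toy_opt):
    """VP = PS*c_s exactly; VP = D*s_c (unit-converted); Y = VP/(D*c_s)."""
    _, _, spec, res = toy_opt
    assert res.vp == pytest.approx(res.ps * spec.c_g, abs=1e-9)
    assert res.y_ps == pytest.approx(res.vp / (spec.D * spec.c_g), abs=1e-9)
    assert res.vp == pytest.approx(res.s_c * spec.D, abs=1e-6)


def test_carbon_cap_on_toy(toy_opt):
    """VP cannot exceed full conversion of the feed (1 glucose -> 1 product)."""
    _, _, spec, res = toy_opt
    cap = spec.D * spec.c_g * spec.mw_product / spec.mw_substrate
    assert res.vp <= cap + 1e-9


def test_washout_gives_explicit_infeasible(toy_opt):
    params, model, spec, _ = toy_opt
    res = maximize_productivity(
        model, dataclasses.replace(spec, D=1.1 * params.mu_max), n_regions=5
    )
    assert res.status == "infeasible" and not res.feasible


# -----------------------------------------------------------------------------
# prediction mode


def test_prediction_at_analytic_optimum_matches_optimizer(toy_opt):
    params, model, spec, res = toy_opt
    vp_star, x_star = toy_closed_form(params, spec)
    pred = predict_concentrations(model, spec, x_measured=x_star)
    assert pred.status == "optimal"
    assert pred.vp == pytest.approx(vp_star, abs=1e-6)
    assert pred.s_g == pytest.approx(0.0, abs=1e-9)
    assert pred.region is None


def test_prediction_profile_maximum_matches_relaxation(toy_opt):
    """Max over a fine X grid of the exact fixed-X LP ~ the piecewise optimum."""
    params, model, spec, res = toy_opt
    im = build_from_cbm(model, spec)
    xs = [spec.effective_x_max * i / 200 for i in range(201)]
    best = max(
        (predict_concentrations(im, x_measured=x).vp or 0.0)
        for x in xs
        if predict_concentrations(im, x_measured=x).status == "optimal"
    )
    assert res.vp == pytest.approx(best, rel=0.02)
    assert res.vp >= best - 1e-9  # relaxation stays an upper bound


def test_prediction_without_feed_is_zero(toy):
    _, model, spec = toy
    spec = dataclasses.replace(spec, c_g=0.0, x_max=1.0)
    pred = predict_concentrations(model, spec, x_measured=0.0)
    assert pred.status == "optimal"
    assert pred.s_c == pytest.approx(0.0, abs=1e-9)
    assert pred.s_g == pytest.approx(0.0, abs=1e-9)


def test_prediction_rejects_biomass_outside_bounds(toy):
    _, model, spec = toy
    with pytest.raises(ValueError):
        predict_concentrations(model, spec, x_measured=spec.effective_x_max + 1.0)


# -----------------------------------------------------------------------------
# sweeps and convergence study


def test_sweep_grid_composes_pointwise_calls(toy):
    _, model, spec = toy
    c_gs, ds = [5.0, 10.0], [0.3, 0.5]
    table = sweep_grid(model, spec, c_gs, ds, n_regions=12)
    assert len(table.frame) == 4
    for _, row in table.frame.iterrows():
        point = dataclasses.replace(spec, c_g=row.glucose_g_per_L, D=row.dilution_per_h)
        res = maximize_productivity(model, point, n_regions=12)
        assert row.VP_g_per_L_per_h == pytest.approx(res.vp, abs=1e-9)
    # VP grows with feed concentration at fixed feasible D (closed form is linear in c_g)
    f = table.frame
    for d in ds:
        col = f[f.dilution_per_h == d].sort_values("glucose_g_per_L").VP_g_per_L_per_h
        assert col.is_monotonic_increasing


def test_sweep_rejects_empty_grid(toy):
    _, model, spec = toy
    with pytest.raises(ValueError):
        sweep_grid(model, spec, [], [0.1])


def test_region_convergence_monotone(toy):
    params, model, spec = toy
    ns = [1, 2, 4, 8, 16, 32]
    frame = region_convergence(model, spec, ns)
    ps = frame.PS_per_h.tolist()
    assert frame.n_regions.tolist() == ns
    assert all(a >= b - 1e-9 for a, b in zip(ps, ps[1:]))
    assert ps[0] == max(ps)  # coarsest relaxation is loosest
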