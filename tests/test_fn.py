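"""Flexible-Net core: event semantics, guards, steady-state LP."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermenet import (
    EventHandler,
    FlexibleNet,
    Guard,
    IntensityHandler,
    LinExpr,
    Place,
    Transition,
    active_region,
    apply_event_handler,
    cbm_to_fn,
    optimize_fn,
    steady_state_constraints,
    unfold_reversible,
)
from fermenet.fn import FNStructureError, GuardCoverageError


@pytest.mark.parametrize(
    "stoich, x, expected",
    [
        ({"A": -1.0, "C": 2.0}, 1.0, {"A": -1.0, "C": 2.0}),
        ({"A": -2.0, "B": -1.0, "D": 1.0}, 1.0, {"A": -2.0, "B": -1.0, "D": 1.0}),
        ({"A": -2.0, "B": -1.0, "D": 1.0}, 0.0, {"A": 0.0, "B": 0.0, "D": 0.0}),
        ({"A": -1.0, "C": 2.0}, 2.5, {"A": -2.5, "C": 5.0}),
    ],
)
def test_event_handler_deltas(stoich, x, expected):
    h = EventHandler("h", "R", stoich)
    assert apply_event_handler(h, x) == expected


def test_event_handler_rejects_negative_occurrence():
    with pytest.raises(ValueError):
        apply_event_handler(EventHandler("h", "R", {"A": -1.0}), -0.1)


@pytest.mark.parametrize(
    "state, region, speed",
    [
        ({"A": 5.0, "B": 3.0}, 1, 0.0),
        ({"A": 20.0, "B": 3.0}, 2, 6.0),
        ({"A": 50.0, "B": 2.0}, 3, 8.0),
        ({"A": 10.0, "B": 1.0}, 2, 2.0),   # lower threshold belongs to the upper region
        ({"A": 30.0, "B": 1.0}, 3, 4.0),
    ],
)
def test_guarded_speed_rule(fig1, state, region, speed):
    got_region, got_speed = active_region(fig1.intensity_handlers["s2"], state)
    assert got_region == region
    assert got_speed == pytest.approx(speed)


def test_unguarded_handler_is_proportional(fig1):
    region, speed = active_region(fig1.intensity_handlers["s1"], {"A": 7.0})
    assert region == 1
    assert speed == pytest.approx(14.0)


def test_state_outside_guards_is_a_coverage_violation(fig1):
    with pytest.raises(GuardCoverageError):
        active_region(fig1.intensity_handlers["s2"], {"A": -1.0, "B": 0.0})


@settings(derandomize=True, max_examples=200)
@given(a=st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
       b=st.floats(min_value=0.0, max_value=1e3, allow_nan=False))
def test_exactly_one_guard_active_over_admissible_range(a, b):
    """Guard exclusivity/coverage: any admissible state hits exactly one region."""
    net = fig1_net_cached()
    h = net.intensity_handlers["s2"]
    state = {"A": a, "B": b}
    hits = []
    for i, g in enumerate(h.guards, start=1):
        if g.lo <= a < g.hi or (i == len(h.guards) and a == g.hi):
            hits.append(i)
    assert len(hits) == 1
    assert active_region(h, state)[0] == hits[0]


_FIG1 = None


def fig1_net_cached():
    global _FIG1
    if _FIG1 is None:
        from fermenet import figure1_net

        _FIG1 = figure1_net()
    return _FIG1


def test_guards_must_tile_without_gaps():
    with pytest.raises(FNStructureError):
        IntensityHandler(
            "bad", "R", "A",
            [Guard.equality(0.0, 5.0, LinExpr({})),
             Guard.equality(6.0, math.inf, LinExpr({}))],
        )


# -----------------------------------------------------------------------------
# steady-state constraint semantics


def test_table1_balance_rows_match_stoichiometric_matrix(table1):
    """The FN steady-state equalities are exactly the rows of S.v = 0."""
    unfolded = unfold_reversible(table1)
    net = cbm_to_fn(unfolded)
    cs = steady_state_constraints(net)
    S, mets, rxns = unfolded.stoichiometric_matrix()
    got = {frozenset({r: c for r, c in row.items()}.items()) for row, rhs in cs._eq}
    expected = set()
    for i, m in enumerate(mets):
        row = {f"v[{rxns[j]}]": S[i, j] for j in range(len(rxns)) if S[i, j] != 0}
        expected.add(frozenset(row.items()))
    assert got == expected
    assert all(rhs == 0 for _, rhs in cs._eq)
    # place A balance written by hand: v1 - v3f + v3b = 0
    assert frozenset({"v[R1]": 1.0, "v[R3_f]": -1.0, "v[R3_b]": 1.0}.items()) in got


def test_source_into_dead_end_place_forces_zero_flux():
    net = FlexibleNet()
    net.add_place(Place("A"))
    net.add_transition(Transition("src", 0.0, 50.0))
    net.add_event_handler(EventHandler("eh", "src", {"A": 1.0}))
    sol = optimize_fn(net, {"src": 1.0}, sense="max")
    assert sol.status == "optimal"
    assert sol["v[src]"] == pytest.approx(0.0, abs=1e-9)


def test_table1_optimum_and_pinned_fluxes(table1):
    net = cbm_to_fn(table1)
    sol = optimize_fn(net, {"R4": 1.0}, sense="max")
    assert sol.status == "optimal"
    assert sol.objective == pytest.approx(10.0, abs=1e-6)
    assert sol["v[R1]"] == pytest.approx(5.0, abs=1e-6)
    assert sol["v[R2]"] == pytest.approx(10.0, abs=1e-6)
    assert sol["v[R3_f]"] - sol["v[R3_b]"] == pytest.approx(5.0, abs=1e-6)


def test_conservation_in_optimum(table1):
    """Each place's net steady-state flow is zero in an optimal solution."""
    unfolded = unfold_reversible(table1)
    net = cbm_to_fn(unfolded)
    sol = optimize_fn(net, {"R4": 1.0})
    S, mets, rxns = unfolded.stoichiometric_matrix()
    v = [sol[f"v[{r}]"] for r in rxns]
    for i in range(len(mets)):
        assert sum(S[i, j] * v[j] for j in range(len(rxns))) == pytest.approx(0, abs=1e-6)


@pytest.mark.parametrize("k", [0.5, 2.0, 7.0])
def test_scaling_lambda0_scales_homogeneous_objective(table1, k):
    scaled = table1.copy()
    for r in scaled.reactions:
        r.lb *= k
        r.ub *= k
    base = optimize_fn(cbm_to_fn(table1), {"R4": 1.0}).objective
    got = optimize_fn(cbm_to_fn(scaled), {"R4": 1.0}).objective
    assert got == pytest.approx(k * base, rel=1e-9)


def test_infeasible_and_unbounded_status():
    net = FlexibleNet()
    net.add_place(Place("A"))
    net.add_transition(Transition("in", 5.0, 5.0))
    net.add_transition(Transition("out", 0.0, 1.0))
    net.add_event_handler(EventHandler("e1", "in", {"A": 1.0}))
    net.add_event_handler(EventHandler("e2", "out", {"A": -1.0}))
    assert optimize_fn(net, {"out": 1.0}).status == "infeasible"

    free = FlexibleNet()
    free.add_place(Place("B"))
    free.add_transition(Transition("loop", 0.0, math.inf))
    free.add_event_handler(EventHandler("e", "loop", {}))
    assert optimize_fn(free, {"loop": 1.0}).status == "unbounded"


def test_optimize_rejects_guarded_nets_and_unknown_objectives(fig1):
    with pytest.raises(FNStructureError):
        optimize_fn(fig1, {"R1": 1.0})  # s2 is guarded
    net = cbm_to_fn(fig1_table())
    with pytest.raises(FNStructureError):
        optimize_fn(net, {"nope": 1.0})


def fig1_table():
    from fermenet import table1_model

    return table1_model()


def test_lp_export_contains_rows_and_bounds(table1):
    cs = steady_state_constraints(cbm_to_fn(table1))
    text = cs.to_lp_string({"v[R4]": 1.0}, sense="max")
    assert text.startswith("Maximize")
    assert "v[R4]" in text and "Bounds" in text and text.rstrip().endswith("End")
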