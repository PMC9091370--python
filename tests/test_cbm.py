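"""Model reading, editing, reversible unfolding and FN conversion."""

import numpy as np
import pytest

from conftest import direct_fba
from fermenet import (
    Reaction,
    add_citramalate_pathway,
    add_reaction,
    cbm_to_fn,
    fba,
    flux_variability,
    load_model,
    random_small_cbm,
    unfold_reversible,
)
from fermenet.cbm import ModelError, parse_formula

TABLE1_TSV = """id\tformula\tlb\tub
R1\t -> A\t5\t5
R2\t -> C\t0\t20
R3\tA <-> 2 B\t-500\t1000
R4\tB + C -> \t0\t1000
"""


def test_load_tsv_fixture(tmp_path):
    p = tmp_path / "table1.tsv"
    p.write_text(TABLE1_TSV)
    m = load_model(str(p))
    assert len(m.reactions) == 4
    assert sorted(m.metabolites) == ["A", "B", "C"]
    r3 = m.reaction("R3")
    assert (r3.lb, r3.ub) == (-500.0, 1000.0)
    assert r3.stoich == {"A": -1.0, "B": 2.0}


def test_empty_file_is_a_parse_error(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    with pytest.raises(ModelError):
        load_model(str(p))


def test_missing_bounds_are_an_error(tmp_path):
    p = tmp_path / "m.json"
    p.write_text('{"reactions": [{"id": "R1", "formula": "-> A", "lb": 0}]}')
    with pytest.raises(ModelError):
        load_model(str(p))


def test_json_roundtrip(tmp_path, table1):
    from fermenet.io import write_model_dialect

    p = tmp_path / "t.json"
    write_model_dialect(table1, str(p))
    m = load_model(str(p))
    assert [r.id for r in m.reactions] == [r.id for r in table1.reactions]
    assert m.objective == "R4"
    assert fba(m, "R4")[0] == pytest.approx(10.0)


@pytest.mark.parametrize(
    "formula, stoich, rev",
    [
        ("2 A + B -> D", {"A": -2.0, "B": -1.0, "D": 1.0}, False),
        ("A <-> 2 B", {"A": -1.0, "B": 2.0}, True),
        ("-> C", {"C": 1.0}, False),
        ("B + C -> ", {"B": -1.0, "C": -1.0}, False),
    ],
)
def test_formula_parser(formula, stoich, rev):
    got, got_rev = parse_formula(formula)
    assert got == stoich and got_rev == rev


# -----------------------------------------------------------------------------
# editing


def test_add_citramalate_synthase_and_exchange(table1):
    m2 = add_reaction(
        table1,
        Reaction("CIMA", {"accoa_c": -1, "pyr_c": -1, "h2o_c": -1,
                          "citramalate_c": 1, "coa_c": 1, "h_c": 1}, 0, 1000),
    )
    assert len(m2.reactions) == len(table1.reactions) + 1
    m3 = add_reaction(m2, Reaction("EX_citramalate", {"citramalate_c": -1}, 0, 1000))
    assert m3.has_reaction("EX_citramalate")
    with pytest.raises(ModelError):
        add_reaction(m3, Reaction("CIMA", {"citramalate_c": -1}, 0, 1))


def test_citramalate_pathway_helper(table1):
    m = add_citramalate_pathway(table1)
    assert m.has_reaction("CIMA") and m.has_reaction("EX_citramalate")
    assert m.reaction("CIMA").stoich["citramalate_c"] == 1.0
    assert m.reaction("EX_citramalate").stoich == {"citramalate_c": -1.0}


# -----------------------------------------------------------------------------
# unfolding


def test_unfold_splits_reversible_only(table1):
    u = unfold_reversible(table1)
    ids = [r.id for r in u.reactions]
    assert ids == ["R1", "R2", "R3_f", "R3_b", "R4"]
    f, b = u.reaction("R3_f"), u.reaction("R3_b")
    assert (f.lb, f.ub) == (0.0, 1000.0)
    assert (b.lb, b.ub) == (0.0, 500.0)
    assert b.stoich == {"A": 1.0, "B": -2.0}
    assert (u.reaction("R4").lb, u.reaction("R4").ub) == (0.0, 1000.0)
    assert all(r.lb >= 0 for r in u.reactions)


def test_unfold_forced_backward_reaction():
    from fermenet.cbm import ConstraintBasedModel

    m = ConstraintBasedModel(
        [Reaction("R", {"A": -1.0}, -5.0, -2.0), Reaction("S", {"A": 1.0}, 0.0, 10.0)],
        ["A"],
    )
    u = unfold_reversible(m)
    f, b = u.reaction("R_f"), u.reaction("R_b")
    assert (f.lb, f.ub) == (0.0, 0.0)
    assert (b.lb, b.ub) == (2.0, 5.0)


def test_unfolding_preserves_lp_optimum_on_random_models(rng):
    """Optimum of max flux is invariant under forward/backward splitting."""
    for _ in range(20):
        m = random_small_cbm(rng)
        before, st_before = direct_fba(m, "SNK")
        after, st_after = direct_fba(unfold_reversible(m), "SNK")
        assert st_before == st_after
        if st_before == "optimal":
            assert after == pytest.approx(before, abs=1e-6)


def test_unfolding_soundness_on_feasible_points(rng):
    """Any feasible v maps to a feasible (v_f, v_b) with v = v_f - v_b and back."""
    for _ in range(10):
        m = random_small_cbm(rng)
        u = unfold_reversible(m)
        opt, fluxes, st = fba(m, "SNK")
        if st != "optimal":
            continue
        S, mets, _ = m.stoichiometric_matrix()
        rxn_ids = [r.id for r in m.reactions]
        v = np.array([fluxes[r] for r in rxn_ids])
        # the net-flux vector satisfies the original model exactly
        assert np.allclose(S @ v, 0.0, atol=1e-6)
        for r in m.reactions:
            assert r.lb - 1e-6 <= fluxes[r.id] <= r.ub + 1e-6


# -----------------------------------------------------------------------------
# FN conversion and FBA equivalence


def test_fn_structure_counts(table1):
    net = cbm_to_fn(table1)  # unfolds internally
    assert len(net.places) == 3
    assert len(net.transitions) == 5
    assert len(net.event_handlers) == 5
    assert len(net.intensity_handlers) == 0
    assert net.transitions["R1"].lambda0_lo == net.transitions["R1"].lambda0_hi == 5.0


def test_empty_model_gives_places_only():
    from fermenet.cbm import ConstraintBasedModel

    net = cbm_to_fn(ConstraintBasedModel([], ["A", "B"]))
    assert len(net.places) == 2 and len(net.transitions) == 0


def test_fba_equivalence_against_independent_lp(rng):
    """FN-pipeline FBA equals the direct LP over {S.v=0, L<=v<=U} on 20 models."""
    agree = 0
    for _ in range(20):
        m = random_small_cbm(rng)
        expected, st = direct_fba(m, "SNK")
        got, _, got_st = fba(m, "SNK")
        assert got_st == st
        if st == "optimal":
            assert got == pytest.approx(expected, abs=1e-6)
            agree += 1
    assert agree >= 10  # the generator must exercise mostly feasible models


def test_fba_equivalence_against_cobra(table1):
    """Independent cross-check through cobrapy on the four-reaction model."""
    import cobra

    cm = cobra.Model("t1")
    mets = {x: cobra.Metabolite(x, compartment="c") for x in "ABC"}
    for r in table1.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
    # close the boundary: the textbook model already has explicit source/sink
    cm.objective = "R4"
    expected = cm.optimize().objective_value
    assert fba(table1, "R4")[0] == pytest.approx(expected, abs=1e-6)


def test_fva_agreement_on_table1(table1):
    """Min/max achievable FN flux equals direct-LP flux variability per reaction."""
    for r in table1.reactions:
        lo, hi = flux_variability(table1, r.id)
        exp_lo, _ = direct_fba(table1, r.id, "min")
        exp_hi, _ = direct_fba(table1, r.id, "max")
        assert lo == pytest.approx(exp_lo, abs=1e-6)
        assert hi == pytest.approx(exp_hi, abs=1e-6)
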