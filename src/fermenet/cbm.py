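"""Constraint-based metabolic models and their conversion to Flexible Nets.

A constraint-based model is the tuple (reactions R, metabolites M,
stoichiometric matrix S, flux bounds L and U); flux balance analysis (FBA)
optimizes a linear objective over {S.v = 0, L <= v <= U}.  The conversion
to an FN uses one place per metabolite, one transition per reaction (its
lambda0 bounds are the flux bounds) and one event handler per reaction
carrying the stoichiometry; reversible reactions are first unfolded into
forward/backward copies so all transition fluxes are non-negative.

SBML (Level 3 + FBC) input is read through cobrapy; a plain JSON/TSV model
dialect is provided so small textbook models can live in the repository as
text (see :mod:`fermenet.io`).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .fn import EventHandler, FlexibleNet, Place, Transition, optimize_fn

__all__ = [
    "Reaction",
    "ReactionSpec",
    "ConstraintBasedModel",
    "ModelError",
    "load_model",
    "parse_formula",
    "add_reaction",
    "add_citramalate_pathway",
    "unfold_reversible",
    "cbm_to_fn",
    "fba",
    "flux_variability",
    "CITRAMALATE_SYNTHASE_STOICH",
]

log = logging.getLogger(__name__)


class ModelError(ValueError):
    """Malformed constraint-based model or model file."""


@dataclass
class Reaction:
    """One reaction: signed stoichiometry and flux bounds (mmol gDW^-1 h^-1)."""

    id: str
    stoich: dict[str, float]
    lb: float
    ub: float

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id!r}: lower bound {self.lb} > upper {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0


#: alias matching the domain vocabulary for user-supplied reactions
ReactionSpec = Reaction


@dataclass
class ConstraintBasedModel:
    """Reactions, metabolites and flux bounds; optionally an objective reaction.

    ``unfold_map`` records, after :func:`unfold_reversible`, which forward/
    backward copies replaced each originally reversible reaction.
    """

    reactions: list[Reaction] = field(default_factory=list)
    metabolites: list[str] = field(default_factory=list)
    objective: str | None = None
    unfold_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen_r = set()
        mets = set(self.metabolites)
        if len(mets) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            for m in r.stoich:
                if m not in mets:
                    raise ModelError(
                        f"reaction {r.id!r} references undeclared metabolite {m!r}"
                    )

    # -- queries --------------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) plus row/column id orderings."""
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                S[met_idx[m], j] = c
        return S, list(self.metabolites), [r.id for r in self.reactions]

    def copy(self) -> "ConstraintBasedModel":
        return ConstraintBasedModel(
            reactions=[replace(r, stoich=dict(r.stoich)) for r in self.reactions],
            metabolites=list(self.metabolites),
            objective=self.objective,
            unfold_map=dict(self.unfold_map),
        )


# -----------------------------------------------------------------------------
# reading models

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def parse_formula(formula: str) -> tuple[dict[str, float], bool]:
    """Parse a reaction string like ``2 A + B -> D`` or ``A <-> 2 B``.

    Returns (signed stoichiometry, reversible).  An empty side (or the
    symbol ``∅``) denotes an exchange with the environment.
    """
    if "<->" in formula:
        lhs, rhs = formula.split("<->")
        rev = True
    elif "->" in formula:
        lhs, rhs = formula.split("->")
        rev = False
    else:
        raise ModelError(f"formula {formula!r} lacks '->' or '<->'")

    stoich: dict[str, float] = {}

    def side(text: str, sign: float) -> None:
        text = text.strip()
        if not text or text in ("∅", "0"):
            return
        for term in text.split("+"):
            m = _TERM_RE.match(term.strip())
            if not m:
                raise ModelError(f"cannot parse term {term!r} in {formula!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    side(lhs, -1.0)
    side(rhs, +1.0)
    return stoich, rev


def _from_records(records: list[dict], objective: str | None) -> ConstraintBasedModel:
    reactions: list[Reaction] = []
    metabolites: list[str] = []
    seen = set()
    for rec in records:
        if "lb" not in rec or "ub" not in rec or rec["lb"] is None or rec["ub"] is None:
            raise ModelError(f"reaction {rec.get('id')!r}: missing flux bounds")
        if "stoich" in rec:
            stoich = {m: float(c) for m, c in rec["stoich"].items()}
        elif "formula" in rec:
            stoich, _ = parse_formula(rec["formula"])
        else:
            raise ModelError(f"reaction {rec.get('id')!r}: no stoichiometry")
        for m in stoich:
            if m not in seen:
                seen.add(m)
                metabolites.append(m)
        reactions.append(Reaction(rec["id"], stoich, float(rec["lb"]), float(rec["ub"])))
    return ConstraintBasedModel(reactions, metabolites, objective=objective)


def _load_sbml(path: str) -> ConstraintBasedModel:
    from cobra.io import read_sbml_model

    cm = read_sbml_model(path)
    reactions = []
    for r in cm.reactions:
        if r.lower_bound is None or r.upper_bound is None:
            raise ModelError(f"reaction {r.id!r}: missing flux bounds in SBML")
        reactions.append(
            Reaction(
                r.id,
                {m.id: float(c) for m, c in r.metabolites.items()},
                float(r.lower_bound),
                float(r.upper_bound),
            )
        )
    objective = None
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coefs = linear_reaction_coefficients(cm)
        if coefs:
            objective = next(iter(coefs)).id
    except Exception:  # objective is optional metadata
        pass
    return ConstraintBasedModel(reactions, [m.id for m in cm.metabolites], objective)


def load_model(path: str, format: str | None = None) -> ConstraintBasedModel:
    """Read a constraint-based model from SBML, JSON-dialect or TSV-dialect.

    Format is inferred from the extension when not given (.xml/.sbml ->
    sbml, .json -> json, .tsv -> tsv).  Missing flux bounds are an error —
    no silent defaults.
    """
    if format is None:
        low = path.lower()
        if low.endswith((".xml", ".sbml")):
            format = "sbml"
        elif low.endswith(".json"):
            format = "json"
        elif low.endswith(".tsv"):
            format = "tsv"
        else:
            raise ModelError(f"cannot infer model format from {path!r}")
    if format == "sbml":
        model = _load_sbml(path)
    elif format in ("json", "tsv"):
        from . import io as fio

        model = fio.read_model_dialect(path, format)
    else:
        raise ModelError(f"unknown model format {format!r}")
    log.info(
        "loaded %s: %d reactions, %d metabolites",
        path, len(model.reactions), len(model.metabolites),
    )
    return model


# -----------------------------------------------------------------------------
# editing


def add_reaction(model: ConstraintBasedModel, spec: Reaction) -> ConstraintBasedModel:
    """Return a copy of ``model`` with ``spec`` appended.

    Metabolites appearing only in ``spec`` are declared alongside; a
    duplicate reaction id is an error.
    """
    if model.has_reaction(spec.id):
        raise ModelError(f"reaction id {spec.id!r} already present")
    out = model.copy()
    for m in spec.stoich:
        if m not in out.metabolites:
            out.metabolites.append(m)
    out.reactions.append(replace(spec, stoich=dict(spec.stoich)))
    out._validate()
    return out


#: citramalate synthase (cimA, EC 2.3.1.182):
#: acetyl-CoA + pyruvate + H2O -> (3R)-citramalate + CoA + H+
CITRAMALATE_SYNTHASE_STOICH = {
    "accoa_c": -1.0,
    "pyr_c": -1.0,
    "h2o_c": -1.0,
    "citramalate_c": 1.0,
    "coa_c": 1.0,
    "h_c": 1.0,
}


def add_citramalate_pathway(
    model: ConstraintBasedModel,
    synthase_id: str = "CIMA",
    exchange_id: str = "EX_citramalate",
    stoich: dict[str, float] | None = None,
    product_id: str = "citramalate_c",
    bound: float = 1000.0,
) -> ConstraintBasedModel:
    """Add citramalate synthase plus a citramalate exchange to a model.

    Metabolite ids default to the BiGG convention used by iJO1366
    (``accoa_c``, ``pyr_c``, ...); pass ``stoich``/``product_id`` to
    override.  Both reactions are irreversible with bounds [0, bound].
    """
    stoich = dict(stoich or CITRAMALATE_SYNTHASE_STOICH)
    out = add_reaction(model, Reaction(synthase_id, stoich, 0.0, bound))
    out = add_reaction(out, Reaction(exchange_id, {product_id: -1.0}, 0.0, bound))
    return out


# -----------------------------------------------------------------------------
# unfolding and FN conversion


def unfold_reversible(model: ConstraintBasedModel) -> ConstraintBasedModel:
    """Split every reversible reaction into non-negative forward/backward copies.

    ``R`` with bounds [L, U], L < 0 becomes ``R_f`` (same stoichiometry,
    bounds [max(0, L), max(0, U)]) and ``R_b`` (negated stoichiometry,
    bounds [max(0, -U), -min(0, L)]).  The net flux ``v_f - v_b`` spans the
    original [L, U].  Irreversible reactions pass through unchanged.
    """
    out_reactions: list[Reaction] = []
    unfold_map: dict[str, tuple[str, str]] = {}
    for r in model.reactions:
        if r.lb >= 0:
            out_reactions.append(replace(r, stoich=dict(r.stoich)))
            continue
        fwd = Reaction(f"{r.id}_f", dict(r.stoich), max(0.0, r.lb), max(0.0, r.ub))
        bwd = Reaction(
            f"{r.id}_b",
            {m: -c for m, c in r.stoich.items()},
            max(0.0, -r.ub),
            -min(0.0, r.lb),
        )
        out_reactions.extend([fwd, bwd])
        unfold_map[r.id] = (fwd.id, bwd.id)
    objective = model.objective
    if objective in unfold_map:
        objective = unfold_map[objective][0]
    return ConstraintBasedModel(
        out_reactions, list(model.metabolites), objective, unfold_map
    )


def cbm_to_fn(model: ConstraintBasedModel) -> FlexibleNet:
    """Convert a constraint-based model to its Flexible Net.

    One place per metabolite, one transition per (unfolded) reaction whose
    lambda0 bounds are the flux bounds, and one event handler per reaction
    carrying the stoichiometry.  No intensity handlers: constraint-based
    models do not track concentrations.  Models with reversible reactions
    are unfolded internally first.
    """
    if any(r.reversible for r in model.reactions):
        model = unfold_reversible(model)
    net = FlexibleNet()
    for m in model.metabolites:
        net.add_place(Place(m, role="metabolite", units="mM"))
    for r in model.reactions:
        net.add_transition(Transition(r.id, r.lb, r.ub))
        net.add_event_handler(EventHandler(f"eh_{r.id}", r.id, dict(r.stoich)))
    return net


def _net_flux_objective(model: ConstraintBasedModel, rid: str) -> dict[str, float]:
    """Objective selecting reaction ``rid`` by net flux in the unfolded net."""
    if rid in model.unfold_map:
        f, b = model.unfold_map[rid]
        return {f: 1.0, b: -1.0}
    return {rid: 1.0}


def fba(
    model: ConstraintBasedModel,
    objective: str | None = None,
    sense: str = "max",
) -> tuple[float | None, dict[str, float], str]:
    """Flux balance analysis through the FN pipeline.

    Unfolds, converts to an FN, optimizes the steady-state LP.  Returns
    ``(optimum, net-flux vector keyed by original reaction id, status)``.
    """
    rid = objective or model.objective
    if rid is None:
        raise ModelError("no objective reaction given")
    unfolded = unfold_reversible(model)
    net = cbm_to_fn(unfolded)
    sol = optimize_fn(net, _net_flux_objective(unfolded, rid), sense=sense)
    if sol.status != "optimal":
        return None, {}, sol.status
    fluxes: dict[str, float] = {}
    for r in model.reactions:
        if r.id in unfolded.unfold_map:
            f, b = unfolded.unfold_map[r.id]
            fluxes[r.id] = sol[f"v[{f}]"] - sol[f"v[{b}]"]
        else:
            fluxes[r.id] = sol[f"v[{r.id}]"]
    return sol.objective, fluxes, sol.status


def flux_variability(
    model: ConstraintBasedModel, rid: str
) -> tuple[float | None, float | None]:
    """Min and max achievable net flux of one reaction (FVA, no objective fixing)."""
    lo, _, st1 = fba(model, objective=rid, sense="min")
    hi, _, st2 = fba(model, objective=rid, sense="max")
    return (lo if st1 == "optimal" else None, hi if st2 == "optimal" else None)
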