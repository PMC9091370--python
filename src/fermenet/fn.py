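"""Flexible Nets: data model and steady-state constraint semantics.

A Flexible Net (FN) couples two tripartite graphs over the same places
(state variables, e.g. metabolite or tank concentrations) and transitions
(processes, e.g. reactions):

* the *event net*, whose event handlers carry the stoichiometric effect of
  each transition occurrence on the places, and
* the *intensity net*, whose intensity handlers set transition speeds from
  place concentrations through linear (in)equalities, possibly *guarded*
  (different relation sets active in different concentration regions).

At steady state every place's net flow is zero and every transition's flux
equals its default intensity ``lambda0`` plus the intensities contributed by
its intensity handlers.  Collecting those relations yields a linear program;
``optimize_fn`` solves it with HiGHS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "Place",
    "Transition",
    "EventHandler",
    "LinExpr",
    "Guard",
    "IntensityHandler",
    "FlexibleNet",
    "ConstraintSystem",
    "Solution",
    "FNStructureError",
    "GuardCoverageError",
    "apply_event_handler",
    "active_region",
    "steady_state_constraints",
    "optimize_fn",
]

INF = math.inf

#: feasibility tolerance used when checking solutions against constraints
FEAS_TOL = 1e-9
#: optimality tolerance for comparing LP objectives
OPT_TOL = 1e-6


class FNStructureError(ValueError):
    """A net (or a constraint built from it) is structurally malformed."""


class GuardCoverageError(ValueError):
    """A state falls outside every guard of an intensity handler."""


@dataclass
class Place:
    """A state variable: a metabolite or a macroscopic tank species.

    ``conc_lo``/``conc_hi`` bound the concentration variable when the place
    is observed by an intensity handler (e.g. biomass density bounds).
    """

    id: str
    role: str = "metabolite"  # or "macroscopic"
    units: str = "mM"
    conc_lo: float = 0.0
    conc_hi: float = INF


@dataclass
class Transition:
    """A process (reaction).  ``lambda0`` bounds its default intensity.

    Transition fluxes are non-negative in FNs; reversible reactions must be
    unfolded before conversion.  A transition with no ``lambda0`` defaults
    to the fixed value 0.
    """

    id: str
    lambda0_lo: float = 0.0
    lambda0_hi: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda0_lo <= self.lambda0_hi:
            raise FNStructureError(
                f"transition {self.id!r}: need 0 <= lambda0_lo <= lambda0_hi, "
                f"got [{self.lambda0_lo}, {self.lambda0_hi}]"
            )


@dataclass
class EventHandler:
    """Stoichiometric effect of one transition occurrence.

    ``stoich`` maps place id -> signed coefficient per unit occurrence
    (negative = consumed, positive = produced).  E.g. the handler of
    ``R1: A -> 2 C`` has ``stoich={"A": -1, "C": 2}``.
    """

    id: str
    transition: str
    stoich: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p, c in self.stoich.items():
            if not math.isfinite(c):
                raise FNStructureError(
                    f"event handler {self.id!r}: non-finite coefficient for {p!r}"
                )


@dataclass
class LinExpr:
    """Linear expression ``sum(coeffs[v] * v) + const`` over place concentrations."""

    coeffs: dict[str, float] = field(default_factory=dict)
    const: float = 0.0

    def evaluate(self, state: dict[str, float]) -> float:
        return self.const + sum(c * state[v] for v, c in self.coeffs.items())


@dataclass
class Guard:
    """One region of a (possibly guarded) intensity handler.

    Active when the observed place's concentration lies in ``[lo, hi)``
    (the net's last guard is closed at its upper end).  While active the
    produced intensity ``w`` satisfies ``lower <= w <= upper``; equal
    expressions encode an equality such as ``w = 2[B]``.
    """

    lo: float
    hi: float
    lower: LinExpr
    upper: LinExpr

    @classmethod
    def equality(cls, lo: float, hi: float, expr: LinExpr) -> "Guard":
        return cls(lo, hi, expr, expr)

    @property
    def is_equality(self) -> bool:
        return self.lower is self.upper or (
            self.lower.coeffs == self.upper.coeffs
            and self.lower.const == self.upper.const
        )


@dataclass
class IntensityHandler:
    """Sets the speed contribution to ``transition`` from concentrations.

    ``observed`` names the place whose concentration selects the guard.
    A handler with exactly one guard is unguarded; its guard must cover the
    whole admissible range of the observed variable.
    """

    id: str
    transition: str
    observed: str
    guards: list[Guard] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.guards:
            raise FNStructureError(f"intensity handler {self.id!r} has no guards")
        gs = sorted(self.guards, key=lambda g: g.lo)
        for a, b in zip(gs, gs[1:]):
            if not math.isclose(a.hi, b.lo, rel_tol=0, abs_tol=0) and a.hi != b.lo:
                raise FNStructureError(
                    f"intensity handler {self.id!r}: guards must tile the "
                    f"observed range (gap/overlap between {a.hi} and {b.lo})"
                )
        self.guards = gs

    @property
    def is_guarded(self) -> bool:
        return len(self.guards) > 1


@dataclass
class FlexibleNet:
    """An FN: places, transitions, event handlers and intensity handlers.

    ``bilinear`` is a registry of bilinear couplings ``flux(target) =
    flux(source) * [place]`` that cannot be expressed by linear handler
    relations; they are kept symbolic here and linearized region-wise by
    the piecewise module (or made exact by fixing the place concentration).
    Each entry is ``(handler_id, target_transition, source_transition,
    place)``.
    """

    places: dict[str, Place] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)
    event_handlers: dict[str, EventHandler] = field(default_factory=dict)
    intensity_handlers: dict[str, IntensityHandler] = field(default_factory=dict)
    bilinear: list[tuple[str, str, str, str]] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------
    def add_place(self, place: Place) -> Place:
        if place.id in self.places:
            raise FNStructureError(f"duplicate place id {place.id!r}")
        self.places[place.id] = place
        return place

    def add_transition(self, t: Transition) -> Transition:
        if t.id in self.transitions:
            raise FNStructureError(f"duplicate transition id {t.id!r}")
        self.transitions[t.id] = t
        return t

    def add_event_handler(self, h: EventHandler) -> EventHandler:
        if h.id in self.event_handlers:
            raise FNStructureError(f"duplicate event handler id {h.id!r}")
        if h.transition not in self.transitions:
            raise FNStructureError(
                f"event handler {h.id!r} references unknown transition {h.transition!r}"
            )
        for p in h.stoich:
            if p not in self.places:
                raise FNStructureError(
                    f"event handler {h.id!r} references unknown place {p!r}"
                )
        self.event_handlers[h.id] = h
        return h

    def add_intensity_handler(self, h: IntensityHandler) -> IntensityHandler:
        if h.id in self.intensity_handlers:
            raise FNStructureError(f"duplicate intensity handler id {h.id!r}")
        if h.transition not in self.transitions:
            raise FNStructureError(
                f"intensity handler {h.id!r} references unknown transition "
                f"{h.transition!r}"
            )
        if h.observed not in self.places:
            raise FNStructureError(
                f"intensity handler {h.id!r} observes unknown place {h.observed!r}"
            )
        for g in h.guards:
            for v in set(g.lower.coeffs) | set(g.upper.coeffs):
                if v not in self.places:
                    raise FNStructureError(
                        f"intensity handler {h.id!r} relation references "
                        f"unknown place {v!r}"
                    )
        self.intensity_handlers[h.id] = h
        return h

    def add_bilinear(self, handler_id: str, target: str, source: str, place: str) -> None:
        for name, kind in ((target, "transition"), (source, "transition")):
            if name not in self.transitions:
                raise FNStructureError(f"bilinear term references unknown {kind} {name!r}")
        if place not in self.places:
            raise FNStructureError(f"bilinear term references unknown place {place!r}")
        self.bilinear.append((handler_id, target, source, place))

    # -- queries --------------------------------------------------------------
    def handlers_of_transition(self, tid: str) -> list[IntensityHandler]:
        return [h for h in self.intensity_handlers.values() if h.transition == tid]

    def observed_places(self) -> set[str]:
        """Places whose concentration enters some intensity relation or guard."""
        obs: set[str] = set()
        for h in self.intensity_handlers.values():
            obs.add(h.observed)
            for g in h.guards:
                obs.update(g.lower.coeffs)
                obs.update(g.upper.coeffs)
        for _, _, _, place in self.bilinear:
            obs.add(place)
        return obs


# -----------------------------------------------------------------------------
# operational semantics


def apply_event_handler(handler: EventHandler, x: float) -> dict[str, float]:
    """Signed place deltas produced by ``x`` occurrences of the handler's reaction."""
    if x < 0:
        raise ValueError(f"occurrence amount must be non-negative, got {x}")
    return {p: c * x for p, c in handler.stoich.items()}


def active_region(
    handler: IntensityHandler, state: dict[str, float]
) -> tuple[int, float | tuple[float, float]]:
    """Return ``(region index, intensity)`` of the unique active guard.

    Guard intervals are half-open ``[lo, hi)`` except the last, closed at its
    upper end.  The intensity is a float for equality relations, else the
    ``(lower, upper)`` interval.  Region indices are 1-based.
    """
    if handler.observed not in state:
        raise KeyError(f"state lacks observed place {handler.observed!r}")
    x = state[handler.observed]
    n = len(handler.guards)
    for i, g in enumerate(handler.guards, start=1):
        hit = g.lo <= x < g.hi or (i == n and x == g.hi)
        if hit:
            lo = g.lower.evaluate(state)
            hi = g.upper.evaluate(state)
            return i, (lo if g.is_equality else (lo, hi))
    raise GuardCoverageError(
        f"handler {handler.id!r}: state {handler.observed}={x} outside all guards"
    )


# -----------------------------------------------------------------------------
# constraint system


@dataclass
class Solution:
    """Outcome of an LP/MILP solve over a ConstraintSystem."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective: float | None = None
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, var: str) -> float:
        return self.values[var]


class ConstraintSystem:
    """A plain LP container: named variables, bounds, equalities, inequalities.

    Rows are stored as sparse coefficient dicts; ``solve`` assembles scipy
    sparse matrices and calls HiGHS.
    """

    def __init__(self) -> None:
        self._index: dict[str, int] = {}
        self._bounds: list[tuple[float, float]] = []
        self._eq: list[tuple[dict[str, float], float]] = []
        self._ub: list[tuple[dict[str, float], float]] = []

    # -- building -------------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return list(self._index)

    def add_var(self, name: str, lo: float = 0.0, hi: float = INF) -> str:
        if name in self._index:
            raise FNStructureError(f"duplicate variable {name!r}")
        if lo > hi:
            raise FNStructureError(f"variable {name!r}: lower bound {lo} > upper {hi}")
        self._index[name] = len(self._bounds)
        self._bounds.append((lo, hi))
        return name

    def has_var(self, name: str) -> bool:
        return name in self._index

    def bounds_of(self, name: str) -> tuple[float, float]:
        return self._bounds[self._index[name]]

    def set_bounds(self, name: str, lo: float, hi: float) -> None:
        if lo > hi:
            raise FNStructureError(f"variable {name!r}: lower bound {lo} > upper {hi}")
        self._bounds[self._index[name]] = (lo, hi)

    def tighten_bounds(self, name: str, lo: float, hi: float) -> None:
        cur_lo, cur_hi = self.bounds_of(name)
        self.set_bounds(name, max(cur_lo, lo), min(cur_hi, hi))

    def _check_row(self, coeffs: dict[str, float]) -> None:
        for v in coeffs:
            if v not in self._index:
                raise FNStructureError(f"constraint references undeclared variable {v!r}")

    def add_eq(self, coeffs: dict[str, float], rhs: float) -> None:
        self._check_row(coeffs)
        self._eq.append((dict(coeffs), rhs))

    def add_ub(self, coeffs: dict[str, float], rhs: float) -> None:
        """Add ``coeffs . x <= rhs``."""
        self._check_row(coeffs)
        self._ub.append((dict(coeffs), rhs))

    def add_lb(self, coeffs: dict[str, float], rhs: float) -> None:
        """Add ``coeffs . x >= rhs``."""
        self.add_ub({v: -c for v, c in coeffs.items()}, -rhs)

    def copy(self) -> "ConstraintSystem":
        cs = ConstraintSystem()
        cs._index = dict(self._index)
        cs._bounds = list(self._bounds)
        cs._eq = [(dict(c), r) for c, r in self._eq]
        cs._ub = [(dict(c), r) for c, r in self._ub]
        return cs

    # -- solving --------------------------------------------------------------
    def _matrix(self, rows: list[tuple[dict[str, float], float]]):
        data, ri, ci, rhs = [], [], [], []
        for i, (coeffs, b) in enumerate(rows):
            rhs.append(b)
            for v, c in coeffs.items():
                ri.append(i)
                ci.append(self._index[v])
                data.append(c)
        n = len(self._bounds)
        A = sp.csr_matrix((data, (ri, ci)), shape=(len(rows), n))
        return A, np.asarray(rhs, dtype=float)

    def solve(self, objective: dict[str, float], sense: str = "max") -> Solution:
        """Optimize ``objective`` (a var->coefficient map) over the system."""
        if sense not in ("max", "min"):
            raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
        self._check_row(objective)
        n = len(self._bounds)
        c = np.zeros(n)
        for v, w in objective.items():
            c[self._index[v]] = w
        sign = -1.0 if sense == "max" else 1.0
        A_eq = b_eq = A_ub = b_ub = None
        if self._eq:
            A_eq, b_eq = self._matrix(self._eq)
        if self._ub:
            A_ub, b_ub = self._matrix(self._ub)
        res = linprog(
            sign * c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=self._bounds,
            method="highs",
        )
        if res.status == 2:
            return Solution(status="infeasible")
        if res.status == 3:
            return Solution(status="unbounded")
        if res.status != 0:
            raise RuntimeError(f"LP solver failure: {res.message}")
        values = {v: float(res.x[i]) for v, i in self._index.items()}
        return Solution(status="optimal", objective=float(sign * res.fun), values=values)

    # -- export ---------------------------------------------------------------
    def to_lp_string(self, objective: dict[str, float] | None = None,
                     sense: str = "max") -> str:
        """CPLEX-LP-format text dump of the system, for external solvers."""

        def term(c: float, v: str) -> str:
            return f"{'+' if c >= 0 else '-'} {abs(c):g} {v}"

        lines = ["Maximize" if sense == "max" else "Minimize"]
        obj = objective or {}
        lines.append(" obj: " + (" ".join(term(c, v) for v, c in obj.items()) or "0"))
        lines.append("Subject To")
        for i, (coeffs, rhs) in enumerate(self._eq):
            body = " ".join(term(c, v) for v, c in coeffs.items())
            lines.append(f" e{i}: {body} = {rhs:g}")
        for i, (coeffs, rhs) in enumerate(self._ub):
            body = " ".join(term(c, v) for v, c in coeffs.items())
            lines.append(f" u{i}: {body} <= {rhs:g}")
        lines.append("Bounds")
        for v, idx in self._index.items():
            lo, hi = self._bounds[idx]
            hi_s = "+inf" if hi == INF else f"{hi:g}"
            lo_s = "-inf" if lo == -INF else f"{lo:g}"
            lines.append(f" {lo_s} <= {v} <= {hi_s}")
        lines.append("End")
        return "\n".join(lines) + "\n"


# variable-naming conventions shared across modules
def flux_var(tid: str) -> str:
    return f"v[{tid}]"


def conc_var(pid: str) -> str:
    return f"m[{pid}]"


def intensity_var(hid: str) -> str:
    return f"w[{hid}]"


def steady_state_constraints(net: FlexibleNet) -> ConstraintSystem:
    """Linear steady-state constraints of an FN.

    Variables: ``v[t]`` per transition flux, ``m[p]`` per observed place
    concentration, ``w[h]`` per intensity handler contribution.  For every
    place with event arcs the summed production equals the summed
    consumption; every transition flux equals its lambda0 (bounded in
    ``[lambda0_lo, lambda0_hi]``) plus its handlers' intensities.

    Guarded handlers have no monolithic linear encoding; nets containing
    them must be solved region-wise (see the piecewise module).  Bilinear
    registry entries contribute their ``w`` variable but no relation row —
    the caller linearizes them.
    """
    cs = ConstraintSystem()
    bilinear_handlers = {hid for hid, _, _, _ in net.bilinear}

    for h in net.intensity_handlers.values():
        if h.is_guarded:
            raise FNStructureError(
                f"intensity handler {h.id!r} is guarded; build one constraint "
                "system per region (piecewise module) instead"
            )

    for pid in net.observed_places():
        p = net.places[pid]
        cs.add_var(conc_var(pid), p.conc_lo, p.conc_hi)

    handler_ids = set(net.intensity_handlers) | bilinear_handlers
    by_transition: dict[str, list[str]] = {}
    for h in net.intensity_handlers.values():
        by_transition.setdefault(h.transition, []).append(h.id)
    for hid, target, _, _ in net.bilinear:
        by_transition.setdefault(target, []).append(hid)

    for t in net.transitions.values():
        hids = by_transition.get(t.id, [])
        if not hids:
            # flux is exactly the lambda0 variable
            cs.add_var(flux_var(t.id), t.lambda0_lo, t.lambda0_hi)
        else:
            cs.add_var(flux_var(t.id), 0.0, INF)
            cs.add_var(f"l0[{t.id}]", t.lambda0_lo, t.lambda0_hi)
            row = {flux_var(t.id): 1.0, f"l0[{t.id}]": -1.0}
            for hid in hids:
                cs.add_var(intensity_var(hid), -INF, INF)
                row[intensity_var(hid)] = -1.0
            cs.add_eq(row, 0.0)

    # unguarded handler relations: lower <= w <= upper over concentrations
    for h in net.intensity_handlers.values():
        g = h.guards[0]
        w = intensity_var(h.id)
        lo_row = {w: 1.0}
        for v, c in g.lower.coeffs.items():
            lo_row[conc_var(v)] = lo_row.get(conc_var(v), 0.0) - c
        cs.add_lb(lo_row, g.lower.const)
        hi_row = {w: 1.0}
        for v, c in g.upper.coeffs.items():
            hi_row[conc_var(v)] = hi_row.get(conc_var(v), 0.0) - c
        cs.add_ub(hi_row, g.upper.const)

    # place balances: net steady-state flow zero
    balance: dict[str, dict[str, float]] = {}
    for eh in net.event_handlers.values():
        for pid, coef in eh.stoich.items():
            balance.setdefault(pid, {})
            v = flux_var(eh.transition)
            balance[pid][v] = balance[pid].get(v, 0.0) + coef
    for pid, row in balance.items():
        cs.add_eq(row, 0.0)

    return cs


def optimize_fn(
    net: FlexibleNet,
    objective: dict[str, float],
    sense: str = "max",
) -> Solution:
    """Optimize a linear objective over transition fluxes at steady state.

    ``objective`` maps transition ids to coefficients.  For a net obtained
    from a constraint-based model this is exactly flux balance analysis.
    """
    for tid in objective:
        if tid not in net.transitions:
            raise FNStructureError(f"objective references unknown transition {tid!r}")
    if net.bilinear:
        raise FNStructureError(
            "net has unresolved bilinear couplings; use the piecewise solver"
        )
    cs = steady_state_constraints(net)
    return cs.solve({flux_var(t): c for t, c in objective.items()}, sense=sense)
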