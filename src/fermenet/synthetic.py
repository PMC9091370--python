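"""Fixture and oracle factory: textbook nets, a toy producer, random models.

Everything here is generated programmatically so the repository stays
text-only:

* the four-reaction textbook constraint-based model and the small worked
  FN with one proportional and one guarded intensity handler;
* a parametric *toy producer* cell model whose chemostat optimum has a
  closed form, used to validate the piecewise relaxation end to end;
* a brute-force grid oracle for the bilinear chemostat problem (fix X,
  solve an exact LP, take the best over a fine grid — a lower bound on
  the true optimum, while the relaxation is an upper bound: the two
  sandwich the truth);
* seeded random small constraint-based models for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chemostat as ch
from .cbm import ConstraintBasedModel, Reaction
from .chemostat import ChemostatSpec, IntegratedModel, chemostat_steady_state
from .fn import (
    EventHandler,
    FlexibleNet,
    Guard,
    IntensityHandler,
    LinExpr,
    Place,
    Solution,
    Transition,
    conc_var,
    flux_var,
)

__all__ = [
    "ToyProducerParams",
    "table1_model",
    "figure1_net",
    "make_toy_producer",
    "toy_closed_form",
    "oracle_solve",
    "random_small_cbm",
]


def table1_model() -> ConstraintBasedModel:
    """The four-reaction textbook model (bounds in mmol gDW^-1 h^-1).

    R1: 0 -> A [5, 5];  R2: 0 -> C [0, 20];  R3: A <-> 2 B [-500, 1000];
    R4: B + C -> 0 [0, 1000].  Maximizing R4 at steady state gives 10,
    with R1 pinned at 5 by its equal bounds.
    """
    return ConstraintBasedModel(
        reactions=[
            Reaction("R1", {"A": 1.0}, 5.0, 5.0),
            Reaction("R2", {"C": 1.0}, 0.0, 20.0),
            Reaction("R3", {"A": -1.0, "B": 2.0}, -500.0, 1000.0),
            Reaction("R4", {"B": -1.0, "C": -1.0}, 0.0, 1000.0),
        ],
        metabolites=["A", "B", "C"],
        objective="R4",
    )


def figure1_net() -> FlexibleNet:
    """The small worked FN: two reactions, one plain and one guarded handler.

    Event net: R1: A -> 2 C (handler v1: a = x, c = 2x) and
    R2: 2 A + B -> D (handler v2: a = 2x, b = x, d = x).
    Intensity net: s1 sets speed(R1) = 2 [A]; s2 is guarded with three
    regions on [A]: speed(R2) = 0 below 10, 2 [B] between 10 and 30,
    4 [B] above 30.
    """
    net = FlexibleNet()
    for pid in "ABCD":
        net.add_place(Place(pid))
    net.add_transition(Transition("R1", 0.0, 0.0))
    net.add_transition(Transition("R2", 0.0, 0.0))
    net.add_event_handler(EventHandler("v1", "R1", {"A": -1.0, "C": 2.0}))
    net.add_event_handler(EventHandler("v2", "R2", {"A": -2.0, "B": -1.0, "D": 1.0}))
    inf = float("inf")
    net.add_intensity_handler(
        IntensityHandler("s1", "R1", "A", [Guard.equality(0.0, inf, LinExpr({"A": 2.0}))])
    )
    net.add_intensity_handler(
        IntensityHandler(
            "s2",
            "R2",
            "A",
            [
                Guard.equality(0.0, 10.0, LinExpr({})),
                Guard.equality(10.0, 30.0, LinExpr({"B": 2.0})),
                Guard.equality(30.0, inf, LinExpr({"B": 4.0})),
            ],
        )
    )
    return net


@dataclass(frozen=True)
class ToyProducerParams:
    """Parameters of the minimal producer cell.

    ``k``: biomass yield coefficient linking growth rate to the glucose
    flux routed to biomass, h^-1 per mmol gDW^-1 h^-1 (mu = k * v_b).
    ``u_max``: maximum specific glucose uptake, mmol gDW^-1 h^-1.
    Internal glucose is partitioned between growth precursor and product
    1:1, so u_g = v_b + v_p.
    """

    k: float = 0.1
    u_max: float = 10.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.u_max <= 0:
            raise ValueError("k and u_max must be positive")

    @property
    def mu_max(self) -> float:
        """Maximal growth rate: all uptake routed to biomass."""
        return self.k * self.u_max


def make_toy_producer(
    params: ToyProducerParams = ToyProducerParams(),
    c_g: float = 10.0,
    D: float = 0.5,
    x_max: float | None = None,
) -> tuple[ConstraintBasedModel, ChemostatSpec]:
    """Three-reaction producer cell plus a chemostat spec.

    Reactions (all irreversible, finite bounds so the MILP cross-check
    mode stays well posed):

    * ``GLC_upt``: 0 -> Gi, bounds [0, u_max]  (specific glucose uptake)
    * ``GROWTH``: (1/k) Gi -> 0, bounds [0, 10*mu_max]  (flux = mu, h^-1)
    * ``EX_cit``: Gi -> 0, bounds [0, 10*u_max]  (product secretion)

    The internal balance gives u_g = mu/k + v_p.  At steady state with
    mu = D and all substrate consumed, the chemostat optimum is

        VP* = D * c_g_mM * (1 - D / (k * u_max))   (mM h^-1, then scaled
        by the product molar mass)  at  X* = D * c_g_mM / u_max,

    valid for 0 < D < k*u_max; see :func:`toy_closed_form`.
    """
    model = ConstraintBasedModel(
        reactions=[
            Reaction("GLC_upt", {"Gi": 1.0}, 0.0, params.u_max),
            Reaction("GROWTH", {"Gi": -1.0 / params.k}, 0.0, 10.0 * params.mu_max),
            Reaction("EX_cit", {"Gi": -1.0}, 0.0, 10.0 * params.u_max),
        ],
        metabolites=["Gi"],
        objective="EX_cit",
    )
    spec = ChemostatSpec(
        c_g=c_g,
        D=D,
        substrate_exchange_id="GLC_upt",
        product_exchange_id="EX_cit",
        growth_reaction_id="GROWTH",
        x_max=x_max,
    )
    return model, spec


def toy_closed_form(params: ToyProducerParams, spec: ChemostatSpec) -> tuple[float, float]:
    """Analytic chemostat optimum of the toy producer: (VP* in g/L/h, X*).

    Derivation: maximize v_p*X = (u_g - D/k)*X subject to u_g <= u_max and
    the substrate balance u_g*X <= D*c_g (equality at the optimum, s_g=0).
    For fixed consumed substrate S = u_g*X the product rate S - (D/k)*X
    grows as X shrinks, so u_g sits at u_max and X* = D*c_g_mM/u_max,
    giving VP* = D*c_g_mM*(1 - D/(k*u_max)).  Cross-checked numerically
    against :func:`oracle_solve` in the test suite.
    """
    if not 0 < spec.D < params.mu_max:
        raise ValueError(f"closed form valid for 0 < D < {params.mu_max}")
    vp_mm = spec.D * spec.c_g_mm * (1.0 - spec.D / params.mu_max)
    x_star = spec.D * spec.c_g_mm / params.u_max
    return ch.mm_to_g_per_l(vp_mm, spec.mw_product), x_star


def oracle_solve(
    model: IntegratedModel,
    objective: dict[str, float] | None = None,
    n_grid: int = 2001,
) -> tuple[Solution, float | None]:
    """Brute-force bilinear oracle: enumerate X, solve an exact LP at each.

    At fixed X every coupling w = v*X is linear, so each grid point is a
    plain LP; the best over the grid is a *lower* bound on the true
    bilinear optimum, converging as the grid refines (while the piecewise
    relaxation bounds it from above).  Returns (best solution, best X).
    """
    if n_grid < 2:
        raise ValueError("need at least 2 grid points")
    spec = model.spec
    objective = objective or {flux_var(ch.T_COUT): 1.0}
    base = chemostat_steady_state(model)
    x_var = conc_var(ch.PLACE_X)
    best: Solution | None = None
    best_x: float | None = None
    for x in np.linspace(spec.x_min, spec.effective_x_max, n_grid):
        cs = base.copy()
        cs.set_bounds(x_var, x, x)
        for w, v, _ in model.bilinear_terms:
            cs.add_eq({w: 1.0, v: -x}, 0.0)
        sol = cs.solve(objective, sense="max")
        if sol.status != "optimal":
            continue
        if best is None or sol.objective > best.objective:
            best, best_x = sol, float(x)
    if best is None:
        return Solution(status="infeasible"), None
    return best, best_x


def random_small_cbm(
    rng: np.random.Generator,
    n_metabolites: int = 4,
    n_reactions: int = 7,
) -> ConstraintBasedModel:
    """Seeded random small constraint-based model for property tests.

    Contains a bounded source exchange (so optima stay finite), a sink,
    and random sparse integer internal stoichiometry; roughly a third of
    the internal reactions are reversible.
    """
    mets = [f"M{i}" for i in range(n_metabolites)]
    reactions = [
        Reaction("SRC", {mets[0]: 1.0}, 0.0, float(rng.integers(5, 15))),
        Reaction("SNK", {mets[-1]: -1.0}, 0.0, 1000.0),
    ]
    for j in range(n_reactions - 2):
        size = int(rng.integers(2, min(4, n_metabolites) + 1))
        chosen = rng.choice(n_metabolites, size=size, replace=False)
        stoich = {}
        for pos, m in enumerate(chosen):
            coef = float(rng.integers(1, 3))
            stoich[mets[m]] = -coef if pos < size // 2 or size == 1 else coef
        if all(c < 0 for c in stoich.values()):
            stoich[mets[int(chosen[-1])]] = abs(stoich[mets[int(chosen[-1])]])
        reversible = rng.random() < 0.35
        lb = -float(rng.integers(1, 500)) if reversible else 0.0
        reactions.append(Reaction(f"RX{j}", stoich, lb, float(rng.integers(50, 1000))))
    return ConstraintBasedModel(reactions, mets, objective="SNK")
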