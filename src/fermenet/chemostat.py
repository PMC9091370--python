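"""Chemostat macro-model and its coupling to a cell-scale Flexible Net.

A chemostat (continuous culture) feeds fresh medium at dilution rate D
(h^-1) and removes culture at the same rate.  Macroscopic state: biomass
density X (gDW L^-1), substrate concentration s_g and product concentration
s_c in the tank (mM).  At steady state

    dX/dt  = (mu - D) X        = 0    =>  mu = D,
    ds_g/dt = (c_g - s_g) D - u_g X = 0,
    ds_c/dt = -s_c D + |u_c| X      = 0,

where mu is the specific growth rate, u_g the specific substrate uptake
and u_c the specific product secretion flux of the cells (mmol gDW^-1
h^-1; the tank gains product at |u_c| X since secretion is oriented out of
the cell).  The couplings u_g*X, mu*X and |u_c|*X are *bilinear*; they are
registered symbolically on the integrated net and linearized later, either
region-wise (piecewise module) or exactly at fixed X (prediction mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fn import (
    ConstraintSystem,
    EventHandler,
    FlexibleNet,
    FNStructureError,
    Guard,
    IntensityHandler,
    LinExpr,
    Place,
    Transition,
    conc_var,
    flux_var,
    steady_state_constraints,
)

__all__ = [
    "ChemostatSpec",
    "IntegratedModel",
    "MW_GLUCOSE",
    "MW_CITRAMALATE",
    "convert_units",
    "g_per_l_to_mm",
    "mm_to_g_per_l",
    "build_integrated_fn",
    "chemostat_steady_state",
]

#: molar masses, g mol^-1
MW_GLUCOSE = 180.16
MW_CITRAMALATE = 148.12

# tank element ids used on the integrated net
PLACE_X, PLACE_G, PLACE_C = "X", "G", "C"
T_GIN, T_GOUT, T_UT = "t_gin", "t_gout", "t_ut"
T_CT, T_COUT = "t_ct", "t_cout"
T_XT, T_XOUT = "t_xt", "t_xout"
H_U, H_R, H_C = "h_u", "h_r", "h_c"
S_GOUT, S_COUT, S_XOUT = "s_gout", "s_cout", "s_xout"


def g_per_l_to_mm(value: float, molar_mass: float) -> float:
    """g L^-1 -> mM (mmol L^-1)."""
    return value / molar_mass * 1000.0


def mm_to_g_per_l(value: float, molar_mass: float) -> float:
    """mM -> g L^-1."""
    return value * molar_mass / 1000.0


def convert_units(value: float, from_unit: str, to_unit: str,
                  molar_mass: float | None = None) -> float:
    """Convert between the units the model mixes.

    Supported pairs: ``g/L <-> mM`` (needs molar mass), ``mM/h -> g/L/h``
    and back (needs molar mass), and the bilinear product unit
    ``mmol/gDW/h * gDW/L -> mM/h`` (identity on the numeric value).
    """
    pair = (from_unit, to_unit)
    needs_mw = {("g/L", "mM"), ("mM", "g/L"), ("mM/h", "g/L/h"), ("g/L/h", "mM/h")}
    if pair in needs_mw and molar_mass is None:
        raise ValueError(f"conversion {from_unit} -> {to_unit} requires a molar mass")
    if pair == ("g/L", "mM"):
        return g_per_l_to_mm(value, molar_mass)
    if pair == ("mM", "g/L"):
        return mm_to_g_per_l(value, molar_mass)
    if pair == ("mM/h", "g/L/h"):
        return value * molar_mass / 1000.0
    if pair == ("g/L/h", "mM/h"):
        return value / molar_mass * 1000.0
    if pair == ("mmol/gDW/h*gDW/L", "mM/h"):
        return value
    raise ValueError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}")


@dataclass
class ChemostatSpec:
    """Operating point and cell/tank wiring of the chemostat.

    Parameters
    ----------
    c_g:
        Substrate (glucose) concentration in the feed, g L^-1.
    D:
        Dilution rate, h^-1.
    substrate_exchange_id, product_exchange_id, growth_reaction_id:
        Ids of the cell-net transitions carrying, respectively, specific
        substrate uptake, specific product secretion (both mmol gDW^-1
        h^-1, oriented so the flux is non-negative) and the growth rate mu
        (h^-1).  If an id names a reversible reaction that was unfolded,
        the uptake resolves to its backward copy and the secretion to its
        forward copy.
    mw_substrate, mw_product:
        Molar masses, g mol^-1 (defaults: glucose and citramalate).
    x_min, x_max:
        Biomass density bounds, gDW L^-1.  ``x_max=None`` selects a
        generous yield-based cap 1.5 * 0.5 gDW per g substrate * c_g (the
        bounds need not be tight, they only frame the piecewise partition).
    """

    c_g: float
    D: float
    substrate_exchange_id: str
    product_exchange_id: str
    growth_reaction_id: str
    mw_substrate: float = MW_GLUCOSE
    mw_product: float = MW_CITRAMALATE
    x_min: float = 0.0
    x_max: float | None = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"dilution rate must be positive, got {self.D}")
        if self.c_g < 0:
            raise ValueError(f"feed concentration must be >= 0, got {self.c_g}")
        if self.mw_substrate <= 0 or self.mw_product <= 0:
            raise ValueError("molar masses must be positive")
        if self.x_max is not None and not self.x_min < self.x_max:
            raise ValueError(f"need x_min < x_max, got [{self.x_min}, {self.x_max}]")
        if self.x_min < 0:
            raise ValueError("x_min must be >= 0")

    @property
    def c_g_mm(self) -> float:
        """Feed substrate concentration in mM."""
        return g_per_l_to_mm(self.c_g, self.mw_substrate)

    @property
    def effective_x_max(self) -> float:
        if self.x_max is not None:
            return self.x_max
        return max(self.c_g * 0.5 * 1.5, 1.0)


@dataclass
class IntegratedModel:
    """The merged tank + cell Flexible Net and its bilinear registry view."""

    net: FlexibleNet
    spec: ChemostatSpec
    #: resolved transition ids for the uptake / secretion / growth couplings
    resolved: dict[str, str] = field(default_factory=dict)

    @property
    def bilinear_terms(self) -> list[tuple[str, str, str]]:
        """(interface flux var, cell exchange flux var, biomass conc var) triples."""
        return [
            (flux_var(target), flux_var(source), conc_var(place))
            for _, target, source, place in self.net.bilinear
        ]


def _resolve_transition(net: FlexibleNet, rid: str, prefer: str) -> str:
    """Find ``rid`` in the (possibly unfolded) cell net.

    ``prefer`` selects the unfolded copy when the original id is gone:
    "backward" for uptake-oriented exchanges (medium -> cell), "forward"
    for secretion-oriented ones and for growth.
    """
    if rid in net.transitions:
        return rid
    suffix = "_b" if prefer == "backward" else "_f"
    cand = f"{rid}{suffix}"
    if cand in net.transitions:
        return cand
    raise FNStructureError(
        f"reaction {rid!r} not found in cell net (also tried {cand!r})"
    )


def build_integrated_fn(cell_net: FlexibleNet, spec: ChemostatSpec) -> IntegratedModel:
    """Merge a cell FN with the chemostat macro-net.

    Adds three tank places (X, G, C), seven transitions (feed ``t_gin``,
    effluents ``t_gout``/``t_cout``/``t_xout``, interface ``t_ut``/
    ``t_ct``/``t_xt``), six intensity handlers — three linear effluent
    handlers (flux = D * concentration) and three bilinear interface
    handlers (flux = cell exchange flux * X), the latter kept symbolic in
    the bilinear registry — plus one trivial event handler per tank arc.
    The feed transition's lambda0 is pinned to D*c_g (mM h^-1).
    """
    net = cell_net  # integrated in place on a shallow-shared structure; callers
    # pass a freshly built cell net (cbm_to_fn output)
    upt = _resolve_transition(net, spec.substrate_exchange_id, "backward")
    sec = _resolve_transition(net, spec.product_exchange_id, "forward")
    gro = _resolve_transition(net, spec.growth_reaction_id, "forward")

    net.add_place(Place(PLACE_X, role="macroscopic", units="gDW/L",
                        conc_lo=spec.x_min, conc_hi=spec.effective_x_max))
    net.add_place(Place(PLACE_G, role="macroscopic", units="mM"))
    net.add_place(Place(PLACE_C, role="macroscopic", units="mM"))

    feed = spec.D * spec.c_g_mm
    net.add_transition(Transition(T_GIN, feed, feed))
    for tid in (T_GOUT, T_UT, T_CT, T_COUT, T_XT, T_XOUT):
        net.add_transition(Transition(tid, 0.0, 0.0))

    # tank event arcs (one trivial handler per arc)
    arcs = [
        (T_GIN, PLACE_G, +1.0),
        (T_UT, PLACE_G, -1.0),
        (T_GOUT, PLACE_G, -1.0),
        (T_CT, PLACE_C, +1.0),
        (T_COUT, PLACE_C, -1.0),
        (T_XT, PLACE_X, +1.0),
        (T_XOUT, PLACE_X, -1.0),
    ]
    for tid, pid, sign in arcs:
        net.add_event_handler(EventHandler(f"ev_{tid}", tid, {pid: sign}))

    # effluent handlers: flux = D * tank concentration
    for hid, tid, pid in ((S_GOUT, T_GOUT, PLACE_G),
                          (S_COUT, T_COUT, PLACE_C),
                          (S_XOUT, T_XOUT, PLACE_X)):
        expr = LinExpr({pid: spec.D})
        net.add_intensity_handler(
            IntensityHandler(hid, tid, pid, [Guard.equality(0.0, float("inf"), expr)])
        )

    # bilinear interface handlers, kept symbolic: flux(target) = flux(source) * [X]
    net.add_bilinear(H_U, T_UT, upt, PLACE_X)
    net.add_bilinear(H_R, T_XT, gro, PLACE_X)
    net.add_bilinear(H_C, T_CT, sec, PLACE_X)

    return IntegratedModel(
        net=net, spec=spec,
        resolved={"uptake": upt, "secretion": sec, "growth": gro},
    )


def chemostat_steady_state(model: IntegratedModel) -> ConstraintSystem:
    """Steady-state constraint system of the integrated net.

    Contains the cell's S.v = 0 rows and flux bounds, the tank balances
    (substrate D*c_g = u_t + D*s_g with s_g >= 0; product c_t = D*s_c with
    s_c >= 0; biomass r_t = D*X), the biomass bounds X in [Xmin, Xmax] and
    the growth-rate pinning mu = D.  The three bilinear relations remain
    symbolic (see :attr:`IntegratedModel.bilinear_terms`); callers must
    linearize them before solving.
    """
    cs = steady_state_constraints(model.net)
    gro = model.resolved["growth"]
    cs.add_eq({flux_var(gro): 1.0}, model.spec.D)
    return cs
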