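"""Region-wise linear relaxation of the biomass-flux bilinear couplings.

Each interface relation ``w = v * X`` (macroscopic flux = specific cell
flux times biomass density) is bilinear.  Partitioning the biomass range
[Xmin, Xmax] into n regions [X_{i-1}, X_i] and, inside region i, replacing
the product by the bracket

    X_{i-1} * v  <=  w  <=  X_i * v,        X in [X_{i-1}, X_i],

yields one linear program per region; the best objective over all regions
is the relaxed optimum.  Any exact bilinear solution is feasible in the
region containing its X, so the relaxed optimum is an *upper bound* on the
true one, tightening monotonically under nested refinement.  The same
partition of X serves all three interface handlers at once.

Regions are solved as independent LPs by default (fast, embarrassingly
separable); an equivalent single mixed-integer program with one binary
indicator per region is available behind ``solve_piecewise(..., mode=
"milp")`` for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemostat import IntegratedModel, chemostat_steady_state
from .fn import ConstraintSystem, Solution

__all__ = [
    "BiomassPartition",
    "RegionProblem",
    "partition_biomass",
    "region_problem",
    "solve_piecewise",
]


@dataclass(frozen=True)
class BiomassPartition:
    """Ordered breakpoints X0=Xmin < X1 < ... < Xn=Xmax (gDW L^-1)."""

    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if len(bp) < 2:
            raise ValueError("a partition needs at least two breakpoints")
        if any(b <= a for a, b in zip(bp, bp[1:])):
            raise ValueError(f"breakpoints must be strictly increasing: {bp}")

    @property
    def n(self) -> int:
        return len(self.breakpoints) - 1

    def region(self, i: int) -> tuple[float, float]:
        """Closed interval of 1-based region ``i``."""
        if not 1 <= i <= self.n:
            raise IndexError(f"region index {i} outside 1..{self.n}")
        return self.breakpoints[i - 1], self.breakpoints[i]


def partition_biomass(
    x_min: float,
    x_max: float,
    n: int = 100,
    breakpoints: list[float] | None = None,
) -> BiomassPartition:
    """Partition [x_min, x_max] into ``n`` regions (uniform by default).

    Explicit interior ``breakpoints`` need not be evenly separated; they
    must be strictly increasing within (x_min, x_max).
    """
    if not x_min < x_max:
        raise ValueError(f"need x_min < x_max, got [{x_min}, {x_max}]")
    if breakpoints is not None:
        interior = [float(b) for b in breakpoints]
        if any(not x_min < b < x_max for b in interior):
            raise ValueError("explicit breakpoints must lie strictly inside the range")
        return BiomassPartition(tuple([x_min, *interior, x_max]))
    if n < 1:
        raise ValueError(f"region count must be >= 1, got {n}")
    return BiomassPartition(tuple(np.linspace(x_min, x_max, n + 1).tolist()))


@dataclass
class RegionProblem:
    """The LP of one region: steady state + X clamp + bilinear brackets."""

    index: int
    interval: tuple[float, float]
    system: ConstraintSystem


def _bracket_bilinear(
    cs: ConstraintSystem, model: IntegratedModel, x_lo: float, x_hi: float
) -> None:
    for w, v, _ in model.bilinear_terms:
        # x_lo * v <= w  and  w <= x_hi * v
        cs.add_ub({v: x_lo, w: -1.0}, 0.0)
        cs.add_ub({w: 1.0, v: -x_hi}, 0.0)


def region_problem(
    model: IntegratedModel,
    partition: BiomassPartition,
    i: int,
    base: ConstraintSystem | None = None,
) -> RegionProblem:
    """Build region ``i``'s LP (1-based).

    Interval membership is closed on both ends: both LPs adjacent to an
    interior breakpoint contain it, which is harmless for a max and avoids
    boundary infeasibility.  ``base`` lets callers reuse one
    ``chemostat_steady_state`` build across regions.
    """
    x_lo, x_hi = partition.region(i)
    cs = (base.copy() if base is not None else chemostat_steady_state(model))
    x_var = model.bilinear_terms[0][2] if model.bilinear_terms else "m[X]"
    cs.tighten_bounds(x_var, x_lo, x_hi)
    _bracket_bilinear(cs, model, x_lo, x_hi)
    return RegionProblem(index=i, interval=(x_lo, x_hi), system=cs)


def solve_piecewise(
    model: IntegratedModel,
    partition: BiomassPartition,
    objective: dict[str, float],
    sense: str = "max",
    mode: str = "regions",
) -> tuple[Solution, int | None]:
    """Solve the region-wise relaxation; return (best solution, region index).

    ``objective`` maps constraint-system variables (e.g. ``v[t_cout]``) to
    coefficients.  Infeasible regions are skipped; if every region is
    infeasible the returned solution's status is "infeasible" and the
    region index is None.  Ties between regions keep the lowest index.
    ``mode="milp"`` solves the equivalent single mixed-integer program
    instead (cross-checking aid; requires finite variable bounds).
    """
    if mode == "milp":
        return _solve_milp(model, partition, objective, sense)
    if mode != "regions":
        raise ValueError(f"unknown mode {mode!r}")
    base = chemostat_steady_state(model)
    best: Solution | None = None
    best_region: int | None = None
    better = (lambda a, b: a > b) if sense == "max" else (lambda a, b: a < b)
    for i in range(1, partition.n + 1):
        rp = region_problem(model, partition, i, base=base)
        sol = rp.system.solve(objective, sense=sense)
        if sol.status != "optimal":
            continue
        if best is None or better(sol.objective, best.objective):
            best, best_region = sol, i
    if best is None:
        return Solution(status="infeasible"), None
    return best, best_region


# -----------------------------------------------------------------------------
# single-MILP cross-check


def _solve_milp(
    model: IntegratedModel,
    partition: BiomassPartition,
    objective: dict[str, float],
    sense: str,
) -> tuple[Solution, int | None]:
    """Big-M MILP with one binary region indicator; equivalence testing only."""
    from scipy.optimize import LinearConstraint, milp
    from scipy.optimize import Bounds as OptBounds

    cs = chemostat_steady_state(model)
    names = cs.variables
    idx = {v: k for k, v in enumerate(names)}
    nv = len(names)
    n = partition.n
    x_var = model.bilinear_terms[0][2]
    x_min, x_max = partition.breakpoints[0], partition.breakpoints[-1]

    # finite bounds are required to size the big-M constants
    var_bounds = [cs.bounds_of(v) for v in names]
    big = 0.0
    for w, v, _ in model.bilinear_terms:
        _, v_hi = cs.bounds_of(v)
        if not math.isfinite(v_hi):
            raise ValueError(
                f"MILP mode needs a finite upper bound on {v}; tighten the "
                "cell model's exchange bounds or use mode='regions'"
            )
        big = max(big, x_max * v_hi)
        # w is a free intensity variable; clamp it so big-M rows are valid
        w_lo, w_hi = cs.bounds_of(w)
        cs.set_bounds(w, max(w_lo, -x_max * v_hi), min(w_hi, x_max * v_hi))
    big = max(big, x_max - x_min, 1.0)
    var_bounds = [cs.bounds_of(v) for v in names]

    rows, lbs, ubs = [], [], []

    def emit(coeffs: dict[int, float], lo: float, hi: float) -> None:
        r = np.zeros(nv + n)
        for j, c in coeffs.items():
            r[j] = c
        rows.append(r)
        lbs.append(lo)
        ubs.append(hi)

    for coeffs, rhs in cs._eq:
        emit({idx[v]: c for v, c in coeffs.items()}, rhs, rhs)
    for coeffs, rhs in cs._ub:
        emit({idx[v]: c for v, c in coeffs.items()}, -np.inf, rhs)
    # exactly one active region
    emit({nv + k: 1.0 for k in range(n)}, 1.0, 1.0)
    for k in range(n):
        x_lo, x_hi = partition.region(k + 1)
        y = nv + k
        # y=1 clamps X to [x_lo, x_hi]; y=0 leaves the global [x_min, x_max]
        emit({idx[x_var]: 1.0, y: -(x_lo - x_min)}, x_min, np.inf)
        emit({idx[x_var]: 1.0, y: (x_max - x_hi)}, -np.inf, x_max)
        for w, v, _ in model.bilinear_terms:
            m = 2 * big
            # w - x_lo v >= -M(1-y)  ->  w - x_lo v - M y >= -M
            emit({idx[w]: 1.0, idx[v]: -x_lo, y: -m}, -m, np.inf)
            # w - x_hi v <= M(1-y)   ->  w - x_hi v + M y <= M
            emit({idx[w]: 1.0, idx[v]: -x_hi, y: m}, -np.inf, m)

    c = np.zeros(nv + n)
    for v, coef in objective.items():
        c[idx[v]] = coef
    sign = -1.0 if sense == "max" else 1.0
    lb = np.array([b[0] for b in var_bounds] + [0.0] * n)
    ub = np.array([b[1] for b in var_bounds] + [1.0] * n)
    integrality = np.concatenate([np.zeros(nv), np.ones(n)])
    res = milp(
        sign * c,
        constraints=LinearConstraint(np.vstack(rows), np.array(lbs), np.array(ubs)),
        bounds=OptBounds(lb, ub),
        integrality=integrality,
    )
    if res.status == 2 or res.x is None:
        return Solution(status="infeasible"), None
    values = {v: float(res.x[idx[v]]) for v in names}
    region = int(np.argmax(res.x[nv:])) + 1
    return (
        Solution(status="optimal", objective=float(sign * res.fun), values=values),
        region,
    )
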