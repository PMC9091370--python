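"""Text formats: the model dialect, FN JSON serialization, CSV output.

Model dialect
-------------
*TSV*: header ``id<TAB>formula<TAB>lb<TAB>ub``; formulas like
``2 A + B -> D`` or ``A <-> 2 B`` (an empty side is an exchange).
*JSON*: ``{"reactions": [{"id", "formula" | "stoich", "lb", "ub"}, ...],
"objective": <reaction id or null>}``.

FN JSON schema
--------------
``{"places": [{"id", "role", "units", "conc_lo", "conc_hi"}],
"transitions": [{"id", "l0": [lo, hi]}],
"event_handlers": [{"id", "transition", "stoich": {place: coef}}],
"intensity_handlers": [{"id", "transition", "observed",
    "guards": [{"cond": [lo, hi],
                "relations": {"lower": {"coeffs", "const"},
                              "upper": {...}}}]}],
"bilinear": [[handler, target, source, place], ...]}``
with ``"inf"``/``-"inf"`` encoding infinities.
"""

from __future__ import annotations

import csv
import json
import math
from typing import Any

from .cbm import ConstraintBasedModel, ModelError, Reaction, parse_formula
from .fn import (
    EventHandler,
    FlexibleNet,
    Guard,
    IntensityHandler,
    LinExpr,
    Place,
    Transition,
)

__all__ = [
    "read_model_dialect",
    "write_model_dialect",
    "fn_to_json",
    "fn_from_json",
    "write_sweep_csv",
]


# -----------------------------------------------------------------------------
# model dialect


def read_model_dialect(path: str, format: str) -> ConstraintBasedModel:
    if format == "tsv":
        return _read_tsv(path)
    if format == "json":
        return _read_json(path)
    raise ModelError(f"unknown dialect format {format!r}")


def _read_tsv(path: str) -> ConstraintBasedModel:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    if not rows:
        raise ModelError(f"{path}: empty model file")
    records = [
        {"id": r["id"], "formula": r["formula"], "lb": r.get("lb"), "ub": r.get("ub")}
        for r in rows
    ]
    from .cbm import _from_records

    return _from_records(records, objective=None)


def _read_json(path: str) -> ConstraintBasedModel:
    with open(path) as fh:
        doc = json.load(fh)
    if not doc.get("reactions"):
        raise ModelError(f"{path}: no reactions in model file")
    from .cbm import _from_records

    return _from_records(doc["reactions"], objective=doc.get("objective"))


def write_model_dialect(model: ConstraintBasedModel, path: str) -> None:
    """Write the JSON dialect (explicit stoichiometry form)."""
    doc = {
        "reactions": [
            {"id": r.id, "stoich": r.stoich, "lb": r.lb, "ub": r.ub}
            for r in model.reactions
        ],
        "objective": model.objective,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# -----------------------------------------------------------------------------
# FN JSON


def _num(x: float) -> Any:
    if x == math.inf:
        return "inf"
    if x == -math.inf:
        return "-inf"
    return x


def _denum(x: Any) -> float:
    if x == "inf":
        return math.inf
    if x == "-inf":
        return -math.inf
    return float(x)


def fn_to_json(net: FlexibleNet) -> dict:
    def expr(e: LinExpr) -> dict:
        return {"coeffs": e.coeffs, "const": e.const}

    return {
        "places": [
            {"id": p.id, "role": p.role, "units": p.units,
             "conc_lo": _num(p.conc_lo), "conc_hi": _num(p.conc_hi)}
            for p in net.places.values()
        ],
        "transitions": [
            {"id": t.id, "l0": [_num(t.lambda0_lo), _num(t.lambda0_hi)]}
            for t in net.transitions.values()
        ],
        "event_handlers": [
            {"id": h.id, "transition": h.transition, "stoich": h.stoich}
            for h in net.event_handlers.values()
        ],
        "intensity_handlers": [
            {
                "id": h.id,
                "transition": h.transition,
                "observed": h.observed,
                "guards": [
                    {"cond": [_num(g.lo), _num(g.hi)],
                     "relations": {"lower": expr(g.lower), "upper": expr(g.upper)}}
                    for g in h.guards
                ],
            }
            for h in net.intensity_handlers.values()
        ],
        "bilinear": [list(entry) for entry in net.bilinear],
    }


def fn_from_json(doc: dict) -> FlexibleNet:
    net = FlexibleNet()
    for p in doc.get("places", []):
        net.add_place(
            Place(p["id"], p.get("role", "metabolite"), p.get("units", "mM"),
                  _denum(p.get("conc_lo", 0.0)), _denum(p.get("conc_hi", "inf")))
        )
    for t in doc.get("transitions", []):
        lo, hi = t.get("l0", [0.0, 0.0])
        net.add_transition(Transition(t["id"], _denum(lo), _denum(hi)))
    for h in doc.get("event_handlers", []):
        net.add_event_handler(
            EventHandler(h["id"], h["transition"],
                         {k: float(v) for k, v in h["stoich"].items()})
        )
    for h in doc.get("intensity_handlers", []):
        guards = []
        for g in h["guards"]:
            lower = LinExpr({k: float(v) for k, v in g["relations"]["lower"]["coeffs"].items()},
                            float(g["relations"]["lower"]["const"]))
            upper = LinExpr({k: float(v) for k, v in g["relations"]["upper"]["coeffs"].items()},
                            float(g["relations"]["upper"]["const"]))
            guards.append(Guard(_denum(g["cond"][0]), _denum(g["cond"][1]), lower, upper))
        net.add_intensity_handler(
            IntensityHandler(h["id"], h["transition"], h["observed"], guards)
        )
    for entry in doc.get("bilinear", []):
        net.add_bilinear(*entry)
    return net


# -----------------------------------------------------------------------------
# tabular output


def _fmt(x: Any) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_sweep_csv(table, path: str) -> None:
    """Write a sweep table: 6 significant digits, deterministic row order.

    Rows are emitted glucose-major, dilution-minor; infeasible points get
    empty numeric fields.
    """
    frame = table.frame if hasattr(table, "frame") else table
    if len(frame) == 0:
        raise ValueError("refusing to write an empty sweep table")
    frame = frame.sort_values(
        ["glucose_g_per_L", "dilution_per_h"], kind="mergesort"
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(frame.columns.tolist())
        for _, row in frame.iterrows():
            w.writerow([_fmt(v) for v in row.tolist()])
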