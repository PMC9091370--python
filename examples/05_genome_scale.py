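"""End-to-end run on a genome-scale E. coli model (user-supplied SBML).

Downloads are deliberately not automated: place iJO1366 (BioModels
accession MODEL1108160000, or the BiGG SBML) at models/iJO1366.xml, then
run this script.  It grafts the citramalate pathway (synthase cimA:
acetyl-CoA + pyruvate + H2O -> citramalate + CoA + H+, plus an exchange)
onto the model, couples it to a glucose-limited chemostat and predicts the
citramalate concentration at a measured biomass density.
"""

import pathlib

from fermenet import ChemostatSpec, add_citramalate_pathway, load_model, predict_concentrations

MODEL = pathlib.Path(__file__).resolve().parent.parent / "models" / "iJO1366.xml"

if not MODEL.exists():
    raise SystemExit(
        f"model not found at {MODEL}\n"
        "download iJO1366 (BioModels MODEL1108160000) and place it there"
    )

model = add_citramalate_pathway(load_model(str(MODEL)))
spec = ChemostatSpec(
    c_g=10.0,
    D=0.17,
    substrate_exchange_id="EX_glc__D_e",
    product_exchange_id="EX_citramalate",
    growth_reaction_id="BIOMASS_Ec_iJO1366_core_53p95M",
    x_max=20.0,
)
res = predict_concentrations(model, spec, x_measured=3.54)
print(f"status {res.status}: citramalate {res.s_c:.2f} g/L, "
      f"residual glucose {res.s_g:.2f} g/L")
print("the prediction depends on the medium/uptake bounds carried by the "
      "SBML file; tighten exchange bounds to emulate a defined medium.")
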