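"""Predict tank concentrations at a measured biomass density.

With X fixed to a measured value the tank/cell couplings w = v*X become
linear, so a single exact LP predicts the product concentration in the
tank and the residual substrate.  Comparing predictions with measured
concentrations via the relative error 100*(observed - predicted)/predicted
is how the integrated model is validated against chemostat runs.
"""

from fermenet import (
    make_toy_producer,
    predict_concentrations,
    relative_error,
    toy_closed_form,
    ToyProducerParams,
)

params = ToyProducerParams()
model, spec = make_toy_producer(params, c_g=10.0, D=0.5)
_, x_star = toy_closed_form(params, spec)

for x in (0.5 * x_star, x_star, 1.3 * x_star):
    res = predict_concentrations(model, spec, x_measured=x)
    print(f"X = {x:.3f} gDW/L -> citramalate {res.s_c:.3f} g/L, "
          f"residual glucose {res.s_g:.3f} g/L  [{res.status}]")

pred = predict_concentrations(model, spec, x_measured=x_star).s_c
mock_observed = 0.9 * pred  # stand-in for a wet-lab measurement
print(f"\na measurement of {mock_observed:.3f} g/L against the prediction "
      f"{pred:.3f} g/L gives a relative error of "
      f"{relative_error(mock_observed, pred):.2f}%")
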