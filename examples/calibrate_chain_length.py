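"""Fit the chain-length calibration and predict CL for a measured oil.

Fits CL = a*(R2/eta) + b over the bundled 17-oil reference panel,
cross-validates it leave-one-out, and applies it to oleic acid.
"""

from relaxochain import (
    fit_calibration,
    load_table1,
    loo_cross_validate,
    predict_chain_length,
)

records = load_table1()
model = fit_calibration(records)
print(f"calibration over {model.n_samples} oils: "
      f"CL = {model.slope_a:.3f} * (R2/eta) + ({model.intercept_b:.4f})")
print(f"R^2 = {model.r_squared:.3f}, in-sample RMSE = {model.rmse_cl:.2f} carbons")

loo = loo_cross_validate(records)
print(f"leave-one-out RMSE = {loo.loo_rmse:.2f} carbons "
      f"(vs {loo.in_sample_rmse:.2f} in-sample)")
worst = loo.table.loc[loo.table["error"].abs().idxmax()]
print(f"hardest oil to predict: {worst['name']} "
      f"(held-out error {worst['error']:+.1f} carbons)")

# oleic acid: R2 = 6.525 1/s at eta = 17.6 cp
pred = predict_chain_length(model, r2_per_s=6.524779, viscosity_cp=17.6)
print(f"oleic acid prediction: CL = {pred.chain_length:.2f} "
      f"-> {pred.chain_length_rounded} carbons (true chain length: 18)")
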