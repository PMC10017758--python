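"""Physical constants and published operating parameters shared across modules.

All specific rates are mmol·gDW⁻¹·h⁻¹, growth rates h⁻¹, concentrations mg·L⁻¹
unless a name says otherwise.
"""

# Molecular masses, mg·mmol⁻¹.  Nitrate is reported as the NO3⁻ ion (the
# colorimetric assay measures the ion); 85.0 would give NaNO3-equivalents.
MW_GLUCOSE = 180.16
MW_NITRATE = 62.00

# Fixed growth rates used by the open-loop predictor (h⁻¹).
MU_LIGHT = 0.035
MU_DARK = 0.023

# Exchange-rate anchors at those growth rates (mmol·gDW⁻¹·h⁻¹), the values the
# calibrated stoichiometric model must reproduce under FBA.
R_N_LIGHT = 0.1823   # nitrate uptake, autotrophic, at MU_LIGHT
R_N_DARK = 0.1417    # nitrate uptake, heterotrophic, at MU_DARK
R_G_DARK = 0.6426    # glucose uptake, heterotrophic, at MU_DARK
R_G_LIGHT = 0.0      # no glucose uptake in the light (autotrophic)

# Light-shading growth law mu = SHADING_MU0 * exp(-SHADING_K * x[mg/L]).
SHADING_MU0 = 0.0338   # h⁻¹
SHADING_K = 0.00174    # per mg·L⁻¹ biomass

# Bolus feed hardware: stock concentrations (mg·mL⁻¹) and pump flow (mL·s⁻¹).
C_G_STOCK = 20.0
C_N_STOCK = 5.0
PUMP_Q = 3.0

# PID gains for the baseline controller comparison.
PID_KP = 1.91
PID_KI = 1.27
PID_KD = 0.10
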