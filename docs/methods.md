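# Methods

`gmpc` reconstructs, as tested simulation code, a genome-scale model process
control (GMPC) workflow for *Chlorella*-type microalgae grown under
alternating light (photoautotrophic) and dark (heterotrophic) phases in a
fed-batch bioreactor. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic plant does and does
not capture.

## The rate map: from growth rate to substrate demand

All controllers share one contract: given a growth mode and a specific
growth rate μ (h⁻¹), return specific exchange rates r_G (glucose) and r_N
(nitrate) in mmol·gDW⁻¹·h⁻¹. The map is calibrated to one anchor pair per
mode:

| mode  | μ (h⁻¹) | r_G | r_N |
|-------|---------|------|------|
| light | 0.035 | 0 | 0.1823 |
| dark  | 0.023 | 0.6426 | 0.1417 |

Two interchangeable backends exist and are cross-checked in the tests:

* **table** — linear through the origin, r(μ) = (r_anchor/μ_anchor)·μ, with
  an optional affine maintenance offset (default 0; the anchors are assumed
  to carry no non-growth-associated maintenance, since nothing in the
  calibration data separates the two).
* **fba** — a small two-mode stoichiometric model solved with cobra/GLPK.
  The biomass equations carry substrate coefficients r/μ (e.g.
  0.1417/0.023 ≈ 6.161 mmol nitrate per gDW of heterotrophic biomass), so
  fixing the biomass flux to μ and minimizing uptake reproduces the table
  exactly. The LP convention is: pin biomass flux, then lexicographically
  minimize substrate uptake, carbon source before nitrate, each stage fixed
  to within 1e−8 before the next. Parsimonious total-flux minimization
  would give the same uptakes on this network; minimal-uptake is the
  convention exposed.

The packaged toy model (`data/toy_model.json`, COBRA JSON) has 12 reactions:
five exchanges (glucose, nitrate, CO₂, photons, O₂), five transports, and
one biomass reaction per mode. It deliberately contains no internal
metabolism — its only job is to realize the μ→r contract through an LP so
that the code path used with a real genome-scale reconstruction is
exercised end to end. Designated reactions (biomass, the four tracked
exchanges) are resolved by explicit identifier maps, never name heuristics.
An optional photon-uptake cap stands in for "minimal light" when the
autotrophic model is evaluated inside a dark phase (default cap 1e−3
mmol·gDW⁻¹·h⁻¹ if used).

## The plant

The synthetic bioreactor tracks biomass x (gDW·L⁻¹), glucose G and nitrate
N (mg·L⁻¹), and volume V (L).

**Light phases** use the biomass-shading growth law
μ = μ₀·exp(−k·x[mg/L]) with μ₀ = 0.0338 h⁻¹ and k = 0.00174 per mg·L⁻¹.
The biomass unit inside the exponential is mg·L⁻¹: only then does the decay
reproduce the observed decline of light-phase growth to ≈ 0.019 h⁻¹ near
330 mg/L and ≈ 0.014 h⁻¹ near 500 mg/L. Glucose is untouched in the light;
nitrate uptake follows the rate map at the shaded μ, times a Monod factor
so uptake shuts off at exhaustion.

**Dark phases** support mixed metabolism: a fraction `a_true` of the biomass
grows autotrophically (CO₂-fixing, rate μ_A,max, default 0.020 h⁻¹) while
the rest grows heterotrophically on glucose (μ_H,max, default 0.023 h⁻¹).
Substrate limitation is Monod: f_G = G/(K_G+G), f_N = N/(K_N+N) with
K_G = 5 mg·L⁻¹ and K_N = 2 mg·L⁻¹ by default — small enough to act only as
a smooth shut-off near exhaustion (standard dynamic-FBA practice that keeps
concentrations non-negative), large enough to matter near-depletion:

    μ_H = μ_H,max · f_G · f_N         μ_A = μ_A,max · f_N
    dx/dt = (a_true·μ_A + μ_H) · x
    dG/dt = −Mw_G · r_G(μ_H) · x
    dN/dt = −Mw_N · (a_true·r_NA(μ_A) + r_NH(μ_H)) · x

Mode switches are instantaneous (rapid metabolic steady-state assumption);
no transient kinetics are modeled.

**Boluses** are instantaneous with exact mixing: a demand F (mg per L of
culture) adds mass F·V and volume F·V/C from a stock of concentration C
(20 mg·mL⁻¹ glucose, 5 mg·mL⁻¹ nitrate), diluting biomass accordingly; the
pump run-time F·V/(C·Q) at Q = 3 mL·s⁻¹ is recorded. A typical bolus adds
≈ 0.5–1.5 % volume; a `dilution=False` toggle gives the constant-volume
idealization. Nitrate masses are reported as the NO₃⁻ ion
(Mw = 62.00 mg·mmol⁻¹, configurable to 85.0 for NaNO₃-equivalents);
glucose uses 180.16.

**Integration** is piecewise: the adaptive solver (LSODA, rtol 1e−10,
atol 1e−12) restarts at every phase boundary and bolus because the dynamics
are only piecewise smooth. The state vector carries cumulative consumed
substrate masses so that conservation (initial + fed − consumed = remaining)
can be asserted to 1e−6 relative on every scenario without re-quadrature.

**Measurements** are linear interpolations of the truth plus additive
Gaussian noise clipped at zero, with defaults σ_x = 5, σ_G = 2,
σ_N = 1 mg·L⁻¹ — the scale of OD-based biomass proxies and enzymatic/
colorimetric assays. A shared seeded generator makes every scenario
bit-reproducible.

## Controllers

**Open loop** extrapolates biomass with the fixed rates (0.035 light /
0.023 dark) and feeds, per phase start, the closed-form demand integral
F = Mw·r·x₀·(e^{μΔt} − 1)/μ over the actual phase duration (16 h light
nitrate, 8 h dark glucose + nitrate); `expm1` keeps the μ→0 limit exact.
No measurement is ever read — a purity property the tests assert.

**Closed loop (cycle-wise)** measures (x_m, G_m, N_m) at every phase
boundary. For each completed dark cycle it computes the calculated growth
rate μ_c = ln(x_t/x_{t−8})/8 and the consumed substrate per litre
(previous level + fed bolus − current level, floored at 0 — the magnitude
convention keeps the objective's denominators positive even though the raw
level difference is negative under consumption). It then minimizes

    J = ((μ_model−μ_c)/μ_c)² + ((F_G,model−F_GC)/F_GC)² + ((F_N,model−F_NC)/F_NC)²

over the mixed-metabolism parameters, with μ_model = a·μ_A + μ_H and model
demands from the same closed-form integral. Any denominator with magnitude
≤ 1e−6 switches that term to absolute squared error and the result is
flagged. The default fit optimizes (a, μ_A, μ_H) with each exchange rate
tied to its growth rate through the rate map (genome-scale consistency);
a literal six-parameter mode with box bounds [0, 2× anchor] is available.

*Identifiability.* J depends on a and μ_A only through the product a·μ_A,
so the pair is a flat ridge. The fit therefore adds a tiny quadratic tether
(weight 1e−6) pulling μ_A toward its nominal value — the autotrophic growth
rate the genome-scale model predicts at the minimal dark-phase light level
(default 0.020 h⁻¹) — which selects a unique, scientifically meaningful
point on the ridge. The reported J excludes the tether. The search is a
deterministic multi-start bounded L-BFGS-B (an analytic warm start that
reads μ_H off the glucose demand, a nominal start, and 8 seeded draws;
ftol 1e−16). With noiseless data the pure-heterotrophic case closes exactly
(J ≲ 1e−10): the demand integral evaluated at μ_c telescopes to
Mw·coeff·(x_end − x_start) no matter how the instantaneous rate varied.

Light cycles feed nitrate only, sized from the shading-law μ at the
measured biomass density through the rate map.

**Hourly setpoint law (GMPC)** for the PID comparison: feed = predicted
consumption over the next hour + (setpoint − measured), floored at 0. The
consumption forecast uses the rate map at a growth rate re-estimated every
hour from the previous hour's observed consumption (feedback through the
model, which is what lets the controller absorb plant–model mismatch);
before the first update it uses the nominal dark rate 0.023 h⁻¹.

**PID baseline**: positional discrete PID, rectangle-rule integral,
backward-difference derivative on the measurement (no setpoint kick),
gains K_p = 1.91, K_i = 1.27 h⁻¹, K_d = 0.10 h, 1 h interval. The output
is a feed amount floored at 0; anti-windup is conditional integration plus
an optional hard clamp. Feeds are one-sided actuators — neither controller
can remove substrate, which is why downward setpoint steps are followed by
a burn-down interval set by the culture's own consumption rate.

## The reference comparison scenario

The packaged setpoint-tracking comparison runs a dark (heterotrophic)
reactor for 50 h at 1 h control interval: initial biomass 0.4 gDW·L⁻¹ (the
density of the reference experimental comparison), glucose starting at its
40 mg·L⁻¹ setpoint stepping to 20 at 20 h, nitrate starting at 20 stepping
to 10 at 35 h, V = 2 L. The plant is simulated noiselessly: the comparison
emulates a deterministic numerical (Simulink-style) experiment, and the
controller–plant mismatch that feedback must absorb comes from the plant's
Monod saturation and self-dilution rather than from assay noise. The seed
is still threaded through so noisy variants reproduce exactly.

On this scenario the PID loop shows the classic damped oscillation (the
proportional gain near 2 on a near-integrating plant alternates the error
sign) while the GMPC law settles without overshoot; summed post-step
errors, their relative reduction, and the late nitrate deviation are the
quantities `scripts/acceptance.py` recomputes.

## What the synthetic plant does not capture

* No pH, temperature, dissolved O₂/CO₂, or light-spectrum effects; light
  shading is a single exponential in biomass density.
* The mixotrophic dark fraction is a fixed plant parameter, not a dynamic
  physiological state; real cultures shift it with history and CO₂ supply.
* Measurement noise is Gaussian and independent; real assays drift and
  correlate.
* Biomass composition is fixed: no nitrogen-quota dynamics, no product
  (lutein/lipid) pools. Yields computed here are carbon bookkeeping on the
  toy rate map, not predictions for a real strain.

Passing tests therefore demonstrate internal consistency of the control
algorithms against this plant — not quantitative fidelity to any specific
culture. Problem sizes in the tests (8 h single cycles for fits, 48–96 h
scenarios, a 50 h comparison) were chosen as the smallest runs that exercise
every code path with multiple cycles.

## Numerical conventions

* LP feasibility/optimality 1e−8; rate comparisons 1e−6.
* ODE tolerances rtol 1e−10 / atol 1e−12; trajectory sampling every 0.25 h
  plus all breakpoints.
* Degenerate inputs: μ = 0 uses the analytic limit of the demand integral
  (no numeric guard threshold); zero denominators in J switch to absolute
  form; zero-glucose fed yields are reported as `None` markers, never
  exceptions.
* All randomness flows from a single `numpy` Generator per scenario seed;
  fits use an internal fixed seed for their start list so identical inputs
  give identical parameters.
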