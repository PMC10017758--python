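"""Closed-loop GMPC over four 16 h light / 8 h dark cycles.

Light phases: the shading law mu = 0.0338*exp(-0.00174*x) sets the growth
forecast and the rate map sizes the nitrate bolus.  Dark phases: the most
recent dark cycle is refit (mixed-metabolism parameters) and the fit dictates
the next glucose + nitrate boluses.  Feeds respond to the measured culture,
unlike the open-loop plan.
"""

from gmpc.scenarios import closed_loop_scenario, run_scenario

scenario = closed_loop_scenario(seed=3)
traj, log, metrics = run_scenario(scenario)

print("feeds commanded at each phase start (from noisy measurements):")
print(f"  {'t (h)':>6} {'phase':>6} {'x_m (mg/L)':>10} {'F_G':>8} {'F_N':>8}")
for row in log.itertuples():
    print(f"  {row.t:6.1f} {row.phase:>6} {row.x_m:10.1f} {row.F_G:8.2f} {row.F_N:8.2f}")

final = traj.final_state()
y = metrics.yield_on_consumed
print(f"\nfinal biomass {final.x * 1000:.1f} mg/L; "
      f"glucose fed {metrics.fed_g:.0f} mg, consumed {metrics.consumed_g:.0f} mg")
print(f"biomass yield on consumed glucose: {y:.2f} g/g")
print("dark-phase residual glucose (mg/L) at cycle ends:",
      [round(r["G"], 1) for r in metrics.residuals if r["phase"] == "dark"])
# Dark boluses are sized to be consumed nearly completely, so residual
# glucose at dark-cycle ends stays low while biomass keeps accumulating.
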