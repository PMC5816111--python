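"""Thyroid activity build-up under repeated occupational intakes.

Solves the compartmental model for a male nurse inhaling the gas fraction
every 3 days and prints the thyroid activity trajectory: after ~8 intakes
the weekly pattern reaches a quasi-equilibrium plateau, the quantity a
whole-body counter would measure.
"""

from iodair import biokinetics, deposition, scenario

s = scenario.ExposureScenario.default("nurse", "male")
model = biokinetics.build_iodine_model("male", "gas")
intake = scenario.single_intake(s, "gas")
deposit = deposition.regional_deposition(intake, "male", "gas")
horizon = 36.0
timeline = scenario.build_timeline(s, horizon)
traj = biokinetics.solve(model, timeline, deposit, horizon)

print(f"single gas intake: {intake:.0f} Bq every {s.intake_spacing:.0f} d")
print("t [d]  thyroid [Bq]")
for t in range(0, 37, 3):
    print(f"{t:5d}  {biokinetics.thyroid_activity(traj, float(t)):10.0f}")

plateau = biokinetics.plateau_thyroid_activity(s)
print(f"\nmid-interval plateau activity: {plateau:.0f} Bq")
print("(evaluated at the midpoint of an inter-intake interval after >=10 "
      "intakes, when the build-up has converged)")
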