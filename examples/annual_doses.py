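"""Annual equivalent and effective doses for the four reference workers.

Runs the full chain (scenario -> deposition -> biokinetics -> dose
summation) for technicians (weekly 6-h hot-room intakes at 490 Bq/m^3 gas)
and nurses (12-h shifts every 3 days at 170 Bq/m^3 gas), both sexes,
with the default first-principles S-table.
"""

from iodair import dosimetry, scenario

print(f"{'worker':22s} {'fraction':8s} {'intake Bq/yr':>12s} "
      f"{'H_thyroid Sv/yr':>15s} {'E Sv/yr':>10s}")
for profession in ("technician", "nurse"):
    for sex in ("male", "female"):
        s = scenario.ExposureScenario.default(profession, sex)
        report = dosimetry.annual_dose(s)
        for fraction, fd in report.fractions.items():
            print(
                f"{profession + ' ' + sex:22s} {fraction:8s} {fd.annual_intake:12.0f} "
                f"{fd.tissue_equivalent['thyroid']:15.2g} {fd.effective:10.2g}"
            )
print(
    "\nThe gas fraction dominates (aerosol doses are 1-2 orders of magnitude"
    "\nsmaller); the thyroid receives by far the largest equivalent dose, and"
    "\nE/H_thyroid stays close to the thyroid tissue weighting factor 0.04."
)
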