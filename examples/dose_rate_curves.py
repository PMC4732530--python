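"""Surface beta dose-rate curves for a range of deposition-ratio mixes.

Prints the dose rate (uSv/h per 1000 kBq/m2 of Cs-137) at a few times
after deposition for the standard I-131/Cs-137 ratio sweep at
Te-129m/Cs-137 = 1.  The iodine-rich mixes start far higher but decay
to the common caesium floor within about 80 days.
"""
import numpy as np

import betadose as bd

model = bd.calibrate_coefficients(bd.PUBLISHED_FIT)
times_days = np.array([0, 1, 5, 10, 20, 40, 80, 160, 365])

print("dose rate (uSv/h per 1000 kBq/m2 Cs-137), r_T = 1:")
print("days:     " + "".join(f"{d:>9d}" for d in times_days))
for r_i in bd.DEFAULT_RI_GRID:
    curve = bd.dose_rate_curve(model, bd.RatioSet(r_i, 1.0), times_days * 24.0)
    print(f"r_I={r_i:5.1f} " + "".join(f"{r:9.3f}" for r in curve.rates))

one_year = bd.cumulative_dose(model, bd.RatioSet(9.2, 1.0))
print(f"\none-year cumulative dose at (r_I, r_T) = (9.2, 1): {one_year:.1f} mSv"
      " per 1000 kBq/m2 of Cs-137")
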