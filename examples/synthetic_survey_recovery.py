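"""Full synthetic round trip: plume -> survey -> pipeline -> recovery report.

Generates a ground-truthed fallout plume, samples a mesh survey months
after deposition (decay, measurement noise, I-131 detection-limit
censoring), runs the dose pipeline on the survey, and compares the
recovered per-location doses with the exact truth.
"""
import betadose as bd

config = bd.PlumeConfig(
    dep_gsd=1.2,
    mesh_spacing_deg=0.04,
    west=140.4, south=37.0, east=141.3, north=37.9,
    seed=3,
)
truth = bd.generate_truth(config)
records = bd.sample_survey(truth)
detected = records["i131_kbq_m2"].notna().mean()
print(f"survey: {len(records)} locations, I-131 detected at {100 * detected:.0f}% "
      "(the rest were below the detection limit after ~3 months of decay)")

result = bd.run_pipeline(records)
print(f"pipeline: {result.counts['dosed']} locations dosed, "
      f"{result.counts['excluded']} excluded (no I-131 ratio), "
      f"{result.counts['r_t_interpolated']} Te ratios interpolated")

report = bd.recovery_report(truth, result.table)
print(f"dose recovery: median relative error "
      f"{100 * report['d_a']['median_rel_error']:.1f}%, "
      f"90th percentile {100 * report['d_a']['p90_rel_error']:.1f}%")
print("(errors reflect measurement noise on the activities; the noise-free,")
print(" uncensored configuration recovers every dose exactly)")
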