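"""DNA-damage focus kinetics after irradiation.

Simulates live 53BP1-reporter cells imaged at 0, 3, 9 and 20 h after a
4 Gy dose, counts puncta per cell with the background-relative detector,
and prints the detected time course against the generating rate law
(baseline before irradiation, then exponential repair decay).
"""

import gedikit as gk

cfg = gk.SimulationConfig(
    seed=5, n_cells=120, fov_shape=(900, 900), cell_radius_px=20,
    timepoints_h=(0.0, 3.0, 9.0, 20.0), radiation_dose_Gy=4.0,
    puncta_baseline_rate=1.0, puncta_induction_per_Gy=3.0,
    puncta_repair_halflife_h=4.0,
)

stack, truth = gk.simulate_foci_images(cfg, marker="red")
detected = gk.live_foci_counts(stack)
detected["group"] = "RS + 4 Gy"
course = gk.foci_time_course(detected)

print("detected 53BP1 puncta per cell (mean +/- SEM) vs generating rate:")
for _, row in course.iterrows():
    rate = cfg.puncta_rate(row["timepoint_h"])
    print(f"  t={row['timepoint_h']:4.0f} h: {row['mean_puncta']:5.2f} "
          f"+/- {row['sem']:.2f}  (rate law: {rate:5.2f}, "
          f"n={row['n_cells']} cells)")
print("\ncounts peak at the first post-irradiation frame and return to the"
      "\npre-irradiation baseline as double-strand breaks are repaired.")
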