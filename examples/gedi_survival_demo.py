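"""Single-cell death assay, end to end.

Simulates a four-arm experiment (control plus three sEV doses that scale
the radiation-driven death hazard down), calibrates the live/dead GEDI
ratio threshold from baseline and lethal-dose acquisitions, segments and
tracks every cell, classifies per-cell fates, and prints Kaplan-Meier
survival per arm with log-rank tests against the control arm.
"""

from dataclasses import replace

import numpy as np

import gedikit as gk

ARMS = {  # sEV dose -> hazard scaling (protection factor)
    "control (0 sEV/cell)": 1.0,
    "low (2500 sEV/cell)": 0.7,
    "medium (5000 sEV/cell)": 0.5,
    "high (15000 sEV/cell)": 0.4,
}

base = gk.SimulationConfig(
    n_cells=150, fov_shape=(768, 768),
    base_hazard_per_h=0.1, spontaneous_hazard_per_h=0.0,
)

print(f"irradiation: 8 Gy at 4.82 Gy/min -> "
      f"{gk.irradiation_duration(8.0):.2f} min exposure")

calib = gk.calibrate_from_simulation(base, n_cells=120, seed=99)
print(f"calibrated GEDI threshold: {calib.threshold:.3f} "
      f"(live median {calib.live_median:.3f}, dead median {calib.dead_median:.3f})")

records = []
for i, (label, pf) in enumerate(ARMS.items()):
    cfg = replace(base, seed=10 + i, group=label, protection_factor=pf)
    stack, truth = gk.simulate_timelapse(cfg)
    recs, _ = gk.analyze_timelapse(stack, calib, group=label)
    records.extend(recs)

df = gk.records_to_dataframe(records)
print("\nKaplan-Meier survival at 18 h post-irradiation:")
for label, pf in ARMS.items():
    km = gk.km_estimate(df, label)
    lam = base.base_hazard_per_h * pf
    print(f"  {label:24s} S(18h) = {km.survival_at(18.0):.3f} "
          f"(true exponential: {np.exp(-lam * 18):.3f})")

print("\nlog-rank vs control (protection should grow with dose):")
control = list(ARMS)[0]
print(gk.pairwise_logrank(df, control=control).to_string(index=False))
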