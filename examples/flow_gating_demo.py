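"""Flow-cytometry uptake gating against an unstained control.

Simulates labelled-vesicle uptake acquisitions for a high-uptake tumor
population (95% truly labelled) and a low-uptake progenitor population
(30%), places the positivity gate at the 99.5th percentile of a matched
unstained control, and prints the recovered percent-positive and MFI.
"""

import gedikit as gk

for name, fraction, seed in (
    ("tumor-like (high uptake)", 0.95, 11),
    ("progenitor-like (low uptake)", 0.30, 12),
):
    stained, truth = gk.simulate_flow_events(
        20_000, fraction, neg_mu=100.0, pos_mu=1000.0, sigma_log=0.3, seed=seed
    )
    unstained, _ = gk.simulate_flow_events(
        20_000, 0.0, neg_mu=100.0, pos_mu=1000.0, sigma_log=0.3, seed=seed + 50
    )
    res = gk.gate_flow_events(stained, unstained, percentile=99.5)
    print(f"{name}: gate at {res.gate_threshold:.0f} a.u. -> "
          f"{res.percent_positive:.1f}% positive "
          f"(simulated truth {100 * fraction:.0f}%), "
          f"MFI(positive)={res.mfi_positive:.0f}, MFI(all)={res.mfi_all:.0f}")

print("\nthe gate sits in the upper tail of the unstained distribution, so"
      "\n~0.5% of a purely negative sample would still fall above it.")
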