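"""Compare the adaptive pipeline with the fixed-attenuation baseline.

Both methods run on the same contaminated scans; the baseline uses one fixed
anchor, window and scattering factor, with no quality control or parameter
iteration. Across seeds, the adaptive estimates scatter less.
"""

import numpy as np

import specoct as sp

truth_so2 = 0.60
ads, fa = [], []
for seed in range(5):
    spec = sp.PhantomSpec(vessel=sp.VesselSpec(so2_true=truth_so2,
                                               diameter_um=70.0,
                                               anterior_depth_um=160.0),
                          n_bscans=8, n_alines=128, seed=seed)
    scan, truth = sp.simulate_scan(spec)
    ann = sp.default_annotation(spec, truth)
    for method, sink in (("ads", ads), ("fa", fa)):
        records, _, _ = sp.process_scan(scan, [ann], method=method)
        sink.append(records[0].so2_fraction if records else np.nan)

print(f"true sO2: {100 * truth_so2:.0f}%")
print("adaptive :", [f"{100 * v:.1f}" for v in ads],
      f" SD = {100 * np.nanstd(ads):.1f} pts")
print("fixed    :", [f"{100 * v:.1f}" for v in fa],
      f" SD = {100 * np.nanstd(fa):.1f} pts")
# The fixed baseline inherits every contaminant its fixed parameters cannot
# absorb; the adaptive method's iteration + filtering narrows the spread.
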