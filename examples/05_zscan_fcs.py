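"""z-scan FCS: calibration-free diffusion coefficient from the diffusion law.

Simulates a 20-step z-scan (150 nm spacing) with 5% dwell-time noise, fits
the diffusion-law parabola, and compares two probe populations with the
unequal-variance t-test (significance threshold p < 0.1).
"""

import numpy as np

import mcfret as m

series = m.make_zscan_series(5.0, waist_nm=250.0, noise=0.05, seed=3)
fit = m.zscan_diffusion_fit(series)
print(f"true D  : 5.00 um^2/s")
print(f"fitted D: {fit.diffusion_coefficient:.2f} um^2/s "
      f"(waist {fit.waist:.0f} nm, z0 {fit.z0:.0f} nm)")

# two GUV populations: homogeneous vs nanodomain-containing bilayers
rng = np.random.default_rng(9)
d_homog = 5.0 + 0.15 * rng.standard_normal(8)
d_domain = 4.5 + 0.15 * rng.standard_normal(8)  # probes slowed by domains
p, significant = m.compare_diffusion(d_homog, d_domain)
print(f"t-test p-value: {p:.4f} -> {'significant' if significant else 'not significant'}")
print("A significant slow-down of a domain-partitioning probe corroborates")
print("the nanodomains seen by FRET.")
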