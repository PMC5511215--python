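"""Simulate a donor decay for a bilayer with and without nanodomains.

Builds a ternary-mixture scene (R_D = 9 nm nanodomains covering 45% of the
bilayer, probes strongly enriched in the domains, K_D = 20), runs the
event-sampling Monte Carlo, and compares the FRET efficiency against the
homogeneous bilayer.  E_rel > 1 is the nanodomain signature: co-enrichment
of donors and acceptors speeds up the donor decay.
"""

import numpy as np

import mcfret as m

photo = m.default_photophysics()
kw = dict(n_events=100_000, reuse=100, window=50.0, bins=1024)

homog = m.simulate_survival(m.SceneSpec(area_fraction=0.0), photo, seed=1, **kw)
domains = m.simulate_survival(
    m.SceneSpec(domain_radius=9.0, area_fraction=0.45,
                partition=m.PartitionCoefficients(20.0, 20.0)),
    photo, seed=2, **kw)

t = homog.time
donor_only = m.DecayHistogram(t, m.intrinsic_intensity(t, photo) * 1e6)
e_homog = m.fret_efficiency(m.compose_decay(homog, photo), donor_only)
e_domain = m.fret_efficiency(m.compose_decay(domains, photo), donor_only)

print(f"FRET efficiency, homogeneous bilayer : {e_homog:.3f}")
print(f"FRET efficiency, with nanodomains    : {e_domain:.3f}")
print(f"relative efficiency E_rel            : {e_domain / e_homog:.3f}")
print("E_rel above 1 means the domains concentrate both probes and thus")
print("accelerate donor quenching relative to the homogeneous bilayer.")
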