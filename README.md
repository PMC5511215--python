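# mcfret

Monte Carlo FRET analysis of lipid-bilayer nanodomains.

Sphingomyelin/cholesterol-driven nanodomains in model membranes are too
small (~10 nm) for optical microscopy, but they reshape Förster resonance
energy transfer between membrane probes: when donors and acceptors
partition into (or out of) the domains, the donor fluorescence decay speeds
up or slows down in a way that encodes the domain radius R_D, the bilayer
area fraction Ar they cover, and the probe partition coefficients
K_D = [inside]/[outside]. `mcfret` is for membrane biophysicists who want
to run this MC-FRET analysis end to end on time-correlated single photon
counting (TCSPC) decays — and to validate every stage on synthetic data.

## The model in brief

An excited donor i surrounded by acceptors at distances r_ij is quenched
with total rate

    Ω_i = Σ_j (1/τ_D) (R0 / r_ij)⁶,

and each excitation event samples a transfer time Δt = −ln(γ)/Ω_i,
γ ~ U(0, 1]. Averaging over probe configurations in a periodic bilayer
patch with hard-disk nanodomains gives the FRET-only survival function
G(t); the observable decay is F(t) = I_intrinsic(t)·G(t). For a
homogeneous bilayer G(t) has the closed Baumann–Fayer form
G = exp(−c_A Σ_planes S_h(t)) with the in-plane law
−ln G = c_A π R0² Γ(2/3)(t/τ)^{1/3}, used to calibrate the acceptor surface
density c_A. The inverse problem scans a (R_D, Ar, K_D) grid in χ², with
local refinement and explicit reporting of all near-degenerate minima.
Fitted geometry converts to per-domain lipid counts, and a z-scan FCS
module extracts calibration-free diffusion coefficients from the
diffusion-law parabola τ(z) = (w0²/4D)[1 + (λ(z−z0)/(π w0² n))²].

## Worked example

```python
import mcfret as m

photo = m.default_photophysics()          # R0 5.7 nm, tau 5 ns, c_A 0.0069/nm^2
truth = m.SceneSpec(domain_radius=9.0, area_fraction=0.45,
                    partition=m.PartitionCoefficients(20.0, 20.0))

surv = m.simulate_ensemble_survival(truth, photo, window=50, bins=256, seed=5)
data = m.compose_decay(surv, photo, total_counts=1e6, poisson=True, seed=6)

result = m.grid_fit(data, photo, n_events=1600, n_donors=128, seed=7)
best = result.best
print(best["domain_radius"], best["area_fraction"], best["k_d"], round(best["chi2_red"], 2))
```

prints (this is `examples/03_grid_fit.py`, ~1 minute)

```
9.0 0.45 20.0 1.05
```

i.e. the fit recovers the 9 nm domain radius, the 45% area coverage and the
partition coefficient 20 that generated the decay, with a reduced
chi-square near 1 (the decay carries 10⁶ photons of Poisson noise); the
profile intervals span R_D 8-12 nm and Ar 0.45-0.50, the χ² valley the
decay shape genuinely constrains.
Feeding that geometry to the composition calculator,

```python
comp = m.BilayerComposition.ternary(0.65, 0.25, 0.10)
counts = m.domain_lipid_counts(9.0, 0.45, comp)
print(counts.rounded)        # {'DOPC': 230, 'Chol': 196, 'SM': 79}
print(m.domain_ratios(counts))  # DOPC:SM ≈ 2.9, Chol:SM = 2.5
```

shows a single nanodomain leaflet holds ≈ 230 DOPC, 196 cholesterol and 79
sphingomyelin molecules — DOPC outnumbers SM ~3:1, which is what keeps
these domains fluid and disordered.

The `examples/` directory has one short script per capability (forward
simulation, acceptor calibration, grid fitting, composition, z-scan FCS);
each prints its numbers with a line on what they mean. A thin CLI mirrors
the same stages: `mcfret simulate | bf-fit | fit | compose | fcs-fit |
synth`.

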