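# Methods

`mcfret` models Förster resonance energy transfer (FRET) between donor and
acceptor fluorophores embedded in a lipid bilayer that may contain circular
nanodomains, and inverts measured donor decays for the nanodomain radius
R_D, the bilayer area fraction Ar they cover, and the probe partition
coefficients K_D. This note records the model, its assumptions, the
numerical choices, and what the synthetic data do and do not emulate.

## Bilayer scene model

A scene is a periodic square box (side L, default 100 nm, always ≥ 10 R_D)
containing `round(Ar · L² / (π R_D²))` non-overlapping disks of radius R_D —
i.e. the domain number density is Ar/(π R_D²). Domains are registered
across the two leaflets: one 2D domain pattern, with the donor and acceptor
fluorophore planes separated by h = 4.0 nm (configurable; appropriate for
headgroup-labelled probes on opposite leaflets).

Disk packing uses random sequential adsorption (RSA) up to 42% coverage.
Above that — RSA jams near 54.7% and insertion becomes impractically slow —
disks start on a randomly vacated square lattice and are randomised by
Metropolis displacement sweeps (60 sweeps, step 0.3 R_D). The resulting
high-coverage configurations are valid hard-disk packings but retain more
positional order than an equilibrated fluid; at the coverages used here
(≤ 0.6) we observed no effect on the decays beyond the noise floor, because
the Förster kernel only probes the ~10 nm neighbourhood of each donor.

Probes land inside a domain with probability
`p_in = K_D·Ar / (K_D·Ar + 1 − Ar)`, which follows from the definition of
the partition coefficient K_D = [inside]/[outside] as a surface
concentration ratio, weighted by the available areas. Leaflet assignment is
a fair coin; positions are uniform in the domain union or its complement.

The per-leaflet acceptor count is Poisson with mean c_A L². The
grand-canonical draw makes the simulated patch an unbiased window into an
effectively infinite membrane: survival expectations become independent of
the box size and reduce exactly to the Baumann–Fayer law in the
homogeneous limit. (A fixed count with stochastic rounding would introduce
an O(c_A S²/L²) finite-size term that differs between boxes of different
size, which matters because grid nodes with large R_D require larger
boxes.)

## Forward Monte Carlo (event sampling)

An excited donor i transfers energy with total rate
Ω_i = Σ_j (1/τ)(R0/r_ij)⁶ summed over all acceptors (minimum-image
distances; cross-leaflet pairs use r = √(ρ² + h²); distances are clamped at
a 0.5 nm contact radius to avoid rate divergence). One excitation event
draws Δt = −ln(γ)/Ω_i with γ uniform in (0, 1]. Each scene hosts 100
events (donors picked uniformly at random) before a fresh scene is drawn;
the default run uses 3 × 10⁵ events. G(t) is the fraction of events with
Δt > t; events with Ω = 0 or Δt beyond the 100 ns observation window
(10 MHz repetition) are censored as "no transfer". Donor–donor transfer,
acceptor depletion and re-excitation are ignored: one excitation per event,
acceptors always available. κ² orientational averaging is absorbed into R0.

The measurable decay is F(t) = [Σ_m a_m e^(−t/τ_m)] · G(t) on 4096 bins by
default, optionally circularly convolved with a normalised instrument
response (off by default), scaled to the requested photon count and
Poisson-sampled. FRET efficiency is E = 1 − ∫F_DA/∫F_D with both decays
normalised to their first bin, and E_rel = E_hetero/E_homo.

Because each scene is reused for 100 events, the effective number of
independent samples for the scene-level noise component is
n_events/100, not n_events: an event-sampled decay at 3 × 10⁵ events
carries ≈ 0.3% coherent shape noise. This matters for the inverse problem
(below).

## Exact acceptor averaging (ensemble model)

For i.i.d. acceptors the expectation over acceptor positions and Poisson
counts factorises exactly:

    E[e^(−Ω t) | x, layout] = exp(−λ q(x, t)),

with λ the mean acceptor count and q the single-pair kernel average. q is
affine in I_p(x, t), the Förster kernel mass over the domain union for
plane p ∈ {in-plane, cross-leaflet}:

    I_p(x,t) = ∫_domains [1 − e^(−k_p(r) t)] dA.

I_p is assembled from a precomputed kernel–disk overlap table T(d, t)
(distance grid 0.25 nm, 256-point arc quadrature per entry, cached
process-wide per (R_D, h, R0, τ)); domains beyond R_D + 30 nm contribute
their average coverage through a far-field term, with an analytic r⁻⁶
remainder. The whole-plane mass S_h(t) uses a dense trapezoid grid in ρ²
(verified against the closed form π R0² Γ(2/3)(t/τ)^{1/3} to < 10⁻⁷
relative).

Only the domain layout and the donor positions remain Monte Carlo averaged.
Donors are sampled per stratum (inside/outside, combined with the exact
weight p_in) using low-discrepancy patterns — round-robin allocation over
the equal-area domains with golden-angle spirals inside, a jittered grid
outside — which removes the dominant donor-sampling variance. The
homogeneous bilayer is fully analytic: G = exp(−c_A (S_0 + S_h)), the
contact-clamped two-plane Baumann–Fayer law.

This estimator computes the same G(t) as event sampling (they agree within
Monte Carlo bounds in the tests) at roughly two orders of magnitude less
variance per CPU second, and because q is affine in I the entire K_D grid
axis reuses one set of per-donor kernel masses.

## Baumann–Fayer model and acceptor calibration

`bf_survival` evaluates G(t) = exp(−c_A Σ_planes S_h(t)) with

    S_h(t) = ∫₀^∞ [1 − exp(−(t/τ)(R0²/(ρ²+h²))³)] 2πρ dρ

by adaptive quadrature (substitution u = ρ², relative tolerance 10⁻⁸, split
at the characteristic scale). `fit_acceptor_density` fits the composed BF
decay to a homogeneous-bilayer measurement by weighted least squares
(Poisson weights max(counts, 1), analytic intensity scale); since the
exponent is linear in c_A the minimisation is one-dimensional, and the
confidence interval is the Δχ² = 1 profile. The calibrated c_A is then
held fixed in the nanodomain fits, mirroring the two-GUV-set protocol.

## Inverse problem

`grid_fit` scans R_D ∈ {2, 4, …, 20, 25, …, 50} nm, Ar ∈ {0, 0.05, …, 0.6},
K_D ∈ {1, 2, 5, 10, 20, 50} with K_D(D) = K_D(A), one ensemble-model decay
per node, common random numbers (identical scene seeds) across nodes, and
the reduced chi-square

    χ²_red = Σ (d_i − s·m_i)²/max(d_i, 1) / (n_bins − 4),

with s the analytic least-squares scale (experimental decays have arbitrary
normalisation). Nodes with Ar = 0 or K_D = 1 are physically identical to
the homogeneous bilayer and share one decay, so a homogeneous dataset
yields an exactly flat surface and is flagged "degenerate" (also triggered
when more than 25% of all nodes fall within the reporting band).

The χ² surface of a nanodomain decay is a narrow diagonal valley in
(R_D, Ar): increasing R_D while increasing Ar leaves the decay nearly
unchanged. Two consequences, both verified numerically:

- On the coarse default grid the valley floor can sit at a node several nm
  from the truth (e.g. truth (9 nm, 0.45) is matched slightly better by the
  node (12 nm, 0.50) than by (8 nm, 0.45) — confirmed independently with
  the event-sampling simulator). `grid_fit` therefore refines locally:
  every coarse node within 0.5 of the best χ²_red spans a second scan with
  R_D step 1 nm and Ar step 0.025, from which the reported minima and
  profile intervals are taken. With refinement the ternary test scenario is
  recovered at (9, 0.45, 20) in ≥ 90% of replicates.
- Distinct local minima within Δχ²_red = 0.05 of the best are all reported,
  ranked — the method's honest output for a degenerate valley is a solution
  set, as in the binary-mixture case which yields two minima
  ((8 nm, 37%) and (12 nm, 55%)).

Per-parameter uncertainty intervals are the spans of grid values whose
profile χ²_red lies within the same threshold; intervals touching a grid
edge are flagged unbounded.

## Synthetic data

Presets cover the study conditions: homogeneous binary (≤ 8 mol% SM) and
ternary (75/25/0) bilayers; binary nanodomains (R_D 8 or 12 nm, Ar 0.37 or
0.55, K_D 10); ternary nanodomains seen by the GM1 pair (9 nm, 0.45,
K_D 20) and by the PEG-DSPE pair (8 nm, 0.55, K_D 5). Probe loading is
1:200 acceptor-to-lipid, giving c_A = (1/200)/0.72 ≈ 0.0069 nm⁻² per
leaflet. R0 = 5.7 nm and a mono-exponential donor lifetime of 5.0 ns are
typical values for headgroup-BODIPY probes; neither is tabulated for these
dyes in the source study, so both are explicit, configurable defaults.
Default decay statistics are 10⁶ photons per decay.

Decay fixtures come in two flavours: the event-sampled forward model
(carries the ≈ 0.3% scene-level MC noise inherent to 3 × 10⁵ events with
100-fold configuration reuse) and the ensemble method, which emulates an
experimental decay — a FLIM measurement integrates photons over a
macroscopic membrane area, so its only noise is Poisson. Recovery
experiments use the ensemble flavour for the data and are therefore limited
by photon statistics, like the experiment. z-scan FCS fixtures are model
autocorrelations (2D free diffusion, no triplet term) with Gaussian noise —
the claims tested live at the fitted-parameter level, so photon-mode FCS
simulation is out of scope.

What passing tests show: the sampling scheme, the analytic models and the
inverse machinery are mutually consistent and recover known truths at
realistic photon counts. What they do not show: robustness to instrument
response mismatch, dye photophysics beyond a clean multi-exponential
(triplet states, photobleaching), non-circular or unregistered domains, or
acceptor self-quenching at high loading.

## Problem sizes

Default simulations use 3 × 10⁵ events (100 per scene). The grid fitter's
refinement budget is chosen so that the model-side Monte Carlo noise sits
below the Poisson noise of a 10⁶-count decay: 24 scenes × 160 donors per
stratum per node (`n_events = 2400` with `reuse = 100`); the coarse
bracketing pass runs lighter (16 scenes × 128 donors) since it only needs
to locate the valley to within one coarse node. The recovery test suite
runs 20 replicates at this budget. The composition calculator and the
z-scan fits are closed-form or sub-second least squares.
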