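"""Synthetic study fixtures: scenario presets, noisy decays, z-scan series.

The presets mirror the GUV study conditions: binary DOPC/SM bilayers that
are homogeneous below ~10 mol% SM and develop nanodomains of R_D ~ 8-12 nm
covering 37-55% of the bilayer at 10-15 mol% SM (probe partition
coefficient ~10), and ternary DOPC/Chol/SM bilayers with nanodomains of
R_D ~ 8-9 nm at 45-55% coverage seen with K_D >= 20 (GM1 probe pair) or
K_D ~ 5 (PEG-DSPE pair).  Acceptor surface density defaults to the 1:200
acceptor-to-lipid loading over a 0.72 nm^2 area per lipid, c_A ~ 0.0069
nm^-2 per leaflet.  Every generated fixture ships with a machine-readable
truth JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .composition import BilayerComposition
from .fcs import ZScanSeries, acf_2d, diffusion_law_tau, FcsCurve
from .fretmc import (
    DecayHistogram,
    Photophysics,
    SceneSpec,
    compose_decay,
    intrinsic_intensity,
    simulate_survival,
)
from .io import write_decay, write_fcs, write_zscan_series
from .membrane import PartitionCoefficients

__all__ = [
    "ScenarioPreset",
    "list_presets",
    "get_preset",
    "default_photophysics",
    "generate_decay_fixture",
    "make_zscan_series",
    "generate_fcs_fixture",
]

#: Defaults for the probe pairs: R0 and donor lifetime are not tabulated for
#: these dyes in the source study; typical headgroup-BODIPY values are used.
DEFAULT_R0 = 5.7  # nm
DEFAULT_TAU = 5.0  # ns
DEFAULT_CA = 1.0 / 200.0 / 0.72  # 1:200 acceptor:lipid over 0.72 nm^2 ~ 0.0069 nm^-2


def default_photophysics() -> Photophysics:
    return Photophysics(
        forster_radius=DEFAULT_R0,
        intrinsic_decay=((1.0, DEFAULT_TAU),),
        acceptor_density=DEFAULT_CA,
    )


@dataclass(frozen=True)
class ScenarioPreset:
    """One study scenario: composition, truth parameters, probe loadings."""

    label: str
    composition: tuple[tuple[str, float], ...]
    domain_radius: float  # nm; 0 for homogeneous
    area_fraction: float
    k_d_donor: float
    k_d_acceptor: float
    fret_pair: str
    donor_to_lipid: float = 1.0 / 200.0
    acceptor_to_lipid: float = 1.0 / 200.0
    forster_radius: float = DEFAULT_R0
    donor_lifetime: float = DEFAULT_TAU
    acceptor_density: float = DEFAULT_CA

    @property
    def homogeneous(self) -> bool:
        return self.area_fraction == 0.0

    def photophysics(self) -> Photophysics:
        return Photophysics(
            forster_radius=self.forster_radius,
            intrinsic_decay=((1.0, self.donor_lifetime),),
            acceptor_density=self.acceptor_density,
        )

    def scene(self, box_side: float = 100.0, n_donors: int = 100) -> SceneSpec:
        return SceneSpec(
            box_side=box_side,
            domain_radius=self.domain_radius if not self.homogeneous else 8.0,
            area_fraction=self.area_fraction,
            partition=PartitionCoefficients(self.k_d_donor, self.k_d_acceptor),
            n_donors=n_donors,
        )

    def truth(self) -> dict:
        return asdict(self)


_PRESETS: dict[str, ScenarioPreset] = {
    p.label: p
    for p in [
        ScenarioPreset(
            label="binary_homogeneous",
            composition=(("DOPC", 0.95), ("SM", 0.05)),
            domain_radius=0.0,
            area_fraction=0.0,
            k_d_donor=1.0,
            k_d_acceptor=1.0,
            fret_pair="g-GM1/r-GM1",
        ),
        ScenarioPreset(
            label="binary_nanodomain_37",
            composition=(("DOPC", 0.90), ("SM", 0.10)),
            domain_radius=8.0,
            area_fraction=0.37,
            k_d_donor=10.0,
            k_d_acceptor=10.0,
            fret_pair="g-GM1/r-GM1",
        ),
        ScenarioPreset(
            label="binary_nanodomain_55",
            composition=(("DOPC", 0.88), ("SM", 0.12)),
            domain_radius=12.0,
            area_fraction=0.55,
            k_d_donor=10.0,
            k_d_acceptor=10.0,
            fret_pair="g-GM1/r-GM1",
        ),
        ScenarioPreset(
            label="ternary_homogeneous",
            composition=(("DOPC", 0.75), ("Chol", 0.25), ("SM", 0.0)),
            domain_radius=0.0,
            area_fraction=0.0,
            k_d_donor=1.0,
            k_d_acceptor=1.0,
            fret_pair="g-GM1/r-GM1",
        ),
        ScenarioPreset(
            label="ternary_gm1",
            composition=(("DOPC", 0.65), ("Chol", 0.25), ("SM", 0.10)),
            domain_radius=9.0,
            area_fraction=0.45,
            k_d_donor=20.0,
            k_d_acceptor=20.0,
            fret_pair="g-GM1/r-GM1",
        ),
        ScenarioPreset(
            label="ternary_peg",
            composition=(("DOPC", 0.65), ("Chol", 0.25), ("SM", 0.10)),
            domain_radius=8.0,
            area_fraction=0.55,
            k_d_donor=5.0,
            k_d_acceptor=5.0,
            fret_pair="CF-PEG-DSPE/Rh-PEG-DSPE",
        ),
    ]
}


def list_presets() -> list[ScenarioPreset]:
    """Catalogue of the built-in scenario presets."""
    return list(_PRESETS.values())


def get_preset(label: str) -> ScenarioPreset:
    try:
        return _PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown preset {label!r}; available: {sorted(_PRESETS)}"
        ) from None


def preset_composition(preset: ScenarioPreset) -> BilayerComposition:
    return BilayerComposition(dict(preset.composition))


def generate_decay_fixture(
    preset: ScenarioPreset | str,
    outdir: str | Path,
    total_counts: float = 1e6,
    n_events: int = 300_000,
    reuse: int = 100,
    window: float = 100.0,
    bins: int = 4096,
    box_side: float = 100.0,
    seed: int = 0,
    method: str = "events",
) -> dict[str, Path]:
    """Write donor-only and donor+acceptor decay TSVs plus a truth JSON.

    The donor-only decay is the intrinsic model with Poisson noise; the DA
    decay runs the full forward model (scene sampling, event sampling,
    composition, Poisson noise).  ``method="ensemble"`` instead emulates an
    experimental decay — the ensemble-limit survival (acceptors averaged
    analytically over many scenes) carrying only Poisson noise, as a FLIM
    measurement integrating photons over a macroscopic membrane area would.
    Byte-identical for a fixed seed.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    photo = preset.photophysics()
    t = (np.arange(bins) + 0.5) * (window / bins)

    rng = np.random.default_rng(seed)
    donor_counts = intrinsic_intensity(t, photo)
    donor_counts = donor_counts * (total_counts / donor_counts.sum())
    donor = DecayHistogram(
        t,
        rng.poisson(donor_counts).astype(float),
        {"kind": "donor_only", "preset": preset.label, "seed": seed},
    )

    if method == "ensemble":
        from .fitting import simulate_ensemble_survival

        surv = simulate_ensemble_survival(
            preset.scene(box_side=box_side), photo,
            window=window, bins=bins, seed=seed + 1,
        )
    else:
        surv = simulate_survival(
            preset.scene(box_side=box_side),
            photo,
            n_events=n_events,
            reuse=reuse,
            window=window,
            bins=bins,
            seed=seed + 1,
            method=method,
        )
    da = compose_decay(surv, photo, total_counts=total_counts, poisson=True, seed=seed + 2)
    da.meta.update({"kind": "donor_acceptor", "preset": preset.label})

    paths = {
        "donor": outdir / "donor.tsv",
        "donor_acceptor": outdir / "donor_acceptor.tsv",
        "truth": outdir / "truth.json",
    }
    write_decay(paths["donor"], donor)
    write_decay(paths["donor_acceptor"], da)
    truth = preset.truth()
    truth.update(
        {
            "seed": seed,
            "total_counts": total_counts,
            "n_events": n_events,
            "reuse": reuse,
            "window_ns": window,
            "bins": bins,
            "box_side_nm": box_side,
            "method": method,
        }
    )
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def make_zscan_series(
    d_um2_s: float,
    waist_nm: float = 250.0,
    z0_nm: float = 0.0,
    n_z: int = 20,
    step_nm: float = 150.0,
    noise: float = 0.0,
    n_particles_at_waist: float = 5.0,
    seed: int = 0,
) -> ZScanSeries:
    """Synthetic dwell-time series on the standard z-scan raster.

    The raster starts 1.5 um below the nominal waist and climbs in
    ``step_nm`` steps; ``noise`` is the relative Gaussian scatter on the
    dwell times (the particle numbers get the same relative noise).
    """
    rng = np.random.default_rng(seed)
    z = -1500.0 + step_nm * np.arange(n_z)
    tau = diffusion_law_tau(z, d_um2_s, waist_nm, z0_nm)
    n_part = n_particles_at_waist * (tau / tau.min())
    if noise > 0:
        tau = tau * (1.0 + noise * rng.standard_normal(n_z))
        n_part = n_part * (1.0 + noise * rng.standard_normal(n_z))
    return ZScanSeries(z=z, tau_diff=np.abs(tau), n_particles=np.abs(n_part))


def generate_fcs_fixture(
    d_um2_s: float,
    outdir: str | Path,
    waist_nm: float = 250.0,
    z0_nm: float = 0.0,
    n_z: int = 20,
    step_nm: float = 150.0,
    noise: float = 0.05,
    n_particles_at_waist: float = 5.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write per-z autocorrelation TSVs, the dwell-time series and truth JSON."""
    if n_z < 5:
        raise ValueError("a z-scan needs at least 5 steps")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    series = make_zscan_series(
        d_um2_s, waist_nm, z0_nm, n_z, step_nm, noise=noise,
        n_particles_at_waist=n_particles_at_waist, seed=seed,
    )
    lags = np.logspace(-6, 0, 160)
    paths: dict[str, Path] = {}
    for i, (z, tau, n_part) in enumerate(
        zip(series.z, series.tau_diff, series.n_particles)
    ):
        g = acf_2d(lags, n_part, tau)
        if noise > 0:
            g = g * (1.0 + 0.2 * noise * rng.standard_normal(len(lags)))
        curve = FcsCurve(lags, g, z_offset=float(z))
        p = outdir / f"acf_z{i:02d}.tsv"
        write_fcs(p, curve)
        paths[f"acf_z{i:02d}"] = p
    paths["series"] = outdir / "series.tsv"
    write_zscan_series(paths["series"], series)
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(
        json.dumps(
            {
                "diffusion_um2_s": d_um2_s,
                "waist_nm": waist_nm,
                "z0_nm": z0_nm,
                "n_z": n_z,
                "step_nm": step_nm,
                "noise": noise,
                "seed": seed,
            },
            indent=2,
        )
    )
    return paths
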