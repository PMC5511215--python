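"""Inverse problem: recover (R_D, Ar, K_D) from a measured donor decay.

The fitter scans a 3D grid of physically acceptable parameters — domain
radius R_D (2-50 nm), area fraction Ar (0-0.6) and the common partition
coefficient K_D(D) = K_D(A) — simulating one model decay per node and
ranking all near-degenerate chi-square minima.  The acceptor surface
density is not fitted here; it is calibrated beforehand on a
homogeneous-bilayer decay (see :mod:`mcfret.bf`) exactly as in the
two-GUV-set protocol.

Monte Carlo noise is tamed three ways: the acceptor ensemble is averaged
analytically per configuration (see :mod:`mcfret._model`), donors are
sampled with stratified low-discrepancy patterns, and all grid nodes share
common random numbers (identical scene seeds), so chi-square differences
between nodes reflect the parameters, not the noise.  Nodes with K_D = 1 or
Ar = 0 are physically identical to the homogeneous bilayer and share a
single analytic decay, which renders the chi-square surface exactly flat
there and makes degeneracy detection exact.  A light coarse scan brackets
the narrow diagonal (R_D, Ar) chi-square valley; the full simulation budget
is then spent on a local fine scan that produces the reported estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._model import (
    _accumulate_node_survival,
    homogeneous_survival,
    kernel_table,
    plane_mass,
)
from .fretmc import DecayHistogram, Photophysics, SurvivalCurve, compose_decay
from .membrane import partition_probability, place_domains

__all__ = ["FitResult", "chi_squared", "grid_fit", "profile_uncertainty", "default_grids"]

PARAM_NAMES = ("domain_radius", "area_fraction", "k_d")


def default_grids() -> dict[str, np.ndarray]:
    """Default scan grids: R_D 2-20 nm in 2 nm steps then 25-50 in 5 nm steps;
    Ar 0-0.6 in 0.05 steps; K_D in {1, 2, 5, 10, 20, 50}."""
    return {
        "domain_radius": np.array(
            [2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 25, 30, 35, 40, 45, 50], dtype=float
        ),
        "area_fraction": np.round(np.arange(0.0, 0.6001, 0.05), 2),
        "k_d": np.array([1, 2, 5, 10, 20, 50], dtype=float),
    }


def chi_squared(
    model: DecayHistogram, data: DecayHistogram, n_params: int = 1
) -> tuple[float, float]:
    """Reduced chi-square between a model and a measured decay.

    Uses Poisson weights w_i = max(data_i, 1) and absorbs the arbitrary
    experimental intensity normalisation into an analytic least-squares
    scale factor s.  Returns (chi2_red, s).
    """
    if model.time.shape != data.time.shape or not np.allclose(model.time, data.time):
        raise ValueError("model and data must share identical binning")
    d = data.counts
    m = model.counts
    if d.sum() <= 0:
        raise ValueError("data decay contains no counts")
    w = np.maximum(d, 1.0)
    s = float((d * m / w).sum() / (m**2 / w).sum())
    chi2 = float(((d - s * m) ** 2 / w).sum())
    dof = max(len(d) - n_params, 1)
    return chi2 / dof, s


@dataclass
class FitResult:
    """Chi-square surface over (R_D, Ar, K_D) with ranked local minima."""

    axes: dict[str, np.ndarray]
    chi2: np.ndarray  # shape (n_RD, n_Ar, n_KD), reduced chi-square
    minima: list[dict] = field(default_factory=list)
    intervals: dict[str, dict] = field(default_factory=dict)
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    refined: dict | None = None  # local fine-grid surface, when computed

    @property
    def best(self) -> dict:
        return self.minima[0]

    def to_dict(self) -> dict:
        return {
            "axes": {k: v.tolist() for k, v in self.axes.items()},
            "chi2": self.chi2.tolist(),
            "minima": self.minima,
            "intervals": self.intervals,
            "degenerate": self.degenerate,
            "warnings": self.warnings,
            "settings": self.settings,
            "refined": self.refined,
        }


def _scene_seeds(seed: int, n_scenes: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n_scenes)


_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _stratified_inside(layout, n: int, rng: np.random.Generator) -> np.ndarray:
    """Low-discrepancy donor positions in the domain union.

    Domains have equal area, so donors are allocated round-robin across
    domains; within each domain a golden-angle spiral with per-domain random
    rotation and stratified radii keeps the sample unbiased while cutting
    the variance of area averages well below i.i.d. sampling.
    """
    n_dom = layout.n_domains
    counts = np.full(n_dom, n // n_dom)
    extra = rng.permutation(n_dom)[: n % n_dom]
    counts[extra] += 1
    pts = np.empty((n, 2))
    pos = 0
    for d in range(n_dom):
        m = counts[d]
        if m == 0:
            continue
        k = np.arange(m)
        r = layout.domain_radius * np.sqrt((k + rng.random(m)) / m)
        theta = _GOLDEN_ANGLE * k + 2 * np.pi * rng.random()
        pts[pos : pos + m] = layout.centers[d] + np.column_stack(
            [r * np.cos(theta), r * np.sin(theta)]
        )
        pos += m
    return pts % layout.box_side


def _stratified_outside(layout, n: int, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid donor positions in the complement of the domain union."""
    frac_out = max(1.0 - layout.achieved_area_fraction, 1e-6)
    g = int(np.ceil(np.sqrt(n / frac_out)))
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    pts = (
        np.column_stack([i.ravel(), j.ravel()]) + rng.random((g * g, 2))
    ) * (layout.box_side / g)
    pts = pts[~layout.contains(pts)]
    if len(pts) < max(n // 2, 8):  # fall back, should not trigger for Ar <= 0.6
        raise RuntimeError("stratified outside sampling failed")
    return pts


def _node_pair_survivals(
    layouts: list,
    probe_seeds: list[np.random.SeedSequence],
    k_values: np.ndarray,
    photo: Photophysics,
    leaflet_separation: float,
    n_donors: int,
    t: np.ndarray,
    s_total: np.ndarray,
) -> np.ndarray:
    """Survival G_K(t) for every K_D at one (R_D, Ar) grid pair.

    The acceptor average is exact (Poisson thinning of the Förster kernel
    over the domain union); donors are Monte Carlo sampled per stratum
    (inside/outside) and reweighted with the exact inside probability for
    each K_D, so the whole K_D axis reuses one set of donor kernel masses.
    """
    r_d = layouts[0].domain_radius
    h = leaflet_separation
    d_grid, t0_table, far0 = kernel_table(
        r_d, 0.0, photo.forster_radius, photo.mean_lifetime, photo.contact_radius, t
    )
    _, th_table, farh = kernel_table(
        r_d, h, photo.forster_radius, photo.mean_lifetime, photo.contact_radius, t
    )
    d_step = float(d_grid[1] - d_grid[0])
    far_mass = far0 + farh
    g = np.zeros((len(k_values), len(t)))
    for layout, ss in zip(layouts, probe_seeds):
        rng = np.random.default_rng(ss)
        ar_s = layout.achieved_area_fraction
        donors_in = _stratified_inside(layout, n_donors, rng)
        donors_out = _stratified_outside(layout, n_donors, rng)
        p_in = np.array([partition_probability(k, ar_s) for k in k_values])
        alpha = p_in / ar_s - (1.0 - p_in) / (1.0 - ar_s)
        beta = (1.0 - p_in) / (1.0 - ar_s)
        a_coef = photo.acceptor_density * alpha
        b_coef = photo.acceptor_density * beta
        acc_in = np.zeros_like(g)
        acc_out = np.zeros_like(g)
        for donors, acc in ((donors_in, acc_in), (donors_out, acc_out)):
            _accumulate_node_survival(
                donors, layout.centers, layout.box_side, d_step,
                t0_table, th_table, far_mass, ar_s, s_total,
                a_coef, b_coef, acc,
            )
        g += (
            p_in[:, None] * acc_in / len(donors_in)
            + (1.0 - p_in)[:, None] * acc_out / len(donors_out)
        )
    return g / len(layouts)


def simulate_ensemble_survival(
    scene,
    photo: Photophysics,
    n_scenes: int = 96,
    n_donors: int = 256,
    window: float = 100.0,
    bins: int = 4096,
    seed: int = 0,
) -> SurvivalCurve:
    """Ensemble-limit survival G(t): acceptors averaged analytically.

    Emulates the decay a FLIM measurement integrates over a macroscopic
    membrane area: the acceptor ensemble is integrated out exactly (Poisson
    thinning of the Förster kernel) and only the domain geometry and the
    donor positions are Monte Carlo averaged, so the residual noise is far
    below the event-sampling scheme at equal cost.  The homogeneous case
    (Ar = 0 or K_D = 1) is fully analytic.
    """
    t = (np.arange(bins) + 0.5) * (window / bins)
    k_d = scene.partition.donor
    if scene.partition.acceptor != k_d:
        raise ValueError("ensemble survival assumes K_D(D) = K_D(A)")
    if scene.area_fraction == 0.0 or k_d == 1.0:
        g = homogeneous_survival(
            t, photo.forster_radius, photo.mean_lifetime, photo.contact_radius,
            photo.acceptor_density, scene.leaflet_separation,
        )
        return SurvivalCurve(t, g, {"seed": seed, "method": "ensemble"})
    s_total = plane_mass(
        t, photo.forster_radius, photo.mean_lifetime, 0.0, photo.contact_radius
    ) + plane_mass(
        t, photo.forster_radius, photo.mean_lifetime, scene.leaflet_separation,
        photo.contact_radius,
    )
    layout_seeds = _scene_seeds(seed, n_scenes)
    probe_seeds = np.random.SeedSequence((seed, 1)).spawn(n_scenes)
    layouts = [
        place_domains(
            max(scene.box_side, 10.0 * scene.domain_radius),
            scene.domain_radius,
            scene.area_fraction,
            seed=int(ss.generate_state(1)[0] & 0x7FFFFFFF),
        )
        for ss in layout_seeds
    ]
    g = _node_pair_survivals(
        layouts, probe_seeds, np.array([k_d]), photo,
        scene.leaflet_separation, n_donors, t, s_total,
    )[0]
    g = np.minimum.accumulate(np.clip(g, 0.0, 1.0))
    return SurvivalCurve(t, g, {"seed": seed, "method": "ensemble", "n_scenes": n_scenes})


def grid_fit(
    data: DecayHistogram,
    photo: Photophysics,
    grids: dict | None = None,
    box_side: float = 100.0,
    leaflet_separation: float = 4.0,
    n_donors: int = 160,
    n_events: int = 2400,
    reuse: int = 100,
    seed: int = 0,
    delta_chi2: float = 0.05,
    refine: bool = True,
    refine_band: float = 0.5,
    coarse_n_events: int = 1600,
    coarse_n_donors: int = 128,
) -> FitResult:
    """Scan the (R_D, Ar, K_D) grid and report all near-degenerate minima.

    One model decay is simulated per grid node (K_D(D) kept identical to
    K_D(A)); ``ceil(n_events/reuse)`` scenes per node with common random
    numbers across nodes.  Because the chi-square surface forms a narrow
    diagonal valley in (R_D, Ar), the coarse scan is followed (``refine``)
    by a local grid refinement — R_D step 1 nm, Ar step 0.025 — spanning
    every coarse node within ``refine_band`` of the minimum, so the
    reported estimate is not limited to the coarse-grid spacing.  Minima
    within ``delta_chi2`` of the best reduced chi-square are reported, and
    a flat/degenerate surface (homogeneous data) is flagged explicitly.
    """
    grids = {**default_grids(), **(grids or {})}
    r_ax = np.asarray(grids["domain_radius"], dtype=float)
    a_ax = np.asarray(grids["area_fraction"], dtype=float)
    k_ax = np.asarray(grids["k_d"], dtype=float)
    if r_ax.min() < 2 or r_ax.max() > 50:
        raise ValueError("R_D grid must lie within 2-50 nm")
    if a_ax.min() < 0 or a_ax.max() > 0.6:
        raise ValueError("Ar grid must lie within 0-0.6")

    t = data.time
    n_scenes = math.ceil(n_events / reuse)
    coarse_scenes = min(n_scenes, math.ceil(coarse_n_events / reuse))
    coarse_donors = min(n_donors, coarse_n_donors)
    layout_seeds = _scene_seeds(seed, n_scenes)
    probe_seeds = np.random.SeedSequence((seed, 1)).spawn(n_scenes)
    s_total = plane_mass(
        t, photo.forster_radius, photo.mean_lifetime, 0.0, photo.contact_radius
    ) + plane_mass(
        t, photo.forster_radius, photo.mean_lifetime, leaflet_separation,
        photo.contact_radius,
    )

    def node_decay(g: np.ndarray) -> DecayHistogram:
        surv = SurvivalCurve(t, np.minimum.accumulate(np.clip(g, 0.0, 1.0)))
        return compose_decay(surv, photo, total_counts=data.total())

    # the homogeneous bilayer: shared by every K_D = 1 and Ar = 0 node
    g_homog = homogeneous_survival(
        t, photo.forster_radius, photo.mean_lifetime, photo.contact_radius,
        photo.acceptor_density, leaflet_separation,
    )
    chi2_homog, s_homog = chi_squared(node_decay(g_homog), data, n_params=4)

    def scan(r_axis, a_axis, k_axis, scenes, donors):
        chi2 = np.empty((len(r_axis), len(a_axis), len(k_axis)))
        scales = np.empty_like(chi2)
        nontrivial_k = k_axis != 1.0
        for ir, r_d in enumerate(r_axis):
            node_box = max(box_side, 10.0 * r_d)  # finite-size guard
            for ia, ar in enumerate(a_axis):
                chi2[ir, ia, ~nontrivial_k] = chi2_homog
                scales[ir, ia, ~nontrivial_k] = s_homog
                if ar == 0.0:
                    chi2[ir, ia, :] = chi2_homog
                    scales[ir, ia, :] = s_homog
                    continue
                layouts = [
                    place_domains(
                        node_box, r_d, ar,
                        seed=int(ss.generate_state(1)[0] & 0x7FFFFFFF),
                    )
                    for ss in layout_seeds[:scenes]
                ]
                g_all = _node_pair_survivals(
                    layouts, probe_seeds[:scenes], k_axis[nontrivial_k], photo,
                    leaflet_separation, donors, t, s_total,
                )
                for g, ik in zip(g_all, np.flatnonzero(nontrivial_k)):
                    chi2[ir, ia, ik], scales[ir, ia, ik] = chi_squared(
                        node_decay(g), data, n_params=4
                    )
        return chi2, scales

    # the coarse pass only needs to bracket the chi-square valley; the full
    # budget is spent on the local refinement that produces the estimate
    chi2, scales = scan(r_ax, a_ax, k_ax, coarse_scenes, coarse_donors)
    axes = {"domain_radius": r_ax, "area_fraction": a_ax, "k_d": k_ax}
    result = FitResult(
        axes=axes,
        chi2=chi2,
        settings={
            "seed": seed,
            "n_events": n_events,
            "reuse": reuse,
            "n_scenes": n_scenes,
            "n_donors": n_donors,
            "box_side": box_side,
            "leaflet_separation": leaflet_separation,
            "acceptor_density": photo.acceptor_density,
            "delta_chi2": delta_chi2,
            "refine": refine,
            "refine_band": refine_band,
        },
    )
    result.minima = _grid_minima(axes, chi2, scales, delta_chi2)
    _assess_degeneracy(result, delta_chi2)

    if refine and not result.degenerate:
        ref_axes = _refinement_axes(axes, chi2, refine_band)
        if ref_axes is not None:
            chi2_r, scales_r = scan(*ref_axes.values(), n_scenes, n_donors)
            result.refined = {
                "axes": {k: v.tolist() for k, v in ref_axes.items()},
                "chi2": chi2_r.tolist(),
            }
            result.minima = _grid_minima(ref_axes, chi2_r, scales_r, delta_chi2)
            result.intervals = _profile_from(ref_axes, chi2_r, delta_chi2)
    if not result.intervals:
        result.intervals = _profile_from(axes, chi2, delta_chi2)
    top = result.minima[0]
    for name in PARAM_NAMES:
        ax = axes[name]
        if not result.degenerate and (top[name] <= ax[0] or top[name] >= ax[-1]):
            result.warnings.append(f"best {name} lies on the grid edge")
    return result


def _refinement_axes(axes, chi2, band: float) -> dict[str, np.ndarray] | None:
    """Local fine axes spanning every coarse node within `band` of the best."""
    best = float(chi2.min())
    idx = np.argwhere(chi2 <= best + band)
    if not len(idx):
        return None
    r_ax, a_ax, k_ax = axes["domain_radius"], axes["area_fraction"], axes["k_d"]
    ir_lo, ia_lo, ik_lo = idx.min(axis=0)
    ir_hi, ia_hi, ik_hi = idx.max(axis=0)
    # pad by one coarse node, clamp to physical bounds, cap the grid size
    r_lo = r_ax[max(ir_lo - 1, 0)]
    r_hi = r_ax[min(ir_hi + 1, len(r_ax) - 1)]
    r_fine = np.arange(max(r_lo, 2.0), min(r_hi, 50.0) + 1e-9, 1.0)
    a_lo = a_ax[max(ia_lo - 1, 0)]
    a_hi = a_ax[min(ia_hi + 1, len(a_ax) - 1)]
    a_fine = np.round(np.arange(max(a_lo, 0.025), min(a_hi, 0.6) + 1e-9, 0.025), 3)
    k_fine = np.unique(k_ax[max(ik_lo - 1, 0): min(ik_hi + 1, len(k_ax) - 1) + 1])
    if len(r_fine) > 17:  # keep the refinement bounded around the best node
        best_r = r_ax[np.unravel_index(np.argmin(chi2), chi2.shape)[0]]
        r_fine = r_fine[np.argsort(np.abs(r_fine - best_r))[:17]]
        r_fine.sort()
    if len(a_fine) > 15:
        best_a = a_ax[np.unravel_index(np.argmin(chi2), chi2.shape)[1]]
        a_fine = a_fine[np.argsort(np.abs(a_fine - best_a))[:15]]
        a_fine.sort()
    return {"domain_radius": r_fine, "area_fraction": a_fine, "k_d": k_fine}


def _grid_minima(
    axes: dict[str, np.ndarray],
    chi2: np.ndarray,
    scales: np.ndarray,
    delta_chi2: float,
) -> list[dict]:
    """Ranked local minima within delta_chi2 of the best reduced chi-square."""
    best = float(chi2.min())
    shape = chi2.shape
    minima = []
    for idx in np.argwhere(chi2 <= best + delta_chi2):
        val = chi2[tuple(idx)]
        is_min = True
        for axis, i in enumerate(idx):
            for step in (-1, 1):
                j = i + step
                if 0 <= j < shape[axis]:
                    nb = list(idx)
                    nb[axis] = j
                    if chi2[tuple(nb)] < val:
                        is_min = False
        if is_min:
            minima.append(
                {
                    "domain_radius": float(axes["domain_radius"][idx[0]]),
                    "area_fraction": float(axes["area_fraction"][idx[1]]),
                    "k_d": float(axes["k_d"][idx[2]]),
                    "chi2_red": float(val),
                    "scale": float(scales[tuple(idx)]),
                }
            )
    minima.sort(key=lambda m: m["chi2_red"])
    # collapse the exactly-tied homogeneous plateau to a single entry
    seen: list[dict] = []
    for m in minima:
        if any(abs(m["chi2_red"] - s["chi2_red"]) < 1e-12 for s in seen):
            continue
        seen.append(m)
    return seen[:20]


def _assess_degeneracy(result: FitResult, delta_chi2: float) -> None:
    chi2 = result.chi2
    best = float(chi2.min())
    frac_flat = float((chi2 <= best + delta_chi2).mean())
    top = result.minima[0]
    best_is_homog = top["area_fraction"] == 0.0 or top["k_d"] == 1.0
    if best_is_homog or frac_flat > 0.25:
        result.degenerate = True
        result.warnings.append(
            "homogeneous/degenerate: chi-square surface is flat across "
            "(R_D, Ar) — the data carry no nanodomain signature"
        )


def _profile_from(
    axes: dict[str, np.ndarray], chi2: np.ndarray, delta_chi2: float
) -> dict[str, dict]:
    out: dict[str, dict] = {}
    best = float(chi2.min())
    for axis, name in enumerate(PARAM_NAMES):
        other = tuple(i for i in range(3) if i != axis)
        prof = chi2.min(axis=other)
        ax = np.asarray(axes[name])
        sel = ax[prof <= best + delta_chi2]
        lo, hi = float(sel.min()), float(sel.max())
        out[name] = {
            "low": lo,
            "high": hi,
            "unbounded": bool(lo == ax[0] or hi == ax[-1]),
        }
    return out


def profile_uncertainty(result: FitResult, delta_chi2: float = 0.05) -> dict[str, dict]:
    """Per-parameter interval: span of grid values with chi2_red <= min + delta.

    The profile minimises over the other two axes (on the refined surface
    when one exists).  Intervals touching the grid edge are flagged
    "unbounded"; a zero threshold collapses each interval to the point
    estimate.
    """
    if result.refined is not None:
        axes = {k: np.asarray(v) for k, v in result.refined["axes"].items()}
        return _profile_from(axes, np.asarray(result.refined["chi2"]), delta_chi2)
    return _profile_from(result.axes, result.chi2, delta_chi2)
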