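"""Monte Carlo simulation of donor de-excitation by Förster transfer.

An excited donor i surrounded by acceptors at distances r_ij transfers energy
with total rate

    Omega_i = sum_j (1/tau) * (R0 / r_ij)**6

where tau is the (amplitude-weighted mean) intrinsic donor lifetime and R0
the Förster radius.  The FRET-only survival time of one excitation event is
sampled as dt = -ln(gamma) / Omega_i with gamma uniform in (0, 1].  Averaging
the indicator dt > t over many events and scene configurations yields the
total survival probability function G(t); the measurable donor decay is the
intrinsic multi-exponential decay multiplied by G(t).

Each scene configuration (domain layout + probe placement) is reused for a
fixed number of excitation events before a fresh configuration is drawn;
defaults are 3e5 total events with 100 events per configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .membrane import (
    DomainLayout,
    PartitionCoefficients,
    ProbeField,
    place_domains,
    place_probes,
)

__all__ = [
    "Photophysics",
    "SceneSpec",
    "SurvivalCurve",
    "DecayHistogram",
    "pairwise_rate",
    "donor_total_rate",
    "sample_transfer_time",
    "simulate_survival",
    "compose_decay",
    "intrinsic_intensity",
    "fret_efficiency",
    "relative_efficiency",
]


@dataclass(frozen=True)
class Photophysics:
    """Donor/acceptor photophysics: Förster radius, intrinsic decay, density.

    Parameters
    ----------
    forster_radius : Förster radius R0 in nm.
    intrinsic_decay : tuple of (amplitude, lifetime_ns) pairs; amplitudes are
        normalised to sum to 1.
    acceptor_density : acceptor surface density c_A in nm^-2, per leaflet.
    contact_radius : minimum donor-acceptor approach distance in nm; pair
        distances below it are clamped to avoid rate divergence.
    """

    forster_radius: float
    intrinsic_decay: tuple[tuple[float, float], ...] = ((1.0, 5.0),)
    acceptor_density: float = 0.0069
    contact_radius: float = 0.5

    def __post_init__(self) -> None:
        if self.forster_radius <= 0:
            raise ValueError("R0 must be positive")
        if self.acceptor_density < 0:
            raise ValueError("acceptor density must be non-negative")
        amps = np.array([a for a, _ in self.intrinsic_decay], dtype=float)
        taus = np.array([t for _, t in self.intrinsic_decay], dtype=float)
        if np.any(taus <= 0) or np.any(amps < 0) or amps.sum() <= 0:
            raise ValueError("invalid intrinsic decay components")
        object.__setattr__(
            self,
            "intrinsic_decay",
            tuple((a / amps.sum(), t) for a, t in zip(amps, taus)),
        )

    @property
    def mean_lifetime(self) -> float:
        """Amplitude-weighted mean intrinsic lifetime (ns)."""
        return sum(a * t for a, t in self.intrinsic_decay)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one bilayer scene fed to the simulator."""

    box_side: float = 100.0
    domain_radius: float = 8.0
    area_fraction: float = 0.0
    partition: PartitionCoefficients = PartitionCoefficients()
    leaflet_separation: float = 4.0
    n_donors: int = 100


@dataclass
class SurvivalCurve:
    """FRET-only survival probability G(t) on a uniform time grid (ns)."""

    time: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise ValueError("time and value grids differ in shape")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("survival curve must be non-increasing")


@dataclass
class DecayHistogram:
    """TCSPC-style decay: uniform time bins (ns) and photon counts/intensity."""

    time: np.ndarray  # bin centres, ns
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.counts.shape:
            raise ValueError("time and counts must be 1D arrays of equal length")
        if len(self.time) >= 2:
            widths = np.diff(self.time)
            if not np.allclose(widths, widths[0], rtol=1e-6, atol=1e-9):
                raise ValueError("bin width must be constant")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def total(self) -> float:
        return float(self.counts.sum())


def pairwise_rate(r, photo: Photophysics):
    """Förster transfer rate k = (1/tau_mean) (R0/r)^6 in ns^-1 (r in nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    k = (photo.forster_radius / r) ** 6 / photo.mean_lifetime
    return k if k.ndim else float(k)


def _all_donor_rates(probes: ProbeField, photo: Photophysics) -> np.ndarray:
    """Total transfer rate Omega_i for every donor in the field (ns^-1)."""
    if probes.n_acceptors == 0:
        return np.zeros(probes.n_donors)
    box = probes.box_side
    d = probes.donor_xy[:, None, :] - probes.acceptor_xy[None, :, :]
    d -= box * np.round(d / box)
    rho2 = (d**2).sum(-1)
    cross = probes.donor_leaflet[:, None] != probes.acceptor_leaflet[None, :]
    r2 = rho2 + np.where(cross, probes.leaflet_separation**2, 0.0)
    r2 = np.maximum(r2, photo.contact_radius**2)
    return ((photo.forster_radius**2 / r2) ** 3).sum(axis=1) / photo.mean_lifetime


def donor_total_rate(donor_index: int, probes: ProbeField, photo: Photophysics) -> float:
    """Omega_i: summed Förster rate from donor i to every acceptor.

    Distances use the minimum-image convention; cross-leaflet pairs use
    r = sqrt(rho^2 + h^2).  An empty acceptor set gives Omega = 0.
    """
    return float(_all_donor_rates(probes, photo)[donor_index])


def sample_transfer_time(omega, gamma):
    """Transfer time dt = -ln(gamma)/Omega (ns); Omega = 0 maps to +inf."""
    omega = np.asarray(omega, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0) or np.any(gamma > 1):
        raise ValueError("gamma must lie in (0, 1]")
    with np.errstate(divide="ignore"):
        dt = np.where(omega > 0, -np.log(gamma) / np.where(omega > 0, omega, 1.0), np.inf)
    return dt if dt.ndim else float(dt)


def _acceptor_count(photo: Photophysics, box_side: float, rng: np.random.Generator) -> int:
    """Per-leaflet acceptor count, Poisson with mean c_A * box^2.

    The grand-canonical draw makes the simulated patch an unbiased window
    into an effectively infinite membrane: survival expectations become
    independent of the box size and reduce exactly to the Baumann-Fayer
    form in the homogeneous limit.
    """
    return int(rng.poisson(photo.acceptor_density * box_side**2))


def _build_scene(
    spec: SceneSpec, photo: Photophysics, rng: np.random.Generator
) -> ProbeField:
    layout = place_domains(
        spec.box_side,
        spec.domain_radius,
        spec.area_fraction,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    n_acc = _acceptor_count(photo, spec.box_side, rng) + _acceptor_count(
        photo, spec.box_side, rng
    )  # two leaflets
    probes = place_probes(
        layout,
        n_donors=spec.n_donors,
        n_acceptors=max(n_acc, 1),
        partition=spec.partition,
        leaflet_separation=spec.leaflet_separation,
        rng=rng,
    )
    return probes


def simulate_survival(
    scene: SceneSpec,
    photo: Photophysics,
    n_events: int = 300_000,
    reuse: int = 100,
    window: float = 100.0,
    bins: int = 4096,
    seed: int = 0,
    method: str = "events",
    return_event_rates: bool = False,
) -> SurvivalCurve:
    """Simulate the FRET-only survival function G(t).

    ``ceil(n_events / reuse)`` independent scenes are generated.  With
    ``method="events"`` (the default sampling scheme) each scene hosts
    ``reuse`` excitation events: a donor is picked uniformly at random, its
    total rate Omega computed, and dt = -ln(gamma)/Omega drawn; G(t) is the
    fraction of events with dt > t, events beyond the window (or with
    Omega = 0) counting as not transferred.  With ``method="expectation"``
    the exact per-configuration expectation <exp(-Omega t)> is averaged over
    every donor of every scene — the same estimand with the event-sampling
    variance removed, used by the grid fitter.

    Returns a :class:`SurvivalCurve` on the bin-centre grid.  When
    ``return_event_rates`` is true (events mode) the per-event rates are
    attached as ``meta["event_rates"]`` so the analytic expectation over the
    identical configurations can be formed externally.
    """
    if n_events < reuse:
        raise ValueError("n_events must be at least `reuse`")
    if scene.n_donors <= 0:
        raise ValueError("scene must contain donors")
    if window < 5 * photo.mean_lifetime:
        raise ValueError("window must cover at least 5 mean lifetimes")
    rng = np.random.default_rng(seed)
    n_scenes = math.ceil(n_events / reuse)
    t = (np.arange(bins) + 0.5) * (window / bins)

    if method == "expectation":
        acc = np.zeros(bins)
        n_curves = 0
        for _ in range(n_scenes):
            probes = _build_scene(scene, photo, rng)
            omega = _all_donor_rates(probes, photo)
            acc += np.exp(-np.outer(omega, t)).sum(axis=0)
            n_curves += len(omega)
        g = acc / n_curves
        return SurvivalCurve(t, np.minimum.accumulate(np.clip(g, 0, 1)), {"seed": seed, "method": method, "n_curves": n_curves})

    if method != "events":
        raise ValueError("method must be 'events' or 'expectation'")

    all_dt = np.empty(n_events)
    all_rates = np.empty(n_events) if return_event_rates else None
    done = 0
    for _ in range(n_scenes):
        k = min(reuse, n_events - done)
        probes = _build_scene(scene, photo, rng)
        omega = _all_donor_rates(probes, photo)
        picks = rng.integers(0, len(omega), size=k)
        gamma = 1.0 - rng.random(k)  # uniform in (0, 1]
        all_dt[done : done + k] = sample_transfer_time(omega[picks], gamma)
        if all_rates is not None:
            all_rates[done : done + k] = omega[picks]
        done += k
    # censor beyond the window: those events count as "not transferred"
    dt_sorted = np.sort(np.where(np.isfinite(all_dt), all_dt, np.inf))
    g = 1.0 - np.searchsorted(dt_sorted, t, side="right") / n_events
    meta = {"seed": seed, "method": method, "n_events": n_events, "reuse": reuse}
    if all_rates is not None:
        meta["event_rates"] = all_rates
    return SurvivalCurve(t, g, meta)


def intrinsic_intensity(t: np.ndarray, photo: Photophysics) -> np.ndarray:
    """Unquenched donor decay: sum of amplitude-weighted exponentials."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, tau in photo.intrinsic_decay:
        out += a * np.exp(-t / tau)
    return out


def compose_decay(
    survival: SurvivalCurve,
    photo: Photophysics,
    irf: DecayHistogram | None = None,
    total_counts: float = 1e6,
    poisson: bool = False,
    seed: int | None = None,
) -> DecayHistogram:
    """Compose the observable donor decay F(t) = I_intrinsic(t) * G(t).

    Optionally circularly convolved with a normalised IRF on the same grid,
    scaled to ``total_counts`` summed over all bins, and Poisson-sampled.
    """
    f = intrinsic_intensity(survival.time, photo) * survival.values
    if irf is not None:
        if irf.time.shape != survival.time.shape or not np.allclose(
            irf.time, survival.time
        ):
            raise ValueError("IRF grid does not match the survival grid")
        kernel = irf.counts / irf.counts.sum()
        f = np.real(np.fft.ifft(np.fft.fft(f) * np.fft.fft(kernel)))
        f = np.maximum(f, 0.0)
    if f.sum() <= 0:
        raise ValueError("composed decay has zero intensity")
    f = f * (total_counts / f.sum())
    if poisson:
        f = np.random.default_rng(seed).poisson(f).astype(float)
    meta = dict(survival.meta)
    meta.pop("event_rates", None)
    meta.update({"total_counts": total_counts, "poisson": poisson})
    return DecayHistogram(survival.time, f, meta)


def fret_efficiency(decay_da: DecayHistogram, decay_d: DecayHistogram) -> float:
    """FRET efficiency E = 1 - integral(F_DA)/integral(F_D).

    Both decays must share the time grid and are amplitude-matched by
    normalising to their first-bin value, so an arbitrary intensity scale
    (total counts) cancels and E reduces to one minus the ratio of mean
    decay times.
    """
    if decay_da.time.shape != decay_d.time.shape or not np.allclose(
        decay_da.time, decay_d.time
    ):
        raise ValueError("decays must share the same time grid")
    if decay_d.counts.sum() <= 0 or decay_d.counts[0] <= 0:
        raise ValueError("donor-only decay is empty")
    if decay_da.counts[0] <= 0:
        raise ValueError("donor+acceptor decay has an empty first bin")
    area_da = decay_da.counts.sum() / decay_da.counts[0]
    area_d = decay_d.counts.sum() / decay_d.counts[0]
    return float(1.0 - area_da / area_d)


def relative_efficiency(e_hetero: float, e_homo: float) -> float:
    """E_rel: FRET efficiency with nanodomains over the homogeneous-bilayer one."""
    if e_homo <= 0:
        raise ValueError("homogeneous FRET efficiency must be positive")
    return e_hetero / e_homo
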