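"""Stochastic bilayer scenes: periodic box, circular nanodomains, probes.

A scene is a periodic 2D box containing non-overlapping circular nanodomains
of radius ``R_D`` covering a target area fraction ``Ar``, plus donor and
acceptor fluorophores placed on the two leaflets.  Probe partitioning between
the domain interior and the surrounding bilayer is governed by the partition
coefficient ``K_D = [inside]/[outside]`` (surface-concentration ratio), which
together with the achieved area fraction gives the per-probe probability of
landing inside a domain::

    p_in = K_D * Ar / (K_D * Ar + 1 - Ar)

Domains are registered across the leaflets: a single 2D domain pattern with
the two fluorophore planes separated by ``h`` (nm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._packing import pack_disks

__all__ = [
    "PackingError",
    "DomainLayout",
    "PartitionCoefficients",
    "ProbeField",
    "partition_probability",
    "place_domains",
    "place_probes",
]


class PackingError(RuntimeError):
    """Raised when a non-overlapping domain configuration cannot be built."""


def _min_image(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


@dataclass(frozen=True)
class PartitionCoefficients:
    """Domain partition coefficients K_D for donor and acceptor (1 = no preference)."""

    donor: float = 1.0
    acceptor: float = 1.0

    def __post_init__(self) -> None:
        if self.donor < 0 or self.acceptor < 0:
            raise ValueError("partition coefficients must be non-negative")


@dataclass(frozen=True)
class DomainLayout:
    """Non-overlapping circular nanodomains in a periodic square box (nm units)."""

    box_side: float
    domain_radius: float
    target_area_fraction: float
    centers: np.ndarray  # (n, 2)

    @property
    def n_domains(self) -> int:
        return len(self.centers)

    @property
    def achieved_area_fraction(self) -> float:
        return self.n_domains * np.pi * self.domain_radius**2 / self.box_side**2

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: is each (x, y) point inside any domain (periodic)?"""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.n_domains == 0:
            return np.zeros(len(points), dtype=bool)
        tree = cKDTree(self.centers, boxsize=self.box_side)
        dist, _ = tree.query(points % self.box_side)
        return dist < self.domain_radius

    def min_center_distance(self) -> float:
        if self.n_domains < 2:
            return np.inf
        d = _min_image(self.centers[:, None, :] - self.centers[None, :, :], self.box_side)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        return float(r.min())

    def to_json(self) -> str:
        return json.dumps(
            {
                "box_side": self.box_side,
                "domain_radius": self.domain_radius,
                "target_area_fraction": self.target_area_fraction,
                "centers": self.centers.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DomainLayout":
        d = json.loads(text)
        return cls(
            box_side=d["box_side"],
            domain_radius=d["domain_radius"],
            target_area_fraction=d["target_area_fraction"],
            centers=np.asarray(d["centers"], dtype=float).reshape(-1, 2),
        )


@dataclass
class ProbeField:
    """Donor/acceptor positions on two leaflets with inside/outside labels."""

    donor_xy: np.ndarray  # (n_D, 2)
    donor_leaflet: np.ndarray  # (n_D,) in {0, 1}
    donor_inside: np.ndarray  # (n_D,) bool
    acceptor_xy: np.ndarray
    acceptor_leaflet: np.ndarray
    acceptor_inside: np.ndarray
    leaflet_separation: float = 4.0
    box_side: float = field(default=0.0)

    @property
    def n_donors(self) -> int:
        return len(self.donor_xy)

    @property
    def n_acceptors(self) -> int:
        return len(self.acceptor_xy)

    def to_json(self) -> str:
        return json.dumps(
            {
                "box_side": self.box_side,
                "leaflet_separation": self.leaflet_separation,
                "donor_xy": self.donor_xy.tolist(),
                "donor_leaflet": self.donor_leaflet.tolist(),
                "donor_inside": self.donor_inside.astype(int).tolist(),
                "acceptor_xy": self.acceptor_xy.tolist(),
                "acceptor_leaflet": self.acceptor_leaflet.tolist(),
                "acceptor_inside": self.acceptor_inside.astype(int).tolist(),
            }
        )


def partition_probability(k_d: float, area_fraction: float) -> float:
    """Probability that a probe with partition coefficient K_D sits inside a domain.

    Follows from K_D = [inside]/[outside] with area weighting:
    p_in = K_D*Ar / (K_D*Ar + 1 - Ar).  Equals Ar when K_D = 1.
    """
    if k_d < 0:
        raise ValueError("K_D must be non-negative")
    if not 0 <= area_fraction < 1:
        raise ValueError("area fraction must lie in [0, 1)")
    num = k_d * area_fraction
    return num / (num + 1.0 - area_fraction)


def place_domains(
    box_side: float,
    domain_radius: float,
    area_fraction: float,
    seed: int,
) -> DomainLayout:
    """Pack circular nanodomains as hard disks in a periodic box.

    The number of domains is round(Ar * box^2 / (pi R_D^2)), i.e. the domain
    number density is Ar/(pi R_D^2).  Deterministic given ``seed``.
    """
    if not 2.0 <= domain_radius <= 50.0:
        raise ValueError("domain radius must be within 2-50 nm")
    if not 0.0 <= area_fraction <= 0.6:
        raise ValueError("area fraction must lie in [0, 0.6]")
    if box_side < 10.0 * domain_radius:
        raise ValueError("box side must be at least 10 domain radii")
    n = int(round(area_fraction * box_side**2 / (np.pi * domain_radius**2)))
    pos, ok = pack_disks(n, float(domain_radius), float(box_side), int(seed) & 0x7FFFFFFF)
    if not ok:
        raise PackingError(
            f"packing unreachable: {n} disks of radius {domain_radius} nm "
            f"in a {box_side} nm box (coverage {area_fraction:.2f})"
        )
    return DomainLayout(
        box_side=float(box_side),
        domain_radius=float(domain_radius),
        target_area_fraction=float(area_fraction),
        centers=np.asarray(pos[:n]).reshape(n, 2),
    )


def _sample_inside(layout: DomainLayout, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the union of domains (domains are disjoint disks)."""
    idx = rng.integers(0, layout.n_domains, size=n)
    r = layout.domain_radius * np.sqrt(rng.random(n))
    phi = 2 * np.pi * rng.random(n)
    pts = layout.centers[idx] + np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return pts % layout.box_side


def _sample_outside(
    layout: DomainLayout, n: int, rng: np.random.Generator, max_batches: int = 1000
) -> np.ndarray:
    """Uniform points in the complement of the domain union, by rejection."""
    out = np.empty((0, 2))
    for _ in range(max_batches):
        if len(out) >= n:
            break
        cand = rng.random((max(2 * (n - len(out)), 64), 2)) * layout.box_side
        keep = cand[~layout.contains(cand)]
        out = np.vstack([out, keep])
    if len(out) < n:
        raise PackingError("rejection sampling stalled placing probes outside domains")
    return out[:n]


def place_probes(
    layout: DomainLayout,
    n_donors: int,
    n_acceptors: int,
    partition: PartitionCoefficients,
    leaflet_separation: float = 4.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ProbeField:
    """Distribute probes over the scene according to the partition coefficients.

    Each probe is flagged "inside" with probability
    ``partition_probability(K_D, achieved Ar)``, placed uniformly within the
    domain union (inside) or its complement (outside), and assigned to one of
    the two leaflets with probability 1/2.
    """
    if n_donors <= 0 or n_acceptors <= 0:
        raise ValueError("probe counts must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    ar = layout.achieved_area_fraction

    def _one_species(n: int, k_d: float):
        p_in = partition_probability(k_d, ar) if layout.n_domains else 0.0
        inside = rng.random(n) < p_in
        xy = np.empty((n, 2))
        n_in = int(inside.sum())
        if n_in:
            xy[inside] = _sample_inside(layout, n_in, rng)
        if n - n_in:
            xy[~inside] = _sample_outside(layout, n - n_in, rng)
        leaflet = rng.integers(0, 2, size=n)
        return xy, leaflet, inside

    d_xy, d_leaf, d_in = _one_species(n_donors, partition.donor)
    a_xy, a_leaf, a_in = _one_species(n_acceptors, partition.acceptor)
    return ProbeField(
        donor_xy=d_xy,
        donor_leaflet=d_leaf,
        donor_inside=d_in,
        acceptor_xy=a_xy,
        acceptor_leaflet=a_leaf,
        acceptor_inside=a_in,
        leaflet_separation=float(leaflet_separation),
        box_side=layout.box_side,
    )
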