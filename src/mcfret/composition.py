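"""Per-nanodomain lipid counts from fitted geometry and bilayer composition.

Given a fitted domain radius R_D and area fraction Ar, the number of lipid
"sites" per domain leaflet is N_sites = pi R_D^2 / a with a the area per
lipid (default 0.72 nm^2, DOPC-like).  Species that distribute equally
between domains and bulk (e.g. DOPC) contribute N_sites * x_i molecules per
domain; species confined exclusively to the domains (e.g. SM and Chol)
concentrate their whole bilayer pool into the domain area and contribute
N_sites * x_i / Ar.  Molar ratios of two confined species are independent of
both Ar and a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["BilayerComposition", "domain_lipid_counts", "domain_ratios", "DomainCounts"]


@dataclass(frozen=True)
class BilayerComposition:
    """Mole fractions per species plus the confinement assumption.

    ``confined`` species are assumed to localise exclusively inside the
    nanodomains; ``homogeneous`` species spread equally over the bilayer.
    """

    fractions: dict[str, float]
    confined: frozenset[str] = frozenset({"SM", "Chol"})
    homogeneous: frozenset[str] = frozenset({"DOPC"})

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.fractions.values()):
            raise ValueError("mole fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1 (got {total})")
        nonzero = {s for s, x in self.fractions.items() if x > 0}
        if not nonzero <= (set(self.confined) | set(self.homogeneous)):
            raise ValueError("every nonzero species must be confined or homogeneous")

    @classmethod
    def ternary(cls, dopc: float, chol: float, sm: float) -> "BilayerComposition":
        return cls({"DOPC": dopc, "Chol": chol, "SM": sm})

    @property
    def confined_fraction(self) -> float:
        return sum(x for s, x in self.fractions.items() if s in self.confined)


@dataclass
class DomainCounts:
    """Per-domain molecule counts (single leaflet): exact reals and integers."""

    exact: dict[str, float]
    rounded: dict[str, int]
    n_sites: float
    packing_fraction: float  # local site occupancy inside a domain
    meta: dict = field(default_factory=dict)


def domain_lipid_counts(
    domain_radius: float,
    area_fraction: float,
    composition: BilayerComposition,
    area_per_lipid: float = 0.72,
) -> DomainCounts:
    """Count molecules of each species inside one nanodomain (single leaflet).

    Raises if the confined species alone cannot fit the domain area
    (Ar < sum of confined mole fractions).  The returned
    ``packing_fraction`` additionally reports the total local site
    occupancy (confined/Ar + homogeneous) as a diagnostic.
    """
    import math

    if not 0 < area_fraction < 1:
        raise ValueError("area fraction must lie in (0, 1)")
    if area_per_lipid <= 0 or domain_radius <= 0:
        raise ValueError("radius and area per lipid must be positive")
    if composition.confined_fraction > 0 and area_fraction < composition.confined_fraction:
        raise ValueError(
            f"inconsistent: confined mole fraction {composition.confined_fraction:.3f} "
            f"exceeds the domain area fraction {area_fraction:.3f}"
        )
    n_sites = math.pi * domain_radius**2 / area_per_lipid
    exact: dict[str, float] = {}
    for species, x in composition.fractions.items():
        if species in composition.confined:
            exact[species] = n_sites * x / area_fraction
        else:
            exact[species] = n_sites * x
    packing = (
        composition.confined_fraction / area_fraction
        + sum(x for s, x in composition.fractions.items() if s in composition.homogeneous)
    )
    return DomainCounts(
        exact=exact,
        rounded={s: int(round(v)) for s, v in exact.items()},
        n_sites=n_sites,
        packing_fraction=packing,
        meta={
            "domain_radius": domain_radius,
            "area_fraction": area_fraction,
            "area_per_lipid": area_per_lipid,
        },
    )


def domain_ratios(counts: DomainCounts, reference: str = "SM") -> dict[str, float]:
    """Molar ratios of every species to the reference, from the exact counts.

    For two confined species the ratio reduces to the mole-fraction ratio and
    is independent of Ar and the area per lipid.  A zero-count reference
    yields +inf ratios, flagged via the "undefined" key.
    """
    ref = counts.exact.get(reference, 0.0)
    out: dict[str, float] = {}
    for species, v in counts.exact.items():
        if species == reference:
            continue
        out[f"{species}:{reference}"] = (v / ref) if ref > 0 else float("inf")
    out["undefined"] = ref <= 0
    return out
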