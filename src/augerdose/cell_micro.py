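"""Cellular-scale electron dosimetry in a concentric-sphere cell model.

Tumor cells are modelled as two concentric spheres (26 um cell, 18 um
nucleus by default).  Radioligand decays are distributed over three source
compartments -- a perinuclear shell hugging the nuclear envelope, the cell
membrane, and the cytoplasm -- and the quantity of interest is phi(nucleus
<- compartment): the fraction of emitted electron energy deposited inside
the nucleus, where DNA damage happens.

Electrons from the grouped :sup:`125`I spectrum are transported as straight
continuous-slowing-down tracks: an isotropic direction is chosen, the track
has the Cole range of its initial energy, and the energy deposited inside a
sphere is the difference of residual energies at the entry and exit path
lengths.  Two backends integrate over emission angle (and source radius for
volumetric compartments): a seeded Monte Carlo and a deterministic
Gauss-Legendre point-kernel quadrature; they agree to well under a percent
and serve as independent checks of one another.

The nuclear dose relative to the tumor-average dose follows as
``sum_i f_i * phi_i / w_nuc`` with ``f_i`` the compartment weights and
``w_nuc`` the nuclear mass (volume) fraction of the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .physics import EmissionSpectrum, default_i125_spectrum, residual_energy

__all__ = [
    "COMPARTMENTS",
    "CellGeometry",
    "SourceDistribution",
    "DepositionFractions",
    "nuclear_volume_fraction",
    "compartment_energy_fraction",
    "cell_energy_partition",
    "deposition_fractions",
    "nuclear_dose_ratio",
    "tumor_nuclear_dose",
]

#: Source compartments of the cell model.
COMPARTMENTS = ("perinuclear", "membrane", "cytoplasm", "nucleus")


@dataclass(frozen=True)
class CellGeometry:
    """Concentric-sphere cell: nucleus centred inside the cell."""

    cell_diameter_um: float = 26.0
    nucleus_diameter_um: float = 18.0

    def __post_init__(self) -> None:
        if not 0.0 < self.nucleus_diameter_um < self.cell_diameter_um:
            raise ValueError(
                "need 0 < nucleus diameter < cell diameter"
            )

    @property
    def cell_radius_um(self) -> float:
        return self.cell_diameter_um / 2.0

    @property
    def nucleus_radius_um(self) -> float:
        return self.nucleus_diameter_um / 2.0


@dataclass(frozen=True)
class SourceDistribution:
    """Fraction of decays per source compartment (sums to one).

    Defaults are the measured subcellular distribution of the radioligand in
    PSMA-positive tumor cells: 15% perinuclear, 35% membrane, 50% cytoplasm.
    """

    perinuclear: float = 0.15
    membrane: float = 0.35
    cytoplasm: float = 0.50

    def __post_init__(self) -> None:
        fracs = (self.perinuclear, self.membrane, self.cytoplasm)
        if any(f < 0 for f in fracs):
            raise ValueError("compartment fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("compartment fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "perinuclear": self.perinuclear,
            "membrane": self.membrane,
            "cytoplasm": self.cytoplasm,
        }


@dataclass(frozen=True)
class DepositionFractions:
    """phi(nucleus <- compartment) with Monte Carlo standard errors."""

    phi: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.phi.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"phi[{name}] must lie in [0, 1]")


def nuclear_volume_fraction(geom: CellGeometry) -> float:
    """Nucleus-to-cell volume (and unit-density mass) fraction."""
    return (geom.nucleus_diameter_um / geom.cell_diameter_um) ** 3


# ---------------------------------------------------------------------------
# Straight-track CSDA kernel
# ---------------------------------------------------------------------------

def _sphere_interval(r_s, mu, rho):
    """Path-length interval [s1, s2] a straight track spends inside a
    sphere of radius ``rho`` centred at the origin.

    The source sits at distance ``r_s`` from the centre and the track
    direction makes cosine ``mu`` with the outward radial; vectorized.
    """
    disc = rho * rho - r_s * r_s * (1.0 - mu * mu)
    sq = np.sqrt(np.maximum(disc, 0.0))
    s1 = np.maximum(-r_s * mu - sq, 0.0)
    s2 = np.maximum(-r_s * mu + sq, 0.0)
    empty = disc <= 0.0
    s1 = np.where(empty, 0.0, s1)
    s2 = np.where(empty, 0.0, s2)
    return s1, s2


def _energy_in_sphere(energy_kev, r_s, mu, rho):
    """Energy (keV) a track of initial ``energy_kev`` deposits inside the
    sphere of radius ``rho``."""
    s1, s2 = _sphere_interval(r_s, mu, rho)
    return residual_energy(energy_kev, s1) - residual_energy(energy_kev, s2)


def _sample_source_radius(
    geom: CellGeometry, compartment: str, u: np.ndarray
) -> np.ndarray:
    """Map uniform variates to source radii (volume-uniform for shells)."""
    r_n, r_c = geom.nucleus_radius_um, geom.cell_radius_um
    if compartment == "perinuclear":
        return np.full_like(u, r_n)
    if compartment == "membrane":
        return np.full_like(u, r_c)
    if compartment == "cytoplasm":
        return (r_n**3 + u * (r_c**3 - r_n**3)) ** (1.0 / 3.0)
    if compartment == "nucleus":
        return (u * r_n**3) ** (1.0 / 3.0)
    raise ValueError(f"unknown compartment {compartment!r}")


def _partition_samples(geom, energy_kev, r_s, mu):
    """Per-sample energy fractions in (nucleus, cytoplasm, outside)."""
    in_nuc = _energy_in_sphere(energy_kev, r_s, mu, geom.nucleus_radius_um)
    in_cell = _energy_in_sphere(energy_kev, r_s, mu, geom.cell_radius_um)
    return (
        in_nuc / energy_kev,
        (in_cell - in_nuc) / energy_kev,
        (energy_kev - in_cell) / energy_kev,
    )


_REGIONS = ("nucleus", "cytoplasm", "outside")


def cell_energy_partition(
    geom: CellGeometry,
    compartment: str,
    spectrum: EmissionSpectrum | None = None,
    histories: int = 100_000,
    seed: int = 0,
    backend: str = "mc",
) -> dict[str, dict[str, float]]:
    """Partition of emitted electron energy among nucleus / cytoplasm /
    outside-the-cell for decays in one source compartment.

    Returns ``{"phi": {region: fraction}, "se": {region: standard error}}``;
    fractions sum to one by construction (energy conservation).  The ``mc``
    backend samples emission angles and source radii; the ``point_kernel``
    backend uses Gauss-Legendre quadrature (se = 0).
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    spectrum = spectrum or default_i125_spectrum()
    energies, weights = spectrum.electron_energy_weights()

    phi = {r: 0.0 for r in _REGIONS}
    var = {r: 0.0 for r in _REGIONS}

    if backend == "mc":
        if histories <= 0:
            raise ValueError("histories must be positive")
        rng = np.random.default_rng(seed)
        for e_line, w in zip(energies, weights):
            mu = rng.uniform(-1.0, 1.0, histories)
            r_s = _sample_source_radius(geom, compartment, rng.random(histories))
            fracs = _partition_samples(geom, e_line, r_s, mu)
            for region, f in zip(_REGIONS, fracs):
                phi[region] += w * float(f.mean())
                var[region] += w**2 * float(f.var(ddof=1)) / histories
    elif backend == "point_kernel":
        mu_nodes, mu_wts = np.polynomial.legendre.leggauss(256)
        mu_wts = mu_wts / 2.0  # isotropic average over cos(theta) in [-1, 1]
        if compartment in ("cytoplasm", "nucleus"):
            u_nodes, u_wts = np.polynomial.legendre.leggauss(64)
            u_nodes = 0.5 * (u_nodes + 1.0)
            u_wts = u_wts / 2.0
        else:
            u_nodes, u_wts = np.array([0.5]), np.array([1.0])
        for e_line, w in zip(energies, weights):
            for u, uw in zip(u_nodes, u_wts):
                r_s = _sample_source_radius(geom, compartment, np.full_like(mu_nodes, u))
                fracs = _partition_samples(geom, e_line, r_s, mu_nodes)
                for region, f in zip(_REGIONS, fracs):
                    phi[region] += w * uw * float(np.sum(f * mu_wts))
    else:
        raise ValueError(f"unknown backend {backend!r}")

    return {
        "phi": phi,
        "se": {r: math.sqrt(v) for r, v in var.items()},
    }


def compartment_energy_fraction(
    geom: CellGeometry,
    compartment: str,
    spectrum: EmissionSpectrum | None = None,
    histories: int = 100_000,
    seed: int = 0,
    backend: str = "mc",
) -> tuple[float, float]:
    """phi(nucleus <- compartment) with its standard error."""
    part = cell_energy_partition(
        geom, compartment, spectrum, histories, seed, backend
    )
    return part["phi"]["nucleus"], part["se"]["nucleus"]


def deposition_fractions(
    geom: CellGeometry,
    spectrum: EmissionSpectrum | None = None,
    histories: int = 100_000,
    seed: int = 0,
    backend: str = "mc",
) -> DepositionFractions:
    """phi(nucleus <- compartment) for the three extranuclear compartments."""
    phi, se = {}, {}
    for i, comp in enumerate(("perinuclear", "membrane", "cytoplasm")):
        phi[comp], se[comp] = compartment_energy_fraction(
            geom, comp, spectrum, histories, seed + i, backend
        )
    return DepositionFractions(phi=phi, se=se)


def nuclear_dose_ratio(
    dist: SourceDistribution,
    phi: DepositionFractions | dict[str, float],
    w_nuc: float,
) -> float:
    """Nuclear absorbed dose relative to the cell/tumor-average dose.

    ``(sum_i dist_i * phi_i) / w_nuc``: the numerator is the fraction of all
    emitted energy landing in nuclei, the denominator the fraction of mass
    that is nucleus; their ratio is the nucleus-to-average dose ratio.
    Equals 1 when deposition is homogeneous (phi_i == w_nuc for all i).
    """
    if not 0.0 < w_nuc < 1.0:
        raise ValueError("nuclear mass fraction must lie in (0, 1)")
    phi_map = phi.phi if isinstance(phi, DepositionFractions) else phi
    num = sum(f * phi_map[name] for name, f in dist.as_dict().items())
    return num / w_nuc


def tumor_nuclear_dose(
    electron_coeff_gy_per_mbq: float,
    injected_mbq: float,
    ratio: float,
) -> float:
    """Average tumor-cell nuclear dose in Gy at a given injected activity."""
    if electron_coeff_gy_per_mbq < 0 or injected_mbq < 0 or ratio < 0:
        raise ValueError("inputs must be non-negative")
    return electron_coeff_gy_per_mbq * injected_mbq * ratio
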