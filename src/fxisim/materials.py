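"""Element scattering factors, optical media, and refractive-index conversions.

X-rays are scattered by bound electrons.  Far from absorption edges each
atom of species *a* scatters like ``f_a = f1 + i f2`` free electrons,
where the complex atomic scattering factor ``f_a`` depends on the photon
energy.  This module bundles per-element tables of ``(E, f1, f2)`` in
the plain-text ``.nff`` layout (one sample per line), interpolates them
linearly in energy, and uses them for the two density/refractive-index
conversions a weak-phase X-ray model needs:

* electron density ``rho_e`` -> ``n = 1 - r0 lambda^2 rho_e / (2 pi)``
* per-species atom densities ``rho_a`` ->
  ``n = 1 - (r0 lambda^2 / 2 pi) sum_a rho_a f_a(lambda)``

Sign convention: ``n = 1 - delta - i beta`` with ``delta, beta >= 0``,
so the complemented index ``nbar = 1 - n = delta + i beta`` carries the
same phase convention as ``f = f1 + i f2``.  The scattering factor is
treated as angle independent (forward-scattering approximation), valid
when the imaging resolution is far above atomic length scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import gemmi
import numpy as np

from .constants import EV, HC, N_AVOGADRO, R_ELECTRON

__all__ = [
    "ScatteringFactorTable",
    "Material",
    "RefractiveIndex",
    "wavelength_from_energy",
    "energy_from_wavelength",
    "atomic_scattering_factor",
    "tabulated_elements",
    "electron_density",
    "number_densities",
    "refractive_index_from_atom_density",
    "refractive_index_from_electron_density",
    "builtin_materials",
]


def atomic_number(element: int | str) -> int:
    """Normalize an element given as symbol or atomic number to Z."""
    if isinstance(element, str):
        el = gemmi.Element(element)
        if el.atomic_number == 0:
            raise ValueError(f"unknown element symbol {element!r}")
        return el.atomic_number
    z = int(element)
    if z < 1:
        raise ValueError(f"invalid atomic number {element!r}")
    return z


def element_symbol(z: int) -> str:
    return gemmi.Element(int(z)).name


def standard_atomic_weight(element: int | str) -> float:
    """Standard atomic weight in g/mol."""
    return gemmi.Element(atomic_number(element)).weight


def wavelength_from_energy(photon_energy: float) -> float:
    """Convert photon energy in eV to wavelength in m (lambda = hc/E)."""
    if not photon_energy > 0:
        raise ValueError(f"photon energy must be positive, got {photon_energy}")
    return HC / (photon_energy * EV)


def energy_from_wavelength(wavelength: float) -> float:
    """Convert wavelength in m to photon energy in eV (inverse of above)."""
    if not wavelength > 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    return HC / (wavelength * EV)


@dataclass(frozen=True)
class ScatteringFactorTable:
    """Tabulated complex scattering factor of one element.

    ``energies`` (eV) are strictly increasing; ``f1`` and ``f2`` are the
    dispersive and absorptive parts sampled at those energies.  Lookups
    interpolate linearly and refuse to extrapolate.
    """

    element: int
    energies: np.ndarray
    f1: np.ndarray
    f2: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or len(e) < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("energies must be a strictly increasing 1-D array")
        if not (np.all(np.isfinite(self.f1)) and np.all(np.isfinite(self.f2))):
            raise ValueError("scattering factors must be finite")

    @classmethod
    def from_nff(cls, path, element: int) -> "ScatteringFactorTable":
        data = np.loadtxt(path, comments="#")
        return cls(element=element, energies=data[:, 0], f1=data[:, 1], f2=data[:, 2])

    def __call__(self, photon_energy: float) -> complex:
        e = float(photon_energy)
        if e < self.energies[0] or e > self.energies[-1]:
            raise ValueError(
                f"photon energy {e} eV outside tabulated range "
                f"[{self.energies[0]:.1f}, {self.energies[-1]:.1f}] eV "
                f"for element Z={self.element}"
            )
        return complex(np.interp(e, self.energies, self.f1),
                       np.interp(e, self.energies, self.f2))


_TABLE_CACHE: dict[int, ScatteringFactorTable] = {}


def _load_table(z: int) -> ScatteringFactorTable:
    if z not in _TABLE_CACHE:
        symbol = element_symbol(z).lower()
        ref = resources.files("fxisim.data.nff").joinpath(f"{symbol}.nff")
        if not ref.is_file():
            raise ValueError(
                f"no scattering-factor table for element {element_symbol(z)} (Z={z})"
            )
        with resources.as_file(ref) as path:
            _TABLE_CACHE[z] = ScatteringFactorTable.from_nff(path, element=z)
    return _TABLE_CACHE[z]


def tabulated_elements() -> list[int]:
    """Atomic numbers for which a scattering-factor table is bundled."""
    zs = []
    for ref in resources.files("fxisim.data.nff").iterdir():
        if ref.name.endswith(".nff"):
            zs.append(atomic_number(ref.name[:-4].capitalize()))
    return sorted(zs)


def atomic_scattering_factor(element: int | str, photon_energy: float) -> complex:
    """Complex scattering factor f = f1 + i f2, interpolated in energy.

    The same value is used at all scattering angles (forward-scattering
    approximation).  Raises for untabulated elements and for energies
    outside the tabulated range — never extrapolates.
    """
    return _load_table(atomic_number(element))(photon_energy)


@dataclass(frozen=True)
class Material:
    """A homogeneous optical medium.

    ``composition`` maps element (symbol or Z) to a relative
    stoichiometric abundance; abundances are weights, not fractions, so
    {H: 2, O: 1} and {H: 4, O: 2} describe the same medium.
    """

    name: str
    mass_density: float  # kg m^-3
    composition: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.mass_density > 0:
            raise ValueError(f"mass density must be positive, got {self.mass_density}")
        comp = {atomic_number(el): float(w) for el, w in self.composition.items()}
        if not comp or any(w < 0 for w in comp.values()) or sum(comp.values()) <= 0:
            raise ValueError("composition needs non-negative abundances, at least one > 0")
        object.__setattr__(self, "composition", comp)

    @property
    def molar_mass(self) -> float:
        """Abundance-weighted molar mass, kg/mol."""
        return sum(w * standard_atomic_weight(z) for z, w in self.composition.items()) * 1e-3

    @property
    def electrons_per_formula(self) -> float:
        return sum(w * z for z, w in self.composition.items())


@dataclass(frozen=True)
class RefractiveIndex:
    """Complex refractive index n = 1 - delta - i beta of a medium."""

    n: complex

    def __post_init__(self):
        if self.beta < -1e-12:
            raise ValueError("absorption index beta must be non-negative")

    @property
    def delta(self) -> float:
        """Refractive-index decrement 1 - Re(n)."""
        return 1.0 - self.n.real

    @property
    def beta(self) -> float:
        """Absorption index -Im(n) >= 0."""
        return -self.n.imag

    @property
    def nbar(self) -> complex:
        """Complemented index 1 - n = delta + i beta (enters the amplitude)."""
        return complex(self.delta, self.beta)


def electron_density(material: Material) -> float:
    """Electron number density rho_e in m^-3.

    rho_e = mass_density * N_A / molar_mass * electrons_per_formula,
    with abundances acting as stoichiometric weights.
    """
    m = material.molar_mass
    if m <= 0:
        raise ValueError("material has zero molar mass")
    return material.mass_density * N_AVOGADRO / m * material.electrons_per_formula


def number_densities(material: Material) -> dict[int, float]:
    """Number density rho_a (m^-3) of each atomic species in the medium."""
    m = material.molar_mass
    n_formula = material.mass_density * N_AVOGADRO / m  # formula units per m^3
    return {z: w * n_formula for z, w in material.composition.items()}


def refractive_index_from_atom_density(
    material: Material,
    photon_energy: float,
    f_values: dict[int, complex] | None = None,
) -> RefractiveIndex:
    """Refractive index from per-species atom densities.

    n = 1 - (r0 lambda^2 / 2 pi) sum_a rho_a f_a(lambda).

    ``f_values`` overrides the tabulated scattering factors per element
    (e.g. ``{z: z for z in ...}`` for the high-energy limit f -> Z).
    """
    lam = wavelength_from_energy(photon_energy)
    acc = 0.0 + 0.0j
    for z, rho in number_densities(material).items():
        f = f_values[z] if f_values is not None else atomic_scattering_factor(z, photon_energy)
        acc += rho * complex(f)
    nbar = R_ELECTRON * lam**2 / (2.0 * np.pi) * acc
    return RefractiveIndex(n=1.0 - nbar.real - 1j * nbar.imag)


def refractive_index_from_electron_density(rho_e: float, wavelength: float) -> RefractiveIndex:
    """Refractive index of a medium described only by its electron density.

    n = 1 - r0 lambda^2 rho_e / (2 pi); purely real because an electron
    density carries no absorption information.
    """
    if rho_e < 0:
        raise ValueError(f"electron density must be non-negative, got {rho_e}")
    delta = R_ELECTRON * wavelength**2 * float(rho_e) / (2.0 * np.pi)
    return RefractiveIndex(n=complex(1.0 - delta, 0.0))


# Optical media commonly used to model biological FXI samples.  Mass
# densities in kg/m^3; compositions are relative stoichiometries for an
# average formula unit of each medium.
_BUILTIN = {
    "water": (1000.0, {"H": 2, "O": 1}),
    "protein": (1350.0, {"H": 86, "C": 52, "N": 13, "O": 15, "S": 3}),
    "dna": (1700.0, {"H": 11, "C": 10, "N": 4, "O": 6, "P": 1}),
    "lipid": (1000.0, {"H": 69, "C": 36, "O": 6, "P": 1}),
    "cell": (1000.0, {"H": 23, "C": 3, "N": 1, "O": 10, "S": 1}),
    "virus": (1340.0, {"H": 492388, "C": 332652, "N": 98245, "O": 131196, "P": 7501, "S": 2340}),
}


def builtin_materials() -> dict[str, Material]:
    """The built-in optical media (fresh, editable copies)."""
    return {
        name: Material(name=name, mass_density=rho, composition=dict(comp))
        for name, (rho, comp) in _BUILTIN.items()
    }
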