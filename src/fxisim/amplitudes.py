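"""Far-field coherent scattering amplitudes on the Ewald sphere.

Within the first-order Born approximation the far-field amplitude of a
frozen sample is the Fourier transform of its scattering potential
evaluated at the per-pixel scattering vectors q.  All amplitudes here
are in meters (scattering length): one free electron scatters with
amplitude r0, an atom with r0 f(lambda), and a voxel of complemented
refractive index nbar = 1 - n with (k^2 / 2 pi) nbar dx^3.  With these
units |F(q)|^2 is an area, and multiplying by fluence times solid angle
gives expected photon counts (see :mod:`fxisim.detection`).

The global phase factor exp(ikr)/r of the spherical carrier wave and
the unscattered primary wave are dropped: only relative phases across
the detector matter and the direct beam is never measured.

Every fast evaluation path is an exact blocked dense sum, verified in
the tests against :func:`brute_force_dft`, a literal evaluation of the
defining nonuniform discrete Fourier transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_ELECTRON
from .geometry import QMap, Rotation
from .materials import (
    Material,
    RefractiveIndex,
    atomic_scattering_factor,
    energy_from_wavelength,
    refractive_index_from_atom_density,
)
from .particles import (
    ParticleAtoms,
    ParticleMap,
    ParticleSphere,
    ParticleSpheroid,
    spheroid_semiaxes,
)

__all__ = [
    "AmplitudePattern",
    "amplitude_atoms",
    "amplitude_map",
    "amplitude_sphere",
    "amplitude_spheroid",
    "superpose",
    "brute_force_dft",
    "map_nbar",
]


@dataclass
class AmplitudePattern:
    """Complex scattering amplitude per detector pixel, in meters."""

    values: np.ndarray
    qmap: QMap
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.qmap.shape:
            raise ValueError("amplitude shape must match the q-map")

    @property
    def intensity(self) -> np.ndarray:
        """|F|^2 per pixel, m^2 (differential cross-section per pixel)."""
        return np.abs(self.values) ** 2


def _nudft(positions: np.ndarray, weights: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Dense evaluation of sum_j w_j exp(-i q . r_j), blocked over q.

    Mathematically identical to the brute-force sum; blocking only
    bounds memory.  positions (n, 3), weights (n,), q (m, 3) -> (m,).
    """
    positions = np.asarray(positions, dtype=float)
    weights = np.asarray(weights, dtype=complex)
    out = np.empty(len(q), dtype=complex)
    if len(positions) == 0:
        out[:] = 0.0
        return out
    block = max(1, int(2e6 / max(len(positions), 1)))
    for start in range(0, len(q), block):
        phase = q[start:start + block] @ positions.T
        out[start:start + block] = np.exp(-1j * phase) @ weights
    return out


def brute_force_dft(points, weights, qmap: QMap) -> AmplitudePattern:
    """Literal term-by-term sum of the defining nonuniform DFT.

    The testing oracle for every fast path: accumulates
    ``w_j exp(-i q . r_j)`` one point at a time with no vectorized
    shortcuts over the point index.  Keep instances small
    (<= 1e5 point-pixel products recommended... it is slow by design).
    """
    q = qmap.q.reshape(-1, 3)
    acc = np.zeros(len(q), dtype=complex)
    for r, w in zip(np.atleast_2d(np.asarray(points, dtype=float)).reshape(-1, 3),
                    np.asarray(weights, dtype=complex).ravel()):
        acc += w * np.exp(-1j * (q @ r))
    return AmplitudePattern(values=acc.reshape(qmap.shape), qmap=qmap,
                            provenance="brute_force_dft")


def amplitude_atoms(p: ParticleAtoms, qmap: QMap, photon_energy: float) -> AmplitudePattern:
    """Amplitude of an atomic model: F(q) = r0 sum_a f_a sum_i exp(-i q . R r_i)."""
    rotated = p.orientation.apply(p.positions)
    weights = np.empty(len(p), dtype=complex)
    for z in np.unique(p.elements):
        weights[p.elements == z] = R_ELECTRON * atomic_scattering_factor(int(z), photon_energy)
    values = _nudft(rotated, weights, qmap.q.reshape(-1, 3)).reshape(qmap.shape)
    return AmplitudePattern(values=values, qmap=qmap, provenance="atoms")


def map_nbar(p: ParticleMap, wavelength: float) -> np.ndarray:
    """Convert map voxels to the complemented refractive index nbar = 1 - n."""
    if p.value_kind == "refractive_index":
        return 1.0 - np.asarray(p.values, dtype=complex)
    if p.value_kind == "electron_density":
        delta = R_ELECTRON * wavelength**2 / (2.0 * np.pi) * np.asarray(p.values, dtype=float)
        return delta.astype(complex)
    # atom_density: voxels are formula-unit densities of p.material
    energy = energy_from_wavelength(wavelength)
    f_formula = sum(w * atomic_scattering_factor(z, energy)
                    for z, w in p.material.composition.items())
    return (R_ELECTRON * wavelength**2 / (2.0 * np.pi) * f_formula) * \
        np.asarray(p.values, dtype=complex)


def _map_grid_positions(n: int, dx: float) -> np.ndarray:
    centers = (np.arange(n) - (n - 1) / 2.0) * dx
    xg, yg, zg = np.meshgrid(centers, centers, centers, indexing="ij")
    return np.stack([xg, yg, zg], axis=-1).reshape(-1, 3)


def amplitude_map(p: ParticleMap, qmap: QMap, wavelength: float) -> AmplitudePattern:
    """Amplitude of a voxel map: F(q) = (k^2/2pi) dx^3 sum_j nbar_j exp(-i q . R x_j).

    The particle orientation is applied to q (never by resampling the
    grid): rotating the map by R equals evaluating the unrotated map at
    R^-1 q.  A warning flag is set when the grid is too coarse for the
    requested q range (dx > pi / q_max).
    """
    k = 2.0 * np.pi / wavelength
    nbar = map_nbar(p, wavelength).ravel()
    positions = _map_grid_positions(p.n_voxels, p.dx)
    nz = nbar != 0
    weights = (k**2 / (2.0 * np.pi)) * p.dx**3 * nbar[nz]
    q = qmap.q.reshape(-1, 3)
    q_rot = p.orientation.inverse().apply(q)
    values = _nudft(positions[nz], weights, q_rot).reshape(qmap.shape)
    warnings = []
    q_max = float(np.max(qmap.qnorm))
    if q_max > 0 and p.dx > np.pi / q_max:
        warnings.append(
            f"voxel spacing {p.dx:.3e} m undersamples the requested q range "
            f"(Nyquist limit pi/q_max = {np.pi / q_max:.3e} m)")
    return AmplitudePattern(values=values, qmap=qmap, provenance="map", warnings=warnings)


def _sphere_shape_factor(u: np.ndarray) -> np.ndarray:
    """3 [sin u - u cos u] / u^3, with the analytic limit 1 at u = 0."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-3
    us = np.where(small, 1.0, u)
    out = 3.0 * (np.sin(us) - us * np.cos(us)) / us**3
    return np.where(small, 1.0 - u**2 / 10.0 + u**4 / 280.0, out)


def _material_nbar(material: Material | RefractiveIndex, wavelength: float) -> complex:
    if isinstance(material, RefractiveIndex):
        return material.nbar
    return refractive_index_from_atom_density(
        material, energy_from_wavelength(wavelength)).nbar


def amplitude_sphere(p: ParticleSphere, qmap: QMap, wavelength: float) -> AmplitudePattern:
    """Closed-form amplitude of a uniform sphere.

    F(q) = s_tot 3 [sin(qR) - qR cos(qR)] / (qR)^3 with R = d/2 and
    s_tot = (k^2/2pi) nbar (4/3) pi R^3 the total scattering length.
    """
    k = 2.0 * np.pi / wavelength
    radius = p.diameter / 2.0
    nbar = _material_nbar(p.material, wavelength)
    s_total = k**2 / (2.0 * np.pi) * nbar * 4.0 / 3.0 * np.pi * radius**3
    values = s_total * _sphere_shape_factor(qmap.qnorm * radius)
    return AmplitudePattern(values=values, qmap=qmap, provenance="sphere")


def amplitude_spheroid(p: ParticleSpheroid, qmap: QMap, wavelength: float) -> AmplitudePattern:
    """Closed-form amplitude of a uniform spheroid.

    The classic ellipsoid reduction of the sphere solution:
    F(q) = s_tot 3 [sin u - u cos u] / u^3 with
    u = |q| sqrt(a^2 sin^2 psi + c^2 cos^2 psi) and psi the angle
    between q and the rotated symmetry axis.
    """
    k = 2.0 * np.pi / wavelength
    a, _, c = spheroid_semiaxes(p)
    nbar = _material_nbar(p.material, wavelength)
    s_total = k**2 / (2.0 * np.pi) * nbar * 4.0 / 3.0 * np.pi * a * a * c
    axis = p.orientation.apply([0.0, 0.0, 1.0])
    q = qmap.q
    qn = qmap.qnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_psi = np.where(qn > 0, (q @ axis) / np.where(qn > 0, qn, 1.0), 0.0)
    cos_psi = np.clip(cos_psi, -1.0, 1.0)
    r_eff = np.sqrt(a**2 * (1.0 - cos_psi**2) + c**2 * cos_psi**2)
    values = s_total * _sphere_shape_factor(qn * r_eff)
    return AmplitudePattern(values=values, qmap=qmap, provenance="spheroid")


def superpose(patterns_with_positions, source=None,
              reference_fluence: float | None = None) -> AmplitudePattern:
    """Coherent superposition of particles at different beam positions.

    F_tot(q) = sum_j F_j(q) exp(-i q . dr_j) w_j, where dr_j is the
    particle position and w_j = sqrt(fluence(dr_j) / reference fluence)
    weights each particle by the illumination it actually sees (w_j = 1
    when no ``source`` is given).  The reference fluence defaults to the
    on-axis value.
    """
    items = list(patterns_with_positions)
    if not items:
        raise ValueError("nothing to superpose")
    qmap = items[0][0].qmap
    q = qmap.q.reshape(-1, 3)
    total = np.zeros(len(q), dtype=complex)
    warnings: list[str] = []
    for pattern, position in items:
        if pattern.qmap is not qmap and not np.array_equal(pattern.qmap.q, qmap.q):
            raise ValueError("all patterns must share one q-map")
        position = np.asarray(position, dtype=float)
        weight = 1.0
        if source is not None:
            from .source import fluence_at  # local import to avoid a cycle
            ref = reference_fluence if reference_fluence is not None \
                else fluence_at(source, (0.0, 0.0))
            flu = fluence_at(source, position[:2])
            weight = np.sqrt(flu / ref) if ref > 0 else 0.0
        total += weight * pattern.values.ravel() * np.exp(-1j * (q @ position))
        warnings.extend(pattern.warnings)
    return AmplitudePattern(values=total.reshape(qmap.shape), qmap=qmap,
                            provenance="superposition", warnings=warnings)
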