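"""Sample-particle models and per-shot stochastic ensembles.

Four representations of the scattering potential are supported:

* :class:`ParticleSphere` — uniformly filled sphere (analytic amplitude)
* :class:`ParticleSpheroid` — uniformly filled spheroid of revolution
* :class:`ParticleMap` — voxelized refractive-index / electron-density /
  atom-density map on a cubic grid
* :class:`ParticleAtoms` — explicit atom positions and species

:class:`SpeciesSpec` describes a stochastic particle species (Poisson
arrival statistics, size and shape jitter, random position and
orientation); :func:`sample_shot_ensemble` resolves all randomness of
one shot into concrete :class:`ParticleInstance` records that serve as
the ground truth stored with each simulated pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import N_AVOGADRO
from .geometry import Rotation
from .materials import Material, RefractiveIndex

__all__ = [
    "ParticleSphere",
    "ParticleSpheroid",
    "ParticleMap",
    "ParticleAtoms",
    "SpeciesSpec",
    "ParticleInstance",
    "spheroid_semiaxes",
    "sample_shot_ensemble",
    "map_from_geometry",
]

MAP_VALUE_KINDS = ("refractive_index", "electron_density", "atom_density")


@dataclass
class ParticleSphere:
    """Uniformly filled sphere of the given material."""

    diameter: float  # m
    material: Material | RefractiveIndex

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("sphere diameter must be positive")


@dataclass
class ParticleSpheroid:
    """Uniformly filled spheroid of revolution.

    ``diameter`` is the diameter of the equal-volume sphere and
    ``flattening`` the ratio c/a of the symmetry semi-axis c over the
    equatorial semi-axis a; the volume is preserved for any flattening.
    The symmetry axis is ``orientation`` applied to z.
    """

    diameter: float  # m
    flattening: float
    material: Material | RefractiveIndex
    orientation: Rotation = field(default_factory=Rotation.identity)

    def __post_init__(self):
        if not self.diameter > 0 or not self.flattening > 0:
            raise ValueError("spheroid diameter and flattening must be positive")


@dataclass
class ParticleMap:
    """Scattering potential sampled on a cubic N^3 grid at spacing dx.

    ``value_kind`` declares what the voxels store: complex refractive
    indices, an electron density (m^-3), or a formula-unit number
    density (m^-3) of ``material`` whose composition supplies the
    per-species stoichiometry.
    """

    values: np.ndarray
    dx: float  # m
    value_kind: str = "refractive_index"
    material: Material | None = None
    orientation: Rotation = field(default_factory=Rotation.identity)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("map values must live on a cubic N^3 grid")
        if not self.dx > 0:
            raise ValueError("voxel spacing must be positive")
        if self.value_kind not in MAP_VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {MAP_VALUE_KINDS}")
        if self.value_kind == "atom_density" and self.material is None:
            raise ValueError("atom-density maps need a material for the stoichiometry")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class ParticleAtoms:
    """Explicit atomic model: positions (m) and atomic numbers."""

    positions: np.ndarray
    elements: np.ndarray
    orientation: Rotation = field(default_factory=Rotation.identity)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.elements = np.atleast_1d(np.asarray(self.elements, dtype=int))
        if self.positions.shape != (len(self.elements), 3):
            raise ValueError("positions must be (n, 3) matching the element list")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")

    def __len__(self) -> int:
        return len(self.elements)


def spheroid_semiaxes(p: ParticleSpheroid) -> tuple[float, float, float]:
    """Semi-axes (a, a, c) with c/a = flattening and the sphere's volume.

    a = (d/2) f^(-1/3), c = (d/2) f^(2/3), so that a^2 c = (d/2)^3.
    """
    r = p.diameter / 2.0
    f = p.flattening
    a = r * f ** (-1.0 / 3.0)
    c = r * f ** (2.0 / 3.0)
    return a, a, c


@dataclass
class SpeciesSpec:
    """A stochastic particle species injected into the beam.

    Per shot the number of arrivals is Poisson(``arrival_rate``); each
    arrival draws its diameter from a truncated normal
    (``diameter_sigma``), its flattening uniformly from
    ``flattening_range`` (spheroids only), its transverse position from
    ``position_mode`` ('fixed' | 'uniform-in-focus' | 'normal') and its
    orientation either fixed from the template or uniform over SO(3).
    """

    template: ParticleSphere | ParticleSpheroid | ParticleMap | ParticleAtoms
    arrival_rate: float = 1.0
    diameter_sigma: float = 0.0  # m
    flattening_range: tuple[float, float] | None = None
    position_mode: str = "fixed"
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    position_sigma: float = 0.0  # m, for position_mode='normal'
    orientation_mode: str = "fixed"
    label: str = "species"

    def __post_init__(self):
        if self.arrival_rate < 0 or self.diameter_sigma < 0:
            raise ValueError("arrival rate and diameter sigma must be non-negative")
        if self.position_mode not in ("fixed", "uniform-in-focus", "normal"):
            raise ValueError(f"unknown position mode {self.position_mode!r}")
        if self.orientation_mode not in ("fixed", "uniform"):
            raise ValueError(f"unknown orientation mode {self.orientation_mode!r}")


@dataclass
class ParticleInstance:
    """One concrete particle in one shot: all randomness resolved."""

    particle: ParticleSphere | ParticleSpheroid | ParticleMap | ParticleAtoms
    position: np.ndarray
    orientation: Rotation
    label: str = "species"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


def _truncated_normal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    if sigma == 0:
        return mean
    while True:
        x = rng.normal(mean, sigma)
        if x > 0:
            return x


def sample_shot_ensemble(species: list[SpeciesSpec], rng,
                         focus_diameter: float | None = None) -> list[ParticleInstance]:
    """Draw the particle content of one shot.

    ``rng`` is a seed or :class:`numpy.random.Generator`; given the same
    stream the result is bit-reproducible.  ``focus_diameter`` (m) is
    required by species with ``position_mode='uniform-in-focus'``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    instances: list[ParticleInstance] = []
    for spec in species:
        count = rng.poisson(spec.arrival_rate)
        for _ in range(count):
            particle = spec.template
            if isinstance(particle, ParticleSphere) and spec.diameter_sigma > 0:
                particle = replace(particle, diameter=_truncated_normal(
                    rng, particle.diameter, spec.diameter_sigma))
            elif isinstance(particle, ParticleSpheroid):
                d = _truncated_normal(rng, particle.diameter, spec.diameter_sigma)
                f = particle.flattening
                if spec.flattening_range is not None:
                    lo, hi = spec.flattening_range
                    f = rng.uniform(lo, hi)
                particle = replace(particle, diameter=d, flattening=f)

            if spec.orientation_mode == "uniform":
                orientation = Rotation.random(rng)
            else:
                orientation = getattr(particle, "orientation", Rotation.identity())
            if hasattr(particle, "orientation"):
                particle = replace(particle, orientation=orientation)

            if spec.position_mode == "fixed":
                position = np.asarray(spec.position, dtype=float)
            elif spec.position_mode == "uniform-in-focus":
                if focus_diameter is None:
                    raise ValueError("uniform-in-focus positions need a focus diameter")
                radius = focus_diameter / 2.0
                while True:
                    xy = rng.uniform(-radius, radius, size=2)
                    if xy @ xy <= radius**2:
                        break
                position = np.array([xy[0], xy[1], 0.0])
            else:  # normal
                xy = rng.normal(0.0, spec.position_sigma, size=2)
                position = np.array([xy[0], xy[1], 0.0])

            instances.append(ParticleInstance(
                particle=particle, position=position,
                orientation=orientation, label=spec.label))
    return instances


# ---------------------------------------------------------------------------
# Geometric occupancy maps

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _icosahedron_face_normals() -> np.ndarray:
    """Unit outward normals of the 20 faces (vertices of the dual)."""
    v = []
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            for s3 in (-1.0, 1.0):
                v.append((s1, s2, s3))
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            v.append((0.0, s1 / _PHI, s2 * _PHI))
            v.append((s1 / _PHI, s2 * _PHI, 0.0))
            v.append((s1 * _PHI, 0.0, s2 / _PHI))
    v = np.asarray(v)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _icosahedron_inradius_for_volume(volume: float) -> float:
    # V = c r_i^3 for a regular icosahedron with inradius r_i
    edge_per_inradius = 12.0 / (3.0 * np.sqrt(3.0) + np.sqrt(15.0))
    vol_per_edge3 = 5.0 * (3.0 + np.sqrt(5.0)) / 12.0
    c = vol_per_edge3 * edge_per_inradius**3
    return (volume / c) ** (1.0 / 3.0)


def map_from_geometry(shape: str, params: dict, dx: float,
                      material: Material, antialias: bool = True,
                      orientation: Rotation | None = None) -> ParticleMap:
    """Voxelize a filled sphere, spheroid or icosahedron.

    ``params`` holds ``diameter`` (m, of the equal-volume sphere) and,
    for spheroids, ``flattening``.  Voxels inside the body get the
    formula-unit number density of ``material``; surface voxels get a
    fractional value from the signed distance to the surface (linear
    ramp over one voxel) unless ``antialias`` is off.  The returned map
    has ``value_kind='atom_density'``.
    """
    if shape not in ("sphere", "spheroid", "icosahedron"):
        raise ValueError(f"unknown shape {shape!r}")
    diameter = float(params["diameter"])
    if diameter / dx < 8:
        raise ValueError("shape must span at least 8 voxels across")
    orientation = orientation or Rotation.identity()

    if shape == "spheroid":
        flattening = float(params.get("flattening", 1.0))
        a, _, c = spheroid_semiaxes(ParticleSpheroid(
            diameter=diameter, flattening=flattening, material=material))
        extent = 2.0 * max(a, c)
    elif shape == "icosahedron":
        # circumradius of the equal-volume icosahedron is ~0.592 d
        extent = 1.25 * diameter
    else:
        extent = diameter
    n = int(np.ceil(extent / dx)) + 4
    n += n % 2  # even grid, center between voxels

    centers = (np.arange(n) - (n - 1) / 2.0) * dx
    xg, yg, zg = np.meshgrid(centers, centers, centers, indexing="ij")
    pts = np.stack([xg, yg, zg], axis=-1).reshape(-1, 3)
    # rotate the body by R  <=>  evaluate the canonical body at R^-1 x
    pts = orientation.inverse().apply(pts)

    if shape == "sphere":
        sd = np.linalg.norm(pts, axis=1) - diameter / 2.0
    elif shape == "spheroid":
        scaled = pts / np.array([a, a, c])
        f = np.linalg.norm(scaled, axis=1)
        # first-order signed distance: (f - 1) f / |grad f|, exact for a = c
        grad = np.linalg.norm(scaled / np.array([a, a, c]), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.where(grad > 0, (f - 1.0) * f / grad, -min(a, c))
    else:
        normals = _icosahedron_face_normals()
        r_in = _icosahedron_inradius_for_volume(np.pi / 6.0 * diameter**3)
        sd = (pts @ normals.T).max(axis=1) - r_in

    if antialias:
        occupancy = np.clip(0.5 - sd / dx, 0.0, 1.0)
    else:
        occupancy = (sd <= 0).astype(float)
    occupancy = occupancy.reshape(n, n, n)

    formula_density = material.mass_density * N_AVOGADRO / material.molar_mass
    return ParticleMap(values=occupancy * formula_density, dx=dx,
                       value_kind="atom_density", material=material)
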