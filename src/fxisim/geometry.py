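"""Rotations, detector layout, and the pixel -> scattering-vector map.

The lab frame has z along the nominal beam, the detector plane
orthogonal to it at distance D, x the fast detector axis and y the slow
one.  A pixel (i, j) sits at p = ((i - cx) s, (j - cy) s, D) with s the
pixel size and (cx, cy) the (possibly fractional) beam center.  The
scattering vector of that pixel is

    q = k (s_hat - z_hat'),   k = 2 pi / lambda,

with s_hat = p/|p| the scattered direction and z_hat' the (possibly
tilted) incident direction: the detector samples the Ewald sphere of
radius k.  The 2 pi factor is part of q, so the full-period resolution
at a pixel is d = 2 pi / |q|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _SciRotation

__all__ = [
    "Rotation",
    "DetectorGeometry",
    "QMap",
    "rotation_from_euler",
    "apply_rotation",
    "qmap_from_detector",
    "resolution_at_pixel",
]

_VALID_EULER_ORDERS = {
    "xyz", "xzy", "yxz", "yzx", "zxy", "zyx",
    "xyx", "xzx", "yxy", "yzy", "zxz", "zyz",
}


class Rotation:
    """A proper rotation stored as a unit quaternion (w, x, y, z).

    Thin wrapper around scipy's rotation class fixing the conventions
    used throughout the simulator: extrinsic Euler angles, scalar-first
    quaternions, right-handed action on column vectors.
    """

    __slots__ = ("_rot",)

    def __init__(self, scipy_rotation: _SciRotation):
        self._rot = scipy_rotation

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "Rotation":
        return cls(_SciRotation.identity())

    @classmethod
    def from_euler(cls, angles, order: str = "xyz") -> "Rotation":
        """Extrinsic Euler rotation; ``order`` is one of the 12 axis triples."""
        if order not in _VALID_EULER_ORDERS:
            raise ValueError(f"invalid Euler axis order {order!r}")
        return cls(_SciRotation.from_euler(order, angles))  # lowercase = extrinsic

    @classmethod
    def from_matrix(cls, matrix) -> "Rotation":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must be 3x3 with determinant +1")
        return cls(_SciRotation.from_matrix(m))

    @classmethod
    def from_quaternion(cls, wxyz) -> "Rotation":
        w, x, y, z = np.asarray(wxyz, dtype=float)
        norm = np.sqrt(w * w + x * x + y * y + z * z)
        if norm == 0:
            raise ValueError("zero quaternion")
        return cls(_SciRotation.from_quat([x / norm, y / norm, z / norm, w / norm]))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "Rotation":
        """Uniform over SO(3): a normalized 4-D Gaussian quaternion."""
        q = rng.normal(size=4)
        return cls.from_quaternion(q)

    # -- views --------------------------------------------------------
    @property
    def quaternion(self) -> np.ndarray:
        """Unit quaternion as (w, x, y, z)."""
        x, y, z, w = self._rot.as_quat()
        return np.array([w, x, y, z])

    @property
    def matrix(self) -> np.ndarray:
        return self._rot.as_matrix()

    def as_euler(self, order: str = "xyz") -> np.ndarray:
        if order not in _VALID_EULER_ORDERS:
            raise ValueError(f"invalid Euler axis order {order!r}")
        return self._rot.as_euler(order)

    # -- algebra ------------------------------------------------------
    def apply(self, vectors) -> np.ndarray:
        return self._rot.apply(np.asarray(vectors, dtype=float))

    def inverse(self) -> "Rotation":
        return Rotation(self._rot.inv())

    def __mul__(self, other: "Rotation") -> "Rotation":
        """Composition: (r1 * r2) v == r1(r2 v)."""
        return Rotation(self._rot * other._rot)

    def __repr__(self) -> str:
        w, x, y, z = self.quaternion
        return f"Rotation(w={w:.6f}, x={x:.6f}, y={y:.6f}, z={z:.6f})"


def rotation_from_euler(angles, order: str = "xyz") -> Rotation:
    return Rotation.from_euler(angles, order)


def apply_rotation(rotation: Rotation, vectors) -> np.ndarray:
    return rotation.apply(vectors)


@dataclass
class DetectorGeometry:
    """A flat pixel-array detector orthogonal to the beam axis.

    ``mask`` is a per-pixel integer bit-field (0 = good); bit 0 marks
    invalid pixels, bit 8 is reserved for saturation flags.
    ``saturation_level`` is in photons; ``quantum_efficiency`` is a
    scalar in (0, 1].
    """

    nx: int
    ny: int
    pixel_size: float        # m
    detector_distance: float  # m
    center_x: float | None = None  # beam center, fractional pixels
    center_y: float | None = None
    mask: np.ndarray | None = None
    saturation_level: float | None = None
    quantum_efficiency: float = 1.0

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("pixel counts must be >= 1")
        if not self.pixel_size > 0 or not self.detector_distance > 0:
            raise ValueError("pixel size and detector distance must be positive")
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum efficiency must be in (0, 1]")
        if self.center_x is None:
            self.center_x = (self.nx - 1) / 2.0
        if self.center_y is None:
            self.center_y = (self.ny - 1) / 2.0
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != (self.ny, self.nx):
                raise ValueError("mask shape must be (ny, nx)")

    def pixel_positions(self) -> np.ndarray:
        """Lab-frame position of every pixel center, shape (ny, nx, 3)."""
        i = np.arange(self.nx)
        j = np.arange(self.ny)
        x = (i - self.center_x) * self.pixel_size
        y = (j - self.center_y) * self.pixel_size
        pos = np.empty((self.ny, self.nx, 3))
        pos[..., 0] = x[None, :]
        pos[..., 1] = y[:, None]
        pos[..., 2] = self.detector_distance
        return pos


@dataclass
class QMap:
    """Per-pixel scattering vectors on the Ewald sphere.

    ``q`` has shape (ny, nx, 3) in m^-1; ``theta`` is the full
    scattering angle and ``phi`` the detector azimuth.  The identity
    |q| = (4 pi / lambda) sin(theta / 2) holds at every pixel.
    """

    q: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    wavelength: float
    beam_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.q.shape[:2]

    @property
    def qnorm(self) -> np.ndarray:
        return np.linalg.norm(self.q, axis=-1)

    @property
    def wavenumber(self) -> float:
        return 2.0 * np.pi / self.wavelength


def qmap_from_detector(det: DetectorGeometry, wavelength: float,
                       beam_tilt: tuple[float, float] = (0.0, 0.0)) -> QMap:
    """Map every pixel of a detector to its scattering vector.

    ``beam_tilt`` = (tilt_x, tilt_y) in rad tilts the incident direction
    z_hat' away from the detector normal: positive tilt_x (tilt_y)
    inclines the beam toward +x (+y) on the detector, the incident
    direction being the unit vector along (tan tilt_x, tan tilt_y, 1).
    The detector itself stays fixed.
    """
    tx, ty = beam_tilt
    if abs(tx) > 0.1 or abs(ty) > 0.1:
        raise ValueError("beam tilt must stay below 0.1 rad")
    k = 2.0 * np.pi / wavelength
    beam = np.array([np.tan(tx), np.tan(ty), 1.0])
    beam /= np.linalg.norm(beam)
    pos = det.pixel_positions()
    norm = np.linalg.norm(pos, axis=-1, keepdims=True)
    s_hat = pos / norm
    q = k * (s_hat - beam)
    cos_theta = np.clip(s_hat @ beam, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    phi = np.arctan2(pos[..., 1], pos[..., 0])
    return QMap(q=q, theta=theta, phi=phi, wavelength=wavelength, beam_direction=beam)


def resolution_at_pixel(qmap: QMap, pixel: tuple[int, int]) -> float:
    """Full-period resolution d = 2 pi / |q| at pixel (j, i); inf on axis."""
    j, i = pixel
    qn = np.linalg.norm(qmap.q[j, i])
    if qn == 0:
        return np.inf
    return 2.0 * np.pi / qn
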