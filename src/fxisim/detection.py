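"""From |F(q)|^2 to photon counts: the measurement model.

The expected photon count in a pixel is

    I_pix = I0 * dOmega * P * |F|^2 * QE

with I0 the fluence (photons m^-2) at the particle, dOmega the solid
angle of the pixel, P the polarization factor and QE a scalar quantum
efficiency.  Since |F|^2 has units of area the product is a pure photon
count.  Measured counts are Poisson draws around that expectation;
masks, saturation clipping and optional Gaussian read noise follow.

Mask bits follow the CXI pixel-mask convention: bit 0 marks a pixel as
invalid/missing, bit 8 marks saturation.  Masked pixel values are
preserved and only flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .amplitudes import AmplitudePattern
from .geometry import DetectorGeometry
from .source import PhotonSource, fluence_at

__all__ = [
    "IntensityPattern",
    "ProjectionImage",
    "PIXEL_INVALID",
    "PIXEL_SATURATED",
    "solid_angle",
    "polarization_factor",
    "expected_intensity",
    "apply_poisson",
    "add_read_noise",
    "apply_mask_and_saturation",
    "projection_image",
]

PIXEL_INVALID = 1 << 0
PIXEL_SATURATED = 1 << 8

_POLARIZATION_MODES = ("horizontal", "vertical", "unpolarized", "ignore")


@dataclass
class IntensityPattern:
    """Expected and/or sampled photon counts per pixel.

    ``expected`` is the noise-free expectation (float photons),
    ``sampled`` the Poisson-noised integer counts, ``mask`` the
    per-pixel bit-field.  ``metadata`` records wavelength, detector
    distance, fluence etc. for downstream writers.
    """

    expected: np.ndarray | None = None
    sampled: np.ndarray | None = None
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = None
        if self.expected is not None:
            self.expected = np.asarray(self.expected, dtype=float)
            if np.any(self.expected < 0):
                raise ValueError("expected counts must be non-negative")
            shape = self.expected.shape
        if self.sampled is not None:
            self.sampled = np.asarray(self.sampled)
            shape = shape or self.sampled.shape
        if self.mask is None and shape is not None:
            self.mask = np.zeros(shape, dtype=np.int32)

    @property
    def shape(self):
        ref = self.expected if self.expected is not None else self.sampled
        return ref.shape


def solid_angle(det: DetectorGeometry, pixel=None):
    """Solid angle (sr) of one pixel, or of all pixels when pixel is None.

    dOmega = (pixel_size^2 / D^2) cos^3(theta'), the flat-detector
    obliquity: projected pixel area over squared distance.
    """
    pos = det.pixel_positions()
    cos_theta = det.detector_distance / np.linalg.norm(pos, axis=-1)
    omega = (det.pixel_size**2 / det.detector_distance**2) * cos_theta**3
    if pixel is None:
        return omega
    j, i = pixel
    return float(omega[j, i])


def polarization_factor(theta, phi, mode: str = "ignore"):
    """Polarization factor P(theta, phi) of the scattered intensity.

    ``theta`` is the full scattering angle, ``phi`` the detector
    azimuth.  Linear polarization along x ('horizontal') or y
    ('vertical'), the unpolarized average (1 + cos^2 theta)/2, or 1 for
    'ignore'.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if mode == "ignore":
        return np.ones(np.broadcast(theta, phi).shape)[()]
    if mode == "horizontal":
        return (1.0 - np.sin(theta) ** 2 * np.cos(phi) ** 2)[()]
    if mode == "vertical":
        return (1.0 - np.sin(theta) ** 2 * np.sin(phi) ** 2)[()]
    if mode == "unpolarized":
        return ((1.0 + np.cos(theta) ** 2) / 2.0)[()]
    raise ValueError(f"unknown polarization mode {mode!r}; valid: {_POLARIZATION_MODES}")


def expected_intensity(amp: AmplitudePattern, det: DetectorGeometry,
                       src: PhotonSource, pol_mode: str = "ignore",
                       fluence: float | None = None) -> IntensityPattern:
    """Expected photon counts: I0 * dOmega * P * |F|^2 * QE.

    ``fluence`` overrides the source's on-axis fluence (photons m^-2),
    e.g. to account for pulse-energy jitter already sampled upstream.
    """
    if abs(amp.qmap.wavelength - src.wavelength) > 1e-9 * src.wavelength:
        raise ValueError("amplitude q-map and source disagree on the wavelength")
    i0 = fluence_at(src, (0.0, 0.0)) if fluence is None else fluence
    omega = solid_angle(det)
    pol = polarization_factor(amp.qmap.theta, amp.qmap.phi, pol_mode)
    expected = i0 * omega * pol * amp.intensity * det.quantum_efficiency
    mask = det.mask.astype(np.int32).copy() if det.mask is not None else None
    return IntensityPattern(
        expected=expected, mask=mask,
        metadata={
            "wavelength": src.wavelength,
            "photon_energy_ev": src.photon_energy,
            "detector_distance": det.detector_distance,
            "pixel_size": det.pixel_size,
            "fluence": float(i0),
            "polarization": pol_mode,
            "quantum_efficiency": det.quantum_efficiency,
        })


def apply_poisson(pattern: IntensityPattern, rng) -> IntensityPattern:
    """Draw per-pixel independent Poisson counts around the expectation."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if pattern.expected is None:
        raise ValueError("pattern has no expectation to sample from")
    if not np.all(np.isfinite(pattern.expected)):
        raise ValueError("expected counts must be finite")
    sampled = rng.poisson(pattern.expected).astype(np.int64)
    return replace(pattern, sampled=sampled)


def add_read_noise(pattern: IntensityPattern, sigma: float, rng) -> IntensityPattern:
    """Additive Gaussian read noise (photon units) on the sampled counts.

    Applied after Poisson sampling, rounded to integers, floored at 0.
    """
    if sigma == 0 or pattern.sampled is None:
        return pattern
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    noisy = pattern.sampled + rng.normal(0.0, sigma, size=pattern.sampled.shape)
    return replace(pattern, sampled=np.maximum(np.rint(noisy), 0).astype(np.int64))


def apply_mask_and_saturation(pattern: IntensityPattern,
                              det: DetectorGeometry) -> IntensityPattern:
    """Clip counts above the saturation level and propagate mask bits.

    Saturated pixels are clipped to the level and flagged with the
    saturation bit; detector mask bits are OR-ed into the pattern mask.
    Values under the mask are preserved, only flagged.
    """
    mask = pattern.mask.copy() if pattern.mask is not None else \
        np.zeros(pattern.shape, dtype=np.int32)
    if det.mask is not None:
        mask |= det.mask.astype(np.int32)
    sampled = pattern.sampled
    if det.saturation_level is not None and sampled is not None:
        over = sampled > det.saturation_level
        sampled = np.where(over, int(det.saturation_level), sampled)
        mask = mask | np.where(over, PIXEL_SATURATED, 0).astype(np.int32)
    return replace(pattern, sampled=sampled, mask=mask)


@dataclass
class ProjectionImage:
    """Real-space projection: complex image and its pixel sizes (m)."""

    values: np.ndarray
    pixel_size_x: float
    pixel_size_y: float
    warnings: list[str] = field(default_factory=list)


def projection_image(amp: AmplitudePattern, max_angle_deg: float = 5.0) -> ProjectionImage:
    """Real-space projection by inverse transform of the far-field amplitude.

    In the small-angle regime the Ewald sphere is nearly flat, so the
    detector samples a regular transverse q grid and the 2-D inverse DFT
    of F is the projected scattering potential.  The real-space pixel
    size is 2 pi / (N dq) per axis.  Outside the small-angle regime a
    warning flag is set (the flat-grid assumption degrades).
    """
    q = amp.qmap.q
    ny, nx = amp.qmap.shape
    j0, i0 = np.unravel_index(np.argmin(amp.qmap.qnorm), (ny, nx))
    i1 = i0 + 1 if i0 + 1 < nx else i0 - 1
    j1 = j0 + 1 if j0 + 1 < ny else j0 - 1
    dqx = abs(q[j0, i1, 0] - q[j0, i0, 0])
    dqy = abs(q[j1, i0, 1] - q[j0, i0, 1])
    warnings = []
    max_theta = float(np.max(amp.qmap.theta))
    if np.degrees(max_theta) > max_angle_deg:
        warnings.append(
            f"max scattering angle {np.degrees(max_theta):.2f} deg exceeds the "
            f"small-angle regime ({max_angle_deg} deg); projection is approximate")
    qx = q[j0, :, 0]   # center row
    qy = q[:, i0, 1]   # center column
    dx_real = 2.0 * np.pi / (nx * dqx)
    dy_real = 2.0 * np.pi / (ny * dqy)
    x = (np.arange(nx) - nx // 2) * dx_real
    y = (np.arange(ny) - ny // 2) * dy_real
    ax = np.exp(1j * np.outer(x, qx)) / nx          # (nx, nx)
    ay = np.exp(1j * np.outer(y, qy)) / ny          # (ny, ny)
    img = ay @ amp.values @ ax.T
    return ProjectionImage(values=img, pixel_size_x=dx_real, pixel_size_y=dy_real,
                           warnings=warnings)
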