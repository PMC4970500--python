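"""The photon source: wavelength and fluence at the interaction point.

One femtosecond pulse delivers ``pulse_energy / photon_energy`` photons
into a focus of stated diameter.  The fluence (photons per area) at a
transverse position in the focal plane is what scales the expected
photon counts on the detector; it is the I0 of the detection model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EV
from .materials import energy_from_wavelength, wavelength_from_energy

__all__ = ["PhotonSource", "photons_per_pulse", "fluence_at", "sample_pulse_energy"]

_PROFILES = ("flat-top", "gaussian")


@dataclass
class PhotonSource:
    """Monochromatic plane-wave source focused to a small spot.

    Specify either ``photon_energy`` (eV) or ``wavelength`` (m); the
    other is derived.  ``profile`` selects the transverse fluence model:
    ``flat-top`` (uniform disc of diameter ``focus_diameter``, the
    default) or ``gaussian`` (FWHM = ``focus_diameter``, integrating to
    the photon number).  ``pulse_energy_jitter_sigma`` (J) adds optional
    normal-distributed pulse-energy jitter, truncated at zero.
    """

    pulse_energy: float  # J
    focus_diameter: float  # m
    photon_energy: float | None = None  # eV
    wavelength: float | None = None  # m
    profile: str = "flat-top"
    pulse_energy_jitter_sigma: float = 0.0  # J

    def __post_init__(self):
        if (self.photon_energy is None) == (self.wavelength is None):
            raise ValueError("specify exactly one of photon_energy and wavelength")
        if self.photon_energy is None:
            self.photon_energy = energy_from_wavelength(self.wavelength)
        else:
            self.wavelength = wavelength_from_energy(self.photon_energy)
        if not (self.pulse_energy > 0 and self.focus_diameter > 0 and self.photon_energy > 0):
            raise ValueError("pulse energy, focus diameter and photon energy must be positive")
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {_PROFILES}, got {self.profile!r}")
        if self.pulse_energy_jitter_sigma < 0:
            raise ValueError("pulse-energy jitter sigma must be non-negative")


def photons_per_pulse(src: PhotonSource, pulse_energy: float | None = None) -> float:
    """Photon number N = pulse_energy / photon_energy."""
    e_pulse = src.pulse_energy if pulse_energy is None else pulse_energy
    return e_pulse / (src.photon_energy * EV)


def fluence_at(src: PhotonSource, transverse_position=(0.0, 0.0),
               pulse_energy: float | None = None) -> float | np.ndarray:
    """Fluence (photons m^-2) at a transverse position in the focal plane.

    flat-top: N / (pi (d/2)^2) inside the focus, 0 outside.
    gaussian: 2-D Gaussian with FWHM = focus diameter, integrating to N.
    """
    n = photons_per_pulse(src, pulse_energy)
    xy = np.asarray(transverse_position, dtype=float)
    r2 = np.sum(xy * xy, axis=-1)
    if src.profile == "flat-top":
        radius = src.focus_diameter / 2.0
        peak = n / (np.pi * radius**2)
        return np.where(r2 <= radius**2, peak, 0.0)[()]
    sigma = src.focus_diameter / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return (n / (2.0 * np.pi * sigma**2) * np.exp(-r2 / (2.0 * sigma**2)))[()]


def sample_pulse_energy(src: PhotonSource, rng: np.random.Generator) -> float:
    """Per-shot pulse energy with optional normal jitter, truncated > 0."""
    if src.pulse_energy_jitter_sigma == 0:
        return src.pulse_energy
    while True:
        e = rng.normal(src.pulse_energy, src.pulse_energy_jitter_sigma)
        if e > 0:
            return e
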