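"""Scattering amplitudes: oracles, analytic forms, and Fourier properties."""

import numpy as np
import pytest
from scipy.optimize import brentq

import fxisim as fx
from fxisim.amplitudes import brute_force_dft, map_nbar
from fxisim.constants import R_ELECTRON
from fxisim.geometry import Rotation

E0 = 1000.0


@pytest.fixture(scope="module")
def water():
    return fx.builtin_materials()["water"]


class TestBruteForceDft:
    def test_empty_point_set(self, qmap32):
        amp = brute_force_dft(np.empty((0, 3)), np.empty(0), qmap32)
        assert np.all(amp.values == 0)

    def test_single_unit_point_at_origin(self, qmap32):
        amp = brute_force_dft([[0, 0, 0]], [1.0], qmap32)
        assert np.allclose(amp.values, 1.0, atol=1e-15)

    def test_conjugate_symmetry_for_real_weights(self, qmap32, rng):
        pts = rng.uniform(-2e-9, 2e-9, (20, 3))
        amp = brute_force_dft(pts, np.ones(20), qmap32)
        v = amp.values
        # q_xy(-pixel) = -q_xy(pixel) but q_z is shared: restrict to a
        # symmetric flat sub-map where the curvature term is negligible
        flat = fx.QMap(q=qmap32.q * [1, 1, 0], theta=qmap32.theta,
                       phi=qmap32.phi, wavelength=qmap32.wavelength)
        v = brute_force_dft(pts, np.ones(20), flat).values
        assert np.allclose(v, np.conj(v[::-1, ::-1]), rtol=1e-10, atol=1e-12)


class TestAmplitudeAtoms:
    def test_single_atom_is_flat(self, qmap32):
        p = fx.ParticleAtoms(positions=[[0, 0, 0]], elements=[6])
        amp = fx.amplitude_atoms(p, qmap32, E0)
        expected = R_ELECTRON * abs(fx.atomic_scattering_factor(6, E0))
        assert np.allclose(np.abs(amp.values), expected, rtol=1e-12)

    def test_two_atom_interference(self, qmap32):
        d = np.array([3e-9, 0, 0])
        p = fx.ParticleAtoms(positions=[d / 2, -d / 2], elements=[6, 6])
        amp = fx.amplitude_atoms(p, qmap32, E0)
        f = fx.atomic_scattering_factor(6, E0)
        qd = qmap32.q @ d
        expected = (R_ELECTRON * abs(f)) ** 2 * 4 * np.cos(qd / 2) ** 2
        assert np.allclose(np.abs(amp.values) ** 2, expected, rtol=1e-9, atol=1e-40)

    def test_fast_path_matches_oracle(self, qmap32, rng):
        pos = rng.uniform(-4e-9, 4e-9, (50, 3))
        els = rng.choice([1, 6, 7, 8, 16], 50)
        p = fx.ParticleAtoms(positions=pos, elements=els)
        fast = fx.amplitude_atoms(p, qmap32, E0)
        w = np.array([R_ELECTRON * fx.atomic_scattering_factor(int(z), E0) for z in els])
        oracle = brute_force_dft(pos, w, qmap32)
        scale = np.abs(oracle.values).max()
        assert np.max(np.abs(fast.values - oracle.values)) / scale < 1e-9

    def test_untabulated_element_raises(self, qmap32):
        p = fx.ParticleAtoms(positions=[[0, 0, 0]], elements=[92])
        with pytest.raises(ValueError):
            fx.amplitude_atoms(p, qmap32, E0)

    def test_rotation_equivariance(self, qmap32, rng):
        # rotating the particle equals evaluating the unrotated particle
        # at inverse-rotated q
        pos = rng.uniform(-3e-9, 3e-9, (30, 3))
        p = fx.ParticleAtoms(positions=pos, elements=np.full(30, 6))
        rot = Rotation.random(rng)
        rotated = fx.amplitude_atoms(
            fx.ParticleAtoms(positions=pos, elements=np.full(30, 6), orientation=rot),
            qmap32, E0)
        counter = fx.QMap(q=rot.inverse().apply(qmap32.q.reshape(-1, 3)).reshape(qmap32.q.shape),
                          theta=qmap32.theta, phi=qmap32.phi,
                          wavelength=qmap32.wavelength)
        unrotated = fx.amplitude_atoms(p, counter, E0)
        scale = np.abs(unrotated.values).max()
        assert np.max(np.abs(rotated.values - unrotated.values)) / scale < 1e-9


class TestAmplitudeMap:
    def make_map(self, values, dx=1e-9, **kw):
        return fx.ParticleMap(values=values, dx=dx,
                              value_kind="electron_density", **kw)

    def test_single_voxel_is_flat(self, qmap32, wavelength):
        n = 8
        vals = np.zeros((n, n, n))
        vals[4, 4, 4] = 1e30  # electrons / m^3
        p = self.make_map(vals)
        amp = fx.amplitude_map(p, qmap32, wavelength)
        k = 2 * np.pi / wavelength
        nbar = R_ELECTRON * wavelength**2 / (2 * np.pi) * 1e30
        expected = k**2 / (2 * np.pi) * p.dx**3 * nbar
        assert np.allclose(np.abs(amp.values), expected, rtol=1e-12)

    def test_two_voxel_fringe_period(self, wavelength):
        # two voxels m*dx apart along x: intensity ~ cos^2(q_x m dx / 2)
        n, m, dx = 16, 6, 1e-9
        vals = np.zeros((n, n, n))
        vals[5, 8, 8] = vals[5 + m, 8, 8] = 1e30
        det = fx.DetectorGeometry(nx=64, ny=1, pixel_size=300e-6,
                                  detector_distance=0.74, center_y=0.0)
        qm = fx.qmap_from_detector(det, wavelength)
        amp = fx.amplitude_map(self.make_map(vals, dx), qm, wavelength)
        intensity = np.abs(amp.values[0]) ** 2
        qx = qm.q[0, :, 0]
        # normalized fringe: maxima where q_x m dx = 2 pi j
        modulation = intensity / intensity.max()
        expected = np.cos(qx * m * dx / 2) ** 2
        assert np.allclose(modulation, expected, atol=5e-3)

    def test_fast_path_matches_oracle(self, qmap32, wavelength, rng):
        n = 16
        vals = rng.uniform(0, 1e30, (n, n, n))
        p = self.make_map(vals)
        fast = fx.amplitude_map(p, qmap32, wavelength)
        k = 2 * np.pi / wavelength
        nbar = map_nbar(p, wavelength).ravel()
        centers = (np.arange(n) - (n - 1) / 2) * p.dx
        xg, yg, zg = np.meshgrid(centers, centers, centers, indexing="ij")
        pts = np.stack([xg, yg, zg], -1).reshape(-1, 3)
        oracle = brute_force_dft(pts, k**2 / (2 * np.pi) * p.dx**3 * nbar, qmap32)
        scale = np.abs(oracle.values).max()
        assert np.max(np.abs(fast.values - oracle.values)) / scale < 1e-9

    def test_linearity(self, qmap32, wavelength, rng):
        a = self.make_map(rng.uniform(0, 1e30, (8, 8, 8)))
        b = self.make_map(rng.uniform(0, 1e30, (8, 8, 8)))
        ab = self.make_map(a.values + b.values)
        total = fx.amplitude_map(ab, qmap32, wavelength).values
        parts = fx.amplitude_map(a, qmap32, wavelength).values \
            + fx.amplitude_map(b, qmap32, wavelength).values
        assert np.allclose(total, parts, rtol=1e-12)

    def test_undersampling_warning(self, qmap64, wavelength):
        coarse = self.make_map(np.ones((8, 8, 8)) * 1e28, dx=60e-9)
        amp = fx.amplitude_map(coarse, qmap64, wavelength)
        assert amp.warnings

    def test_friedel_symmetry_real_and_absorbing(self, wavelength):
        # flat symmetric q grid: real nbar gives I(q) = I(-q); complex
        # nbar (absorption) breaks it
        det = fx.DetectorGeometry(nx=16, ny=16, pixel_size=300e-6,
                                  detector_distance=0.74)
        qm = fx.qmap_from_detector(det, wavelength)
        flat = fx.QMap(q=qm.q * [1, 1, 0], theta=qm.theta, phi=qm.phi,
                       wavelength=wavelength)
        rng = np.random.default_rng(2)
        real_map = self.make_map(rng.uniform(0, 1e30, (8, 8, 8)))
        i_real = np.abs(fx.amplitude_map(real_map, flat, wavelength).values) ** 2

        def rel_asymmetry(i):
            return np.abs(i - i[::-1, ::-1]).max() / i.max()

        assert rel_asymmetry(i_real) < 1e-9
        complex_map = fx.ParticleMap(
            values=1.0 - 1e-4 * rng.uniform(0, 1, (8, 8, 8))
            - 1e-5j * rng.uniform(0, 1, (8, 8, 8)),
            dx=1e-9, value_kind="refractive_index")
        i_abs = np.abs(fx.amplitude_map(complex_map, flat, wavelength).values) ** 2
        assert rel_asymmetry(i_abs) > 1e-6


class TestAmplitudeSphere:
    def test_forward_scattering_is_total_scattering_length(self, water, wavelength):
        det = fx.DetectorGeometry(nx=3, ny=3, pixel_size=1e-4,
                                  detector_distance=1.0, center_x=1, center_y=1)
        qm = fx.qmap_from_detector(det, wavelength)
        d = 40e-9
        amp = fx.amplitude_sphere(fx.ParticleSphere(diameter=d, material=water),
                                  qm, wavelength)
        k = 2 * np.pi / wavelength
        nbar = fx.refractive_index_from_atom_density(
            water, fx.energy_from_wavelength(wavelength)).nbar
        s_total = k**2 / (2 * np.pi) * nbar * 4 / 3 * np.pi * (d / 2) ** 3
        assert amp.values[1, 1] == pytest.approx(s_total, rel=1e-12)

    def test_first_zero_location(self, water, wavelength, qmap64):
        # independent oracle: smallest positive root of tan x = x
        root = brentq(lambda x: np.sin(x) - x * np.cos(x), 3.5, 5.5, xtol=1e-12)
        assert root == pytest.approx(4.493409, abs=1e-6)
        d = 40e-9
        amp = fx.amplitude_sphere(fx.ParticleSphere(diameter=d, material=water),
                                  qmap64, wavelength)
        qr = qmap64.qnorm * d / 2
        # amplitude changes sign across the root
        shape = (amp.values / amp.values[32, 32]).real
        before = shape[(qr > root - 0.3) & (qr < root - 0.05)]
        after = shape[(qr > root + 0.05) & (qr < root + 0.3)]
        assert np.all(before > 0) and np.all(after < 0)

    def test_voxelized_sphere_matches_analytic(self, water, wavelength, qmap64):
        d = 40e-9
        analytic = fx.amplitude_sphere(fx.ParticleSphere(diameter=d, material=water),
                                       qmap64, wavelength)
        pmap = fx.map_from_geometry("sphere", {"diameter": d}, d / 32, water)
        voxel = fx.amplitude_map(pmap, qmap64, wavelength)
        qr = qmap64.qnorm * d / 2
        sel = qr <= 10
        err = np.abs(voxel.values[sel] - analytic.values[sel])
        assert err.max() / np.abs(analytic.values[sel]).max() < 0.01


class TestAmplitudeSpheroid:
    def test_degenerate_flattening_is_sphere(self, water, wavelength, qmap64, rng):
        d = 40e-9
        sphere = fx.amplitude_sphere(fx.ParticleSphere(diameter=d, material=water),
                                     qmap64, wavelength)
        spheroid = fx.amplitude_spheroid(
            fx.ParticleSpheroid(diameter=d, flattening=1.0, material=water,
                                orientation=Rotation.random(rng)),
            qmap64, wavelength)
        scale = np.abs(sphere.values).max()
        assert np.max(np.abs(spheroid.values - sphere.values)) / scale < 1e-12

    def test_axis_limits(self, water, wavelength):
        # q along the symmetry axis probes R = c; equatorial q probes R = a
        p = fx.ParticleSpheroid(diameter=40e-9, flattening=0.7, material=water)
        a, _, c = fx.spheroid_semiaxes(p)
        qn = 2e8
        qmap_ax = fx.QMap(q=np.array([[[0.0, 0.0, qn]]]), theta=np.zeros((1, 1)),
                          phi=np.zeros((1, 1)), wavelength=wavelength)
        qmap_eq = fx.QMap(q=np.array([[[qn, 0.0, 0.0]]]), theta=np.zeros((1, 1)),
                          phi=np.zeros((1, 1)), wavelength=wavelength)
        amp_ax = fx.amplitude_spheroid(p, qmap_ax, wavelength).values[0, 0]
        amp_eq = fx.amplitude_spheroid(p, qmap_eq, wavelength).values[0, 0]

        def sphere_shape(u):
            return 3 * (np.sin(u) - u * np.cos(u)) / u**3

        k = 2 * np.pi / wavelength
        nbar = fx.refractive_index_from_atom_density(
            water, fx.energy_from_wavelength(wavelength)).nbar
        s_total = k**2 / (2 * np.pi) * nbar * 4 / 3 * np.pi * a * a * c
        assert amp_ax == pytest.approx(s_total * sphere_shape(qn * c), rel=1e-10)
        assert amp_eq == pytest.approx(s_total * sphere_shape(qn * a), rel=1e-10)

    def test_random_orientation_matches_voxel_map(self, water, wavelength, qmap64):
        rng = np.random.default_rng(8)
        rot = Rotation.random(rng)
        p = fx.ParticleSpheroid(diameter=40e-9, flattening=0.8, material=water,
                                orientation=rot)
        analytic = fx.amplitude_spheroid(p, qmap64, wavelength)
        pmap = fx.map_from_geometry(
            "spheroid", {"diameter": 40e-9, "flattening": 0.8}, 40e-9 / 32, water,
            orientation=rot)
        voxel = fx.amplitude_map(pmap, qmap64, wavelength)
        a, _, c = fx.spheroid_semiaxes(p)
        u = qmap64.qnorm * max(a, c)
        sel = u <= 10
        err = np.abs(voxel.values[sel] - analytic.values[sel])
        assert err.max() / np.abs(analytic.values[sel]).max() < 0.01


class TestSuperpose:
    def test_single_particle_at_origin_unchanged(self, water, wavelength, qmap64):
        amp = fx.amplitude_sphere(fx.ParticleSphere(diameter=40e-9, material=water),
                                  qmap64, wavelength)
        total = fx.superpose([(amp, np.zeros(3))])
        assert np.allclose(total.values, amp.values, rtol=1e-15)

    def test_translation_preserves_modulus(self, water, wavelength, qmap64, rng):
        amp = fx.amplitude_sphere(fx.ParticleSphere(diameter=40e-9, material=water),
                                  qmap64, wavelength)
        shift = rng.uniform(-1e-7, 1e-7, 3)
        moved = fx.superpose([(amp, shift)])
        assert np.allclose(np.abs(moved.values), np.abs(amp.values), rtol=1e-12)

    def test_two_sphere_fringes(self, water, wavelength, qmap64):
        amp = fx.amplitude_sphere(fx.ParticleSphere(diameter=40e-9, material=water),
                                  qmap64, wavelength)
        d = np.array([0.0, 8e-8, 0.0])
        pair = fx.superpose([(amp, d / 2), (amp, -d / 2)])
        qd = qmap64.q @ d
        expected = 4 * np.abs(amp.values) ** 2 * np.cos(qd / 2) ** 2
        assert np.allclose(np.abs(pair.values) ** 2, expected, rtol=1e-9, atol=1e-40)

    def test_illumination_weighting(self, water, wavelength, qmap64):
        src = fx.PhotonSource(photon_energy=1000.0, pulse_energy=1e-3,
                              focus_diameter=1e-6, profile="gaussian")
        amp = fx.amplitude_sphere(fx.ParticleSphere(diameter=40e-9, material=water),
                                  qmap64, wavelength)
        off_axis = np.array([0.5e-6, 0.0, 0.0])  # FWHM radius: half fluence
        weighted = fx.superpose([(amp, off_axis)], source=src)
        assert np.allclose(np.abs(weighted.values),
                           np.abs(amp.values) / np.sqrt(2), rtol=1e-9)

    def test_mismatched_qmaps_rejected(self, water, wavelength, qmap64, qmap32):
        a64 = fx.amplitude_sphere(fx.ParticleSphere(diameter=40e-9, material=water),
                                  qmap64, wavelength)
        a32 = fx.amplitude_sphere(fx.ParticleSphere(diameter=40e-9, material=water),
                                  qmap32, wavelength)
        with pytest.raises(ValueError):
            fx.superpose([(a64, np.zeros(3)), (a32, np.zeros(3))])
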