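# fxisim

A forward simulator for **flash X-ray imaging (FXI)**: single-particle
coherent diffractive imaging with femtosecond X-ray free-electron-laser
pulses.  Given an X-ray source, one or more sample-particle models and a
pixel-array detector, `fxisim` computes the far-field coherent
scattering amplitude at each detector pixel on the Ewald sphere and
converts it to expected and Poisson-sampled photon counts, writing
standard CXI/HDF5 imaging files.

It is aimed at people who plan or analyse FXI experiments: estimating
achievable signal for a given source and sample, generating labelled
synthetic data sets for algorithm development (orientation recovery,
phase retrieval, hit classification), and teaching the basics of
coherent X-ray diffraction.

## Model

Within the first-order Born approximation, for a frozen sample
illuminated by a monochromatic plane wave, a detector pixel in
direction **ŝ** samples the Fourier transform of the scattering
potential at the scattering vector

    q = k (ŝ − ŝ₀),   k = 2π/λ,

i.e. on an Ewald sphere of radius *k*.  The amplitude (in meters of
scattering length) is computed from one of four sample models:

* **atoms** — F(q) = r₀ Σ_a f_a(λ) Σ_i exp(−i q·R r_i), with f_a the
  complex, angle-independent atomic scattering factor (f₁ + i f₂,
  energy-interpolated from bundled plain-text tables) and R the
  particle orientation;
* **voxel map** — F(q) = (k²/2π) Δx³ Σ_j n̄_j exp(−i q·R x_j), where
  n̄ = 1 − n is the complemented refractive index, obtained from
  electron densities via n = 1 − r₀λ²ρₑ/2π or from per-species atom
  densities via n = 1 − (r₀λ²/2π) Σ_a ρ_a f_a;
* **sphere / spheroid** — the closed form
  F(q) = s_tot · 3[sin u − u cos u]/u³ with u = qR (spheres) or
  u = |q|·√(a²sin²ψ + c²cos²ψ) (spheroids).

Multiple particles superpose coherently with position phase ramps and
illumination weights.  The expected photon count per pixel is

    I_pix = I₀ · ΔΩ · P · |F(q)|² · QE

(Eq.-of-measurement: fluence × solid angle × polarization factor ×
cross-section × quantum efficiency), followed by Poisson shot noise,
optional Gaussian read noise, saturation clipping and missing-data
masks.  Stochastic per-shot sample ensembles (Poisson arrival
statistics, size/shape jitter, uniform random orientations, random
positions in the focus) are first-class and the resolved ground truth
of every shot is stored alongside the data.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and known limitations.

## Worked example

```python
import fxisim as fx

src = fx.PhotonSource(photon_energy=1200.0,      # eV
                      pulse_energy=1e-3,          # J
                      focus_diameter=0.5e-6)      # m
det = fx.DetectorGeometry(nx=128, ny=128, pixel_size=300e-6,
                          detector_distance=0.74, saturation_level=20000)
water = fx.builtin_materials()["water"]
droplet = fx.SpeciesSpec(
    template=fx.ParticleSpheroid(diameter=30e-9, flattening=0.9, material=water),
    arrival_rate=0.9, diameter_sigma=3e-9, flattening_range=(0.8, 1.0),
    position_mode="uniform-in-focus", orientation_mode="uniform", label="droplet")

exp = fx.Experiment(source=src, species=[droplet], detector=det, seed=4)
for i in range(3):
    shot = exp.propagate(i)
    print(f"shot {i}: {len(shot.particles)} particle(s), "
          f"{shot.intensity.expected.sum():.3g} expected photons, "
          f"peak pixel {shot.intensity.sampled.max()} counts")
fx.write_cxi([exp.propagate(i) for i in range(3)], "example.cxi")
```

prints

```
shot 0: 3 particle(s), 1.59e+07 expected photons, peak pixel 5117 counts
shot 1: 2 particle(s), 1.48e+07 expected photons, peak pixel 3841 counts
shot 2: 2 particle(s), 1.5e+07 expected photons, peak pixel 3693 counts
```

Each shot draws its own Poisson particle count (rate 0.9), droplet
sizes (normal around 30 nm), flattenings (uniform in 0.8–1.0),
positions and orientations; the expected photon number varies with the
sampled ensemble, and the peak pixel is a noisy count near the beam
center.  `example.cxi` contains the detector frames, mask, geometry,
source metadata and the per-shot ground truth.

The same experiment can be driven from a config file:

```
fxisim --config fxisim.conf --shots 100 --seed 1 --output run.cxi
```

with an INI file holding `[source]`, `[particle_*]` and `[detector]`
sections (see `fxisim.io_cli` for every key, default and unit; all
quantities are SI).

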