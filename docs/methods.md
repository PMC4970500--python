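# Methods

## Physical model and assumptions

`fxisim` predicts single-shot far-field coherent diffraction from an
isolated particle in vacuum under four assumptions:

1. **First-order Born approximation.**  Samples are at most a few
   hundred nanometres thick and interact weakly with X-rays; the
   perturbation of the primary wave inside the sample is neglected.
   No multiple scattering, no near-field propagation.
2. **Frozen sample.**  The femtosecond pulse outruns radiation-damage
   dynamics, so the scattering potential is static over the pulse.
3. **Monochromatic plane-wave illumination.**  No temporal structure,
   no partial coherence.  The unscattered direct beam and the global
   spherical-wave phase factor exp(ikr)/r are dropped: only relative
   phases across the detector are meaningful, and the forward beam is
   never measured in practice.
4. **Elastic scattering only.**  Compton scattering is neglected
   (valid far below 511 keV), and the atomic scattering factor is
   taken angle independent (forward-scattering approximation), valid
   while the target resolution is well above atomic length scales —
   which is the FXI regime (nanometres).  This is the main known
   limitation of the atomic model at sub-nanometre resolution.

A flat detector orthogonal to the nominal beam axis at distance D
samples the Ewald sphere: pixel (i, j) at
p = ((i − cx)s, (j − cy)s, D) sees q = k(p/|p| − ẑ′) with k = 2π/λ and
ẑ′ the (possibly tilted) incident direction.  The 2π factor is part of
q; full-period resolution is d = 2π/|q|.  q is evaluated at pixel
centers; no sub-pixel integration is performed.  Beam tilt rotates ẑ′
only (the detector stays fixed) and is sampled per shot from a 2-D
normal with user-set sigma.

## Scattering factors and materials

Per-element complex scattering factors f = f₁ + i f₂ are bundled as
plain-text `.nff`-layout tables (energy eV, f1, f2 per line; 160
log-spaced samples over 100 eV–30 keV for 15 elements: H, C, N, O, Na,
Mg, P, S, Cl, K, Ca, Mn, Fe, Zn, Se), generated by
`scripts/make_sf_tables.py` from the Cromer–Liberman anomalous
scattering algorithm (f₁ = Z + f′, f₂ = f″).  Cromer–Liberman is not
defined below Z = 3, so hydrogen uses f = Z = 1 with zero absorption —
an excellent approximation at X-ray energies.  Lookups interpolate
linearly in energy and refuse to extrapolate; sharp near-edge fine
structure between the log-spaced nodes is smoothed and is out of scope.

Built-in optical media (water, protein, DNA, lipid, cell, virus
particle) carry a mass density and a relative stoichiometric
composition; both are plain editable data, not hard truths.  The two
density conversions are

* electron density:  n = 1 − r₀λ²ρₑ/2π  (purely real — an electron
  density carries no absorption information), and
* atom density:  n = 1 − (r₀λ²/2π) Σ_a ρ_a f_a(λ),

with r₀ = 2.8179403×10⁻¹⁵ m.  They coincide exactly in the
high-energy limit f → Z, which is asserted in the tests.

**Sign convention.**  n = 1 − δ − iβ with δ, β ≥ 0, so that the
complemented index n̄ = 1 − n = δ + iβ carries the same phase
convention as f = f₁ + i f₂ under the exp(−i q·r) transform used for
the amplitudes.  β ≥ 0 encodes absorption.

## Amplitude evaluation

All amplitudes are scattering lengths (meters), so that
I₀·ΔΩ·|F|² closes to a photon count:

* one free electron: r₀;  one atom: r₀ f;  one voxel:
  (k²/2π) n̄ Δx³ — the normalization that makes the three particle
  representations mutually consistent (a uniform sphere computed
  analytically, as a voxel map, and as pseudo-atoms packed at the
  material's number density agrees in |F|² to well under 2% RMS).

The nonuniform DFT over the Ewald-sphere q points is evaluated as an
exact blocked dense matrix product (blocking only bounds memory, about
32 MB per block).  A deliberately literal term-by-term sum,
`brute_force_dft`, serves as the testing oracle for every fast path;
the fast paths match it to better than 10⁻⁹ relative (measured ~10⁻¹⁵).
A nonuniform-FFT backend would be a drop-in performance optimization,
not a semantic change, and is not shipped; GPU acceleration is out of
scope.

Particle orientation is applied without resampling: rotating a
particle by R is evaluated as the unrotated particle at R⁻¹q
(equivariance is asserted to 10⁻⁹).  Rotations are stored as unit
quaternions with constructors from extrinsic Euler triples (all 12 axis
orders, order string explicit — no hidden default convention), 3×3
matrices and quaternions; uniform random orientations come from
normalized 4-D Gaussian quaternions.

Voxelized shapes (sphere, spheroid, icosahedron) get antialiased edges:
surface voxels receive fractional occupancy from a first-order signed
distance (linear ramp over one voxel).  This suppresses edge ringing in
the discretized transform; a hard-edge mode exists for oracle
comparisons.  The spheroid's `flattening` is defined here as c/a of the
symmetry semi-axis over the equatorial one, volume-preserving against
the nominal equal-volume-sphere diameter: a = (d/2)f^(−1/3),
c = (d/2)f^(2/3).  The icosahedron is sized by its equal-volume-sphere
diameter.

## Detection model

Expected counts: I_pix = I₀·ΔΩ·P·|F|²·QE, with

* I₀ — fluence (photons m⁻²) of the shot at the focus; flat-top
  profile by default (uniform disc of the focus diameter), optional
  Gaussian with FWHM = focus diameter integrating to the pulse's
  photon number.  "Intensity" always means fluence at the reference
  (on-axis) point; off-axis particles are weighted by
  √(fluence ratio) inside the coherent superposition.
* ΔΩ = (s²/D²)cos³θ′ — flat-detector solid angle (projected pixel
  area over squared distance); the cos³ obliquity is our explicit
  choice of pixel model.
* P — polarization factor; modes horizontal/vertical
  (P = 1 − sin²θ·trig²φ), unpolarized ((1+cos²θ)/2) and **ignore
  (P = 1), which is the default** since no canonical beamline
  polarization is assumed — set it explicitly when it matters.
* QE — a scalar quantum efficiency; placed multiplicatively on the
  expectation, before noise.  No charge sharing, cross-talk or
  per-pixel gain maps.

Poisson sampling is per-pixel independent and seeded.  Optional
Gaussian read noise (sigma in photon units) is applied after Poisson
sampling, rounded to integers, floored at zero.  Saturation clips
counts at the configured level and sets mask bit 8; missing-data masks
use bit 0; masked values are preserved and only flagged (CXI pixel-mask
bit convention).  Parasitic-scattering backgrounds are left to the user
as additive arrays.

The real-space projection utility inverts the far-field amplitudes on
the detector grid treated as a flat transverse q grid (two exact
separable inverse transforms, handling fractional beam centers);
real-space pixel size is 2π/(NΔq).  This is meaningful only in the
small-angle regime — beyond ~5° maximum scattering angle a warning
flag is set.  The residual imaginary part of the projection of a real
potential measures the Ewald-curvature phase kθ²z/2 and vanishes in
the flat-grid limit.

## Stochastic ensembles and reproducibility

A species spec holds a template particle plus distributions: Poisson
arrival rate per shot, truncated-normal diameter jitter (resampled
until positive), uniform flattening range, position mode (fixed /
uniform inside the focus disc / transverse normal), orientation mode
(fixed / uniform over SO(3)).  One `propagate(config, shot_index,
seed)` call derives its generator from SeedSequence([seed,
shot_index]): shots are independent, individually reproducible, and a
re-run is bit-identical.  Every shot's resolved ground truth (concrete
diameters, flattenings, positions, quaternions, species labels, beam
tilt, pulse energy) is returned and written to the output file under
the non-standard `/entry_1/simulation_1` group, because the main
downstream use of a simulator is algorithm development on labelled
data.  Re-running the deterministic core on the recorded ground truth
reproduces the stored expectation exactly (replay oracle, asserted).

## Configuration and I/O

The INI dialect has one `[source]`, one `[detector]`, one or more
`[particle_*]` sections and an optional `[simulation]` section; all
quantities are SI with the unit in the key name where ambiguity is
possible; every key has a documented default; unknown keys fail fast
with a nearest-match hint.  PDB/mmCIF models are read via gemmi (first
model, highest-occupancy alternate conformers, waters and hydrogens
kept by default with flags to drop either, Å → m).  CCP4/MRC-2014 maps
are read via gemmi with header axis order honored; only cubic grids
with isotropic spacing are supported.  Fetching entries by PDB ID is
provided but never used implicitly (offline by default).  Output is
HDF5 in the CXI layout (detector data/mask/geometry, source energy in
J) plus the ground-truth group.

## Synthetic data generator

`generate_fixtures` produces deterministic stand-ins for downloaded
inputs: coil-like random-walk atom clusters (1.5 Å steps reflected at a
bounding sphere, protein-like element frequencies H/C/N/O/S ≈
50/30/9/10/1%), filled geometric occupancy maps, and matching PDB, MRC
and config files.  These emulate the size, composition and contrast of
single biological particles; they do **not** emulate secondary
structure, solvent shells, internal density fluctuations of real
macromolecules, or conformational heterogeneity — so passing tests
demonstrate correctness of the scattering physics and bookkeeping, not
biological realism of any particular specimen.

## Test problem sizes and numerical choices

The oracle-equivalence checks run 100 atoms and 16³ voxel maps against
64×64-pixel detectors; the discretization benchmark voxelizes a sphere
at 64 voxels across its diameter (1% agreement with the closed form for
qR ≤ 10; measured ~0.03%); cross-model consistency uses a 10 nm carbon
sphere (~26 000 pseudo-atoms).  The mixture scenario uses arrival rates
0.2 (water spheroids, sizes normal around 8 nm, flattening uniform in
0.8–1.0) and 0.9 (protein-complex-like spheres).  Speckle-size scaling
is measured as the FWHM of the azimuthally averaged central intensity
lobe and compared to 2π/D_eff with D_eff = 2√(5/3)·R_g, the
uniform-ball-equivalent diameter; the theoretical ratio is ~1.16 for a
uniform body and ~1.18 for a Gaussian-envelope cluster, well inside the
±30% acceptance band.  Stochastic tests are seeded (derandomized);
statistical bands are 3σ or χ² at α = 0.01.  The sphere form factor
uses a Taylor series below u = 10⁻³ to avoid cancellation; q = 0 pixels
report infinite resolution rather than dividing by zero.

## Known limitations

* Angle-independent scattering factors: no atomic shape beyond the
  forward-scattering limit; no near-edge fine structure between table
  nodes.
* Single flat detector panel; no pixel-area integration, tilts or
  multi-panel geometries.
* Scalar quantum efficiency; detector noise limited to Gaussian read
  noise; no gain maps or charge sharing.
* The refractive-index route assigns every voxel a single material's
  stoichiometry; mixed-composition maps require per-voxel electron
  densities instead.
* Radiation damage, pulse temporal structure and partial coherence are
  out of scope by construction of the model.
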