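# Methods

This note documents the models implemented in `ppsim`, the approximations
they make, the defaults chosen where the design was genuinely open, and
what the test suite's synthetic scenarios do and do not establish about
real tissue.

## Phantoms

A phantom is a 3D integer label grid plus a table of tissue classes, each
carrying wavelength-resolved optical properties (μa, μs [cm⁻¹], the
Henyey–Greenstein anisotropy g, refractive index n).  Conventions are fixed
for reproducibility: voxel indices are 0-based; physical coordinates are
voxel-centre, in µm, right-handed, with z the insertion/depth axis.
Anisotropic voxels are supported; the desk-scale default is 40 µm cubes.

Two builders exist.  `build_layered_slab` stacks tissue layers along z
(the canonical transport test geometry); layer thicknesses round to whole
voxels and sub-voxel layers are rejected by name.  `build_rat_head_phantom`
is a *parametric* head section — ambient gap, skull shell, CSF gap, grey
matter bulk, a white-matter ellipsoid, a nerve-tract cylinder, blood-vessel
cylinders, and a hippocampus stand-in target ellipsoid recorded as a voxel
mask.  It deliberately replaces MRI-derived anatomy: segmented rat data of
sufficient quality are not distributed, and a parametric model reproduces
the optical layering that controls light delivery (strongly scattering
skull, clear CSF, blue-absorbing blood, bulk brain scattering) without
pretending to anatomical fidelity.  Conclusions drawn from it are about
transport physics and relative contrasts, not about absolute fluence in a
particular animal.

Default optical properties ship as an editable JSON table
(`src/ppsim/data/tissue_optics.json`) with representative literature values
for 460 and 620 nm; the code treats the table as configuration, never as
ground truth.

The probe is modelled optically only: a rectangular shaft inserted along z,
with a transparent acrylic-like core (default n = 1.56) wrapped laterally
by a 4 µm lower-index cladding (n = 1.40) and an open emission face at the
tip.  Voxels whose centres fall inside the shaft are relabelled; at 40 µm
voxels the 4 µm cladding is sub-voxel and vanishes from the grid, leaving
core directly against tissue (n = 1.36) — the guiding condition holds
either way.  Fluidic and electrode functions of the real device are
ignored.

## Monte Carlo transport

Photon packets propagate through the voxel grid with:

- **Optical-depth marching.** A total optical depth τ = −ln ξ is consumed
  across voxels (μt·ℓ per sub-path), which handles heterogeneous media
  exactly; μt = 0 voxels are transparent and traversed to the boundary.
- **Implicit capture**: at each interaction a weight fraction μa/μt is
  deposited and the packet continues with weight × μs/μt.
- **Henyey–Greenstein scattering** via the standard inverse-CDF sample;
  g = 0 falls back to isotropic.
- **Russian roulette** below weight 10⁻⁴ with survival probability 0.1
  (survivors boosted ×10).
- **Fresnel boundaries**: wherever the refractive index differs between two
  adjacent voxels, unpolarized Fresnel reflectance is evaluated at the
  shared face and the packet reflects or refracts (Snell), with total
  internal reflection beyond the critical angle.  This is the mechanism by
  which the implanted probe guides light.  Crossing the *outer* grid
  boundary is a plain escape with no Fresnel; phantoms include an ambient
  padding class where boundary physics matters.
- **Tallies**: fluence uses the track-length estimator (robust for μa → 0);
  a separate absorption tally per voxel and per class feeds the energy
  audit and gives deposited power (heat) per voxel, though thermal
  diffusion is not modelled.

Fluence normalization: Φ = (Σ w·ℓ)·P(λ)/(V·N) [W cm⁻²] for source power
P, voxel volume V and N launched packets.  Photon flux follows as
E_PF = Φ·λ/(N_A·h·c) [einstein cm⁻² s⁻¹].

**Energy audit.** The kernel keeps an explicit roulette ledger (weight
destroyed at kills, weight created by survivor boosts), so the identity

    launched + roulette_gain = absorbed + escaped + roulette_loss

holds exactly per run, up to float summation (observed residuals ≲ 10⁻¹⁰).
Without roulette the identity reduces to launched = absorbed + escaped.
Roulette preserves the *expected* weight; the ledger makes the per-run
audit exact without biasing the estimator.

**RNG and determinism.** Each photon owns an independent xorshift64* stream
seeded from (run seed, photon index) through a splitmix64 mix, so results
are bitwise reproducible for a given seed and independent of execution
order; per-wavelength and per-batch runs use derived seeds.

**Sources.** Four emitters: pencil beam, isotropic point, Lambertian disk
(the butt-coupled SMD-LED approximation) and a disk emitting uniformly
within a cone (waveguide facet with a numerical-aperture half-angle,
default 20°).  The real LED's angular spectrum and coupling are not
published, so these are declared approximations; default demo powers are
the device's measured outputs (58.5 mW at 460 nm, 33.6 mW at 620 nm).

Validation: Beer–Lambert attenuation (within 2% to 3 cm at 10⁶ photons),
the isotropic point-source closed form in a non-scattering medium (shell
averages within 5% over r ∈ [0.1, 1] cm — per-voxel comparison is
dominated by the 1/r² variation across a voxel, so shells are the natural
estimator), the diffusion-approximation point-source solution for
μs′ ≫ μa (within 15% beyond three transport mean free paths), HG sampling
statistics, and exact mirror symmetry of absorption-only runs.

## Photoswitch kinetics

Per voxel the E ⇌ Z system is linear.  Photochemical rate constants use
the optically-thin local form k = ln(10)·10³·ε(λ)·φ(λ)·E_PF(λ) [s⁻¹]
(the 10³ converts litres to cm³), summed over illumination wavelengths;
the thermal relaxation k_Δ = ln2/t½ acts on a configurable side.  The
closed-form solution is mono-exponential with κ = k_EZ + k_ZE + k_Δ and
conserves C_E + C_Z exactly (convex-combination evaluation keeps t = 0 and
t → ∞ exact to the ulp).  It matches a 2×2 matrix-exponential oracle to
better than 10⁻¹⁰ relative over randomized rates.

The optically-thin assumption is the key approximation: attenuation
*across* voxels is carried entirely by the Monte Carlo fluence, while the
drug's self-absorption *within* a voxel is neglected.  At ≤40 µm voxels and
the concentrations of interest the per-voxel absorbance is A ≪ 10⁻³, so
the photokinetic correction factor (1−10⁻ᴬ)/(A·ln10) is indistinguishable
from 1 and is not applied by default.

`thermal_direction` is explicit because the generic azobenzene formulation
has the thermal back-reaction Z→E, while the modelled drug class is
*Z-stable*: it inhibits in its thermodynamically stable Z form, relaxes
E→Z in the dark, and is deactivated (Z→E) by 460 nm light.  The sign of
the thermal term therefore must be configurable.

**Synthetic photoswitch spectra.** No measured ε/φ spectra for the drug are
tabulated, so the packaged `synthetic_azobenzene_inhibitor` uses two
Gaussian bands built to mimic the functional behaviour: Z absorbs in the
blue (peak ε 8000 L mol⁻¹ cm⁻¹ at 460 nm), E in the red (peak 15000 at
620 nm, plus a weak blue shoulder), quantum yields 0.30 (E→Z) and 0.40
(Z→E), thermal half-life 600 s — a mid-range T-type value chosen so that
thermal and photochemical rates compete at the photon fluxes the demo
produces.  Tests built on this fixture validate the *kinetics machinery*,
not any real compound's photochemistry; binding-site perturbation of the
spectra and whether receptor-bound drug switches at all are treated as
milieu-independent inputs.

Addressability diagnostics report the light responsiveness ρ = ε·φ per
isomer and wavelength, the strict one-sided condition (ρ of one isomer
zero — complete conversion), and a dominance condition (ratio ≥ 100 by
default).

## Light–chemistry coupling

The drug adds Δμa = ln10·(ε_E·C_E + ε_Z·C_Z) [cm⁻¹] to each voxel
(absorption only; scattering by the dilute solute is neglected).
`coupled_solve` alternates transport (baseline + Δμa) with the voxelwise
PSS until the maximum absolute change in f_Z across voxels falls below the
tolerance.  f_Z is already a fraction in [0, 1], so the metric is absolute;
a relative metric would blow up in effectively dark voxels.  The converged
flag is honest: hitting max_iter returns converged = False with the metric
history.

Each iteration runs the Monte Carlo as two half-batches with derived seeds.
The half-difference of the resulting f_Z fields estimates the MC noise
floor (median over illuminated voxels of |Δf_Z|/2), and a tolerance below
that floor is refused — a fixed point cannot be certified tighter than the
noise that re-randomizes it each iteration.

The constant-concentration initial field (the first-approximation drug
profile) starts in dark equilibrium: all-Z for a Z-stable switch, all-E for
E-stable, 50/50 for P-type.  The converged PSS field is invariant to the
initial isomer split (verified within 2× tolerance).

`time_marched_solve` is the operator-splitting variant: fluence frozen over
each Δt, kinetics advanced in closed form.  An optional step-doubling check
re-runs at Δt/2 and raises if the final f_Z field moves more than a stated
bound, flagging a too-coarse step.  Δt should resolve min(1/κ) in the lit
region; the stationary-limit consistency with `coupled_solve` is tested in
the weak-coupling regime.

Validation: in the weak-coupling limit (Δμa ≪ μa) the fixed point matches
the uncoupled transport + PSS pipeline within MC noise and converges in one
to two iterations; in the strong-coupling slab the f_Z depth profile
matches a deterministic 1D Beer–Lambert + PSS fixed-point integrator to
well within 5% at 10⁶ photons, and the light-driven isomer fraction
decreases monotonically with depth (drug self-shielding).

## Pharmacodynamics

Inhibition is direct Hill occupancy f = C^h/(C^h + IC50^h) of the active
isomer (default IC50 = 3.1 µM — the drug's dark-state value — and h = 1,
since only IC50 is characterized; both configurable).  h = 1 is evaluated
without `pow` so the vectorized map equals scalar recomputation bitwise.
Binary classification uses a boundary-*inclusive* threshold at 0.5: a voxel
at exactly C = IC50 counts as inhibited, for any h.  Volume summaries are
exactly count × voxel volume; when the phantom carries a target mask the
inhibited fraction of the target is reported as well.  No receptor-density,
agonist-competition or electrophysiological model is layered on top.

## Pipeline, configuration, reproducibility

A single YAML config drives phantom → transport → kinetics/coupling →
inhibition.  Validation cross-checks every wavelength against the tissue
optical table (exact entries required — no silent interpolation) and the
photoswitch spectra range before any compute.  The manifest records the
seed, per-stage status, SHA-256 of every artifact and the scalar summaries;
reruns with the same config and seed reproduce summaries and artifact
hashes bit-identically.  Physical constants (h, c, N_A, CODATA 2018) are
pinned in one module.

## Problem sizes

The validation suite uses 10⁶ photons for the closed-form transport
limits and the diffusion comparison, 10⁶ for the strong-coupling oracle,
and 2×10⁵ photons per wavelength on the 100×100×200-voxel (4×4×8 mm at
40 µm) rat-head phantom — sizes at which every statistical bound above
holds with margin on a single CPU in minutes.  The same physics scales to
finer grids (the device's 4 µm coatings need ~4×4×8 µm³ voxels) by raising
`dims`, `voxel_um` and `n_photons`; memory grows with the voxel count and
runtime roughly linearly with photons × optical thickness.

## Known limitations

- Transport: no polarization, fluorescence, time-resolved transport or
  bio-heat modelling; heat deposition is tallied but not diffused.
- Grid-boundary escapes skip Fresnel; pad with ambient voxels when the
  external interface matters.
- Kinetics: strictly two states — no multi-state photochromes,
  photodegradation, azobenzene reduction, or two-photon excitation.
- Pharmacokinetics (diffusion from the probe, clearance, metabolism) is out
  of scope; the constant-concentration profile is a stated first
  approximation.
- The rat-head phantom is parametric, not anatomical; its optical table is
  editable configuration with representative literature values.
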