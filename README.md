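# ppsim — in vivo photokinetic modelling for photopharmacology

`ppsim` simulates how light delivered by an implanted brain probe controls a
photoswitchable drug inside heterogeneous tissue.  It couples three layers
that are usually modelled separately:

1. **Voxel Monte Carlo photon transport** through a labelled tissue phantom
   (absorption μa, scattering μs, Henyey–Greenstein anisotropy g, refractive
   index n per tissue class and wavelength), including Fresnel refraction /
   total internal reflection at index steps — which is what makes an
   implanted high-index probe act as a waveguide.
2. **Two-state E ⇌ Z photoswitch kinetics** driven by the local photon flux:
   per voxel, photochemical rate constants k = ln(10)·10³·ε(λ)·φ(λ)·E_PF(λ)
   compete with the thermal back-reaction k_Δ = ln2/t½, giving a closed-form
   time course and a photostationary state (PSS)
   f_Z = k_EZ/(k_EZ + k_ZE + k_Δ).
3. **IC50 pharmacodynamics**: the active-isomer concentration maps to a
   fractional inhibition f = C^h/(C^h + IC50^h) and a binary
   inhibited/unaffected classification with treated-volume summaries.

Because the dissolved drug absorbs light, the isomer composition feeds back
on every voxel's absorption coefficient; `coupled_solve` iterates transport
and chemistry to a self-consistent fixed point (with an explicit
time-marching variant for half-life-scale dynamics).

The package is aimed at device/photodrug co-design questions: how much of a
deep target can be switched, at which wavelengths and powers, and how much
an implanted waveguide helps.

## Worked example

The packaged demo builds a parametric rat-head section (4 × 4 × 8 mm at
40 µm voxels: skull, CSF, grey/white matter, vessels, a nerve tract and a
hippocampus stand-in target at 3.5 mm depth), implants a 200 µm acrylic
probe reaching the target, and butt-couples a bi-colour LED
(58.5 mW at 460 nm, 33.6 mW at 620 nm) to its top face:

```bash
$ ppsim demo --photons 200000 --seed 1
blue (460 nm) target fluence gain with probe: 6.88x (SE 0.11)
red (620 nm) no-probe/probe target fluence ratio: 0.280
inhibited target fraction: dark 1.000 -> 460 nm 0.000
```

Reading the numbers: blue light reaches the deep target almost an order of
magnitude better through the waveguide than through tissue (scattering and
haemoglobin absorption kill it otherwise), while red light penetrates
tissue well enough that removing the probe only costs a factor ~3.6.  With
10 µM of a Z-active photoswitchable AMPA-antagonist (IC50 3.1 µM in the
dark), the whole target is inhibited in the dark; switching on the guided
460 nm light converts the drug to its inactive E form throughout the
target, releasing the inhibition — the on-demand deactivation that makes
such drugs useful.

The same pipeline is scriptable from Python (`build_rat_head_phantom`,
`insert_probe`, `run_mc`, `field_kinetics`, `coupled_solve`,
`classify_map`) or driven by a single YAML file:

```bash
ppsim validate my_pipeline.yaml
ppsim run --config my_pipeline.yaml   # writes maps + manifest with hashes
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.

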