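# Packaged demo: rat-head section, bi-colour LED above the implanted probe.
seed: 42
output_dir: ppsim_demo_out
phantom:
  preset: rat_head
  dims: [100, 100, 200]
  voxel_um: [40, 40, 40]
  probe:
    width_um: 200
    height_um: 200
    depth_um: 4000
    cladding_um: 4
sources:
  - kind: led_disk
    position_um: [2000, 2000, 2]
    direction: [0, 0, 1]
    radius_um: 90
    power_w:
      460: 0.0585
      620: 0.0336
run:
  n_photons: 200000
  wavelengths: [460, 620]
photoswitch: synthetic
c0_mol_per_l: 1.0e-5
pharmacodynamics:
  ic50: 3.1e-6
  hill: 1.0
  active_isomer: Z
  threshold: 0.5
coupling:
  mode: pss
  tolerance: 0.05
  max_iter: 4
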