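{
  "comment": "Default optical properties per tissue class at 460 and 620 nm. Representative values compiled from the tissue-optics literature (brain grey/white matter, whole blood, CSF, skull bone); editable configuration, not ground truth. mu_a and mu_s in 1/cm.",
  "classes": [
    {
      "label": 0,
      "name": "ambient",
      "properties": [
        {"wavelength": 460, "mu_a": 0.0, "mu_s": 0.0, "g": 0.0, "n": 1.0},
        {"wavelength": 620, "mu_a": 0.0, "mu_s": 0.0, "g": 0.0, "n": 1.0}
      ]
    },
    {
      "label": 1,
      "name": "grey_matter",
      "properties": [
        {"wavelength": 460, "mu_a": 1.4, "mu_s": 120.0, "g": 0.88, "n": 1.36},
        {"wavelength": 620, "mu_a": 0.25, "mu_s": 90.0, "g": 0.89, "n": 1.36}
      ]
    },
    {
      "label": 2,
      "name": "white_matter",
      "properties": [
        {"wavelength": 460, "mu_a": 1.2, "mu_s": 420.0, "g": 0.82, "n": 1.38},
        {"wavelength": 620, "mu_a": 0.2, "mu_s": 380.0, "g": 0.84, "n": 1.38}
      ]
    },
    {
      "label": 3,
      "name": "csf",
      "properties": [
        {"wavelength": 460, "mu_a": 0.05, "mu_s": 2.4, "g": 0.9, "n": 1.33},
        {"wavelength": 620, "mu_a": 0.02, "mu_s": 2.0, "g": 0.9, "n": 1.33}
      ]
    },
    {
      "label": 4,
      "name": "bone",
      "properties": [
        {"wavelength": 460, "mu_a": 0.6, "mu_s": 350.0, "g": 0.92, "n": 1.55},
        {"wavelength": 620, "mu_a": 0.25, "mu_s": 300.0, "g": 0.93, "n": 1.55}
      ]
    },
    {
      "label": 5,
      "name": "blood_vessel",
      "properties": [
        {"wavelength": 460, "mu_a": 280.0, "mu_s": 250.0, "g": 0.97, "n": 1.36},
        {"wavelength": 620, "mu_a": 12.0, "mu_s": 200.0, "g": 0.98, "n": 1.36}
      ]
    },
    {
      "label": 6,
      "name": "nerve_tissue",
      "properties": [
        {"wavelength": 460, "mu_a": 1.0, "mu_s": 300.0, "g": 0.85, "n": 1.37},
        {"wavelength": 620, "mu_a": 0.2, "mu_s": 260.0, "g": 0.87, "n": 1.37}
      ]
    },
    {
      "label": 7,
      "name": "probe_core",
      "properties": [
        {"wavelength": 460, "mu_a": 0.05, "mu_s": 0.0, "g": 0.0, "n": 1.56},
        {"wavelength": 620, "mu_a": 0.05, "mu_s": 0.0, "g": 0.0, "n": 1.56}
      ]
    },
    {
      "label": 8,
      "name": "probe_cladding",
      "properties": [
        {"wavelength": 460, "mu_a": 0.1, "mu_s": 0.0, "g": 0.0, "n": 1.4},
        {"wavelength": 620, "mu_a": 0.1, "mu_s": 0.0, "g": 0.0, "n": 1.4}
      ]
    }
  ]
}
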