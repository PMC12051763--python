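{
  "version": "2024.1",
  "notes": "Rounded evaluated decay data (NNDC NuDat 3 / ICRP Publication 107 style). 'beta_mean' entries give the mean electron energy per decay, including internal-conversion and Auger electrons (dosimetric convention). Alpha entries give branch-weighted mean alpha energies. Gamma/x-ray entries list the principal photon emissions above ~70 keV plus the K x-ray group.",
  "nuclides": [
    {
      "name": "Pb-212",
      "half_life_h": 10.64,
      "daughters": [{"name": "Bi-212", "fraction": 1.0}],
      "emissions": [
        {"kind": "beta_mean", "energy_keV": 160.0, "intensity": 1.0},
        {"kind": "gamma", "energy_keV": 238.6, "intensity": 0.436},
        {"kind": "xray", "energy_keV": 79.0, "intensity": 0.335}
      ]
    },
    {
      "name": "Bi-212",
      "half_life_h": 1.00917,
      "daughters": [
        {"name": "Tl-208", "fraction": 0.3594},
        {"name": "Po-212", "fraction": 0.6406}
      ],
      "emissions": [
        {"kind": "alpha", "energy_keV": 6060.0, "intensity": 0.3594},
        {"kind": "beta_mean", "energy_keV": 771.0, "intensity": 0.6406},
        {"kind": "gamma", "energy_keV": 727.3, "intensity": 0.0658}
      ]
    },
    {
      "name": "Tl-208",
      "half_life_h": 0.050883,
      "daughters": [{"name": "Pb-208", "fraction": 1.0}],
      "emissions": [
        {"kind": "beta_mean", "energy_keV": 617.0, "intensity": 1.0},
        {"kind": "gamma", "energy_keV": 2614.5, "intensity": 0.9975},
        {"kind": "gamma", "energy_keV": 583.2, "intensity": 0.853}
      ]
    },
    {
      "name": "Po-212",
      "half_life_h": 8.3e-11,
      "daughters": [{"name": "Pb-208", "fraction": 1.0}],
      "emissions": [
        {"kind": "alpha", "energy_keV": 8785.0, "intensity": 1.0}
      ]
    },
    {
      "name": "Pb-208",
      "half_life_h": null,
      "daughters": [],
      "emissions": []
    },
    {
      "name": "Ac-225",
      "half_life_h": 240.0,
      "daughters": [{"name": "Fr-221", "fraction": 1.0}],
      "emissions": [
        {"kind": "alpha", "energy_keV": 5790.0, "intensity": 1.0},
        {"kind": "beta_mean", "energy_keV": 16.0, "intensity": 1.0},
        {"kind": "gamma", "energy_keV": 99.8, "intensity": 0.01}
      ]
    },
    {
      "name": "Fr-221",
      "half_life_h": 0.08167,
      "daughters": [{"name": "At-217", "fraction": 1.0}],
      "emissions": [
        {"kind": "alpha", "energy_keV": 6300.0, "intensity": 1.0},
        {"kind": "gamma", "energy_keV": 218.1, "intensity": 0.114}
      ]
    },
    {
      "name": "At-217",
      "half_life_h": 8.97e-6,
      "daughters": [{"name": "Bi-213", "fraction": 1.0}],
      "emissions": [
        {"kind": "alpha", "energy_keV": 7067.0, "intensity": 1.0}
      ]
    },
    {
      "name": "Bi-213",
      "half_life_h": 0.7605,
      "daughters": [
        {"name": "Po-213", "fraction": 0.9786},
        {"name": "Tl-209", "fraction": 0.0214}
      ],
      "emissions": [
        {"kind": "alpha", "energy_keV": 5870.0, "intensity": 0.0214},
        {"kind": "beta_mean", "energy_keV": 444.0, "intensity": 0.9786},
        {"kind": "gamma", "energy_keV": 440.5, "intensity": 0.261}
      ]
    },
    {
      "name": "Po-213",
      "half_life_h": 1.028e-9,
      "daughters": [{"name": "Pb-209", "fraction": 1.0}],
      "emissions": [
        {"kind": "alpha", "energy_keV": 8376.0, "intensity": 1.0}
      ]
    },
    {
      "name": "Tl-209",
      "half_life_h": 0.036,
      "daughters": [{"name": "Pb-209", "fraction": 1.0}],
      "emissions": [
        {"kind": "beta_mean", "energy_keV": 659.0, "intensity": 1.0},
        {"kind": "gamma", "energy_keV": 1567.0, "intensity": 0.997}
      ]
    },
    {
      "name": "Pb-209",
      "half_life_h": 3.234,
      "daughters": [{"name": "Bi-209", "fraction": 1.0}],
      "emissions": [
        {"kind": "beta_mean", "energy_keV": 198.0, "intensity": 1.0}
      ]
    },
    {
      "name": "Bi-209",
      "half_life_h": null,
      "daughters": [],
      "emissions": []
    }
  ]
}
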