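{
  "coulomb_constant": 332.0637157,
  "intra_thole_scale": 3.0,
  "ion": "Br",
  "m_site_fraction": 1.0,
  "m_site_reference_offset": 0.147,
  "model": "i-TTM4",
  "pair_terms": {
    "ion-H": {
      "a": 9000.0,
      "beta": 2.8,
      "c6": 1100.0,
      "delta": null
    },
    "ion-O": {
      "a": 70000.0,
      "beta": 3.0,
      "c6": 4200.0,
      "delta": null
    }
  },
  "sites": {
    "H-charge": {
      "charge": 0.574,
      "polarizability": 0.496,
      "site_kind": "H-charge",
      "smearing_width": 0.4,
      "thole_damping": 1.0
    },
    "M-site": {
      "charge": -1.148,
      "polarizability": 0.0,
      "site_kind": "M-site",
      "smearing_width": 0.4,
      "thole_damping": 1.0
    },
    "O-pol": {
      "charge": 0.0,
      "polarizability": 0.837,
      "site_kind": "O-pol",
      "smearing_width": 0.0,
      "thole_damping": 1.0
    },
    "ion": {
      "charge": -1.0,
      "polarizability": 7.27,
      "site_kind": "ion",
      "smearing_width": 0.6,
      "thole_damping": 1.0
    }
  }
}
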