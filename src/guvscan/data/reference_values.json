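{
  "version": 1,
  "description": "Published reference values for SRR scanning of SM/POPC GUV membranes: cohort delta-|S21| statistics, baseline phases, membrane permittivities and two-domain section values.",
  "mode_frequencies_hz": [2.7e9, 7.9e9],
  "theta0_deg": {"2.7e9": 103.9, "7.9e9": 339.88},
  "delta_s21_stats": {
    "SM": {
      "2.7e9": {"mean": 8.99e-4, "sd": 1.56e-4, "n": 10},
      "7.9e9": {"mean": 9.35e-4, "sd": 0.57e-4, "n": 10}
    },
    "POPC": {
      "2.7e9": {"mean": 4.09e-4, "sd": 0.87e-4, "n": 10},
      "7.9e9": {"mean": 3.11e-4, "sd": 0.97e-4, "n": 10}
    }
  },
  "two_domain_measurements": [
    {"frequency_hz": 2.7e9, "section_I": 10.64e-4, "section_II": 4.55e-4, "label_I": "SM", "label_II": "POPC"},
    {"frequency_hz": 2.7e9, "section_I": 7.32e-4, "section_II": 2.92e-4, "label_I": "SM", "label_II": "POPC"},
    {"frequency_hz": 2.7e9, "section_I": 9.29e-4, "section_II": 4.74e-4, "label_I": "SM", "label_II": "POPC"},
    {"frequency_hz": 7.9e9, "section_I": 7.91e-4, "section_II": 2.71e-4, "label_I": "SM", "label_II": "POPC"}
  ],
  "membrane_permittivity": {
    "contact": {
      "POPC": {"2.7e9": {"eps_real": 73.64, "eps_imag": 6.13}}
    },
    "elevated_100nm": {
      "SM": {
        "2.7e9": {"eps_real": 73.17, "eps_imag": 1.34},
        "7.9e9": {"eps_real": 62.75, "eps_imag": 0.65}
      },
      "POPC": {
        "2.7e9": {"eps_real": 73.34, "eps_imag": 5.66},
        "7.9e9": {"eps_real": 63.61, "eps_imag": 15.41}
      }
    }
  },
  "elevation_reduction_factor_100nm": 0.107,
  "flattening_reference": {
    "diameter_m": 25e-6,
    "contact_length_m": 11e-6,
    "contact_width_m": 20.5e-6
  },
  "membrane_thickness_m": {"SM": 5.0e-9, "POPC": 4.0e-9},
  "two_domain_composition": {"SM": 0.65, "POPC": 0.10, "CHOL": 0.25},
  "scan_duration_range_s": [0.6, 0.9],
  "flow_rate_ul_per_min": 2.0,
  "ifbw_hz": 1000.0
}
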