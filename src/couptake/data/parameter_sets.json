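{
  "strains": {
    "gfp": {
      "description": "Static-experiment fit, GFP-producing strain (cytoplasmic)",
      "params": {"qs_lac_max_star": 0.23, "K_A": 0.0042, "qs_glu_crit": 0.88, "n": 1.77, "qs_lac_noglu": 0.023},
      "nrmse_pct": 0.04
    },
    "hrp": {
      "description": "Static-experiment fit, horseradish-peroxidase strain (periplasmic)",
      "params": {"qs_lac_max_star": 0.17, "K_A": 0.0092, "qs_glu_crit": 1.06, "n": 1.15, "qs_lac_noglu": 0.0032},
      "nrmse_pct": 5.14
    },
    "scfv": {
      "description": "Static-experiment fit, scFv-producing strain",
      "params": {"qs_lac_max_star": 0.09, "K_A": 0.019, "qs_glu_crit": 0.88, "n": 1.16, "qs_lac_noglu": 0.034},
      "nrmse_pct": 9.72
    },
    "tandem_scfv": {
      "description": "Static-experiment fit, tandem-scFv strain",
      "params": {"qs_lac_max_star": 0.13, "K_A": 0.094, "qs_glu_crit": 1.02, "n": 1.48, "qs_lac_noglu": 0.040},
      "nrmse_pct": 9.11
    }
  },
  "datasets": {
    "static": {
      "description": "Tandem-scFv fit to static experiments only",
      "params": {"qs_lac_max_star": 0.13, "K_A": 0.094, "qs_glu_crit": 1.02, "n": 1.48, "qs_lac_noglu": 0.040},
      "nrmse_pct": 9.11
    },
    "ramp_up_down": {
      "description": "Tandem-scFv fit to dynamic data (ramp up and down)",
      "params": {"qs_lac_max_star": 0.093, "K_A": 0.023, "qs_glu_crit": 1.00, "n": 2.17, "qs_lac_noglu": 0.066},
      "nrmse_pct": 22.1
    },
    "ramp_up": {
      "description": "Tandem-scFv fit to dynamic data (ramp up only)",
      "params": {"qs_lac_max_star": 0.072, "K_A": 0.392, "qs_glu_crit": 1.00, "n": 0.83, "qs_lac_noglu": 0.066},
      "nrmse_pct": 17.9
    },
    "ramp_up_all_static": {
      "description": "Tandem-scFv fit to ramp up plus all static data",
      "params": {"qs_lac_max_star": 0.075, "K_A": 0.025, "qs_glu_crit": 1.00, "n": 1.14, "qs_lac_noglu": 0.040},
      "nrmse_pct": 12.5
    },
    "combination": {
      "description": "Tandem-scFv fit to ramp up plus two model-selected static points",
      "params": {"qs_lac_max_star": 0.072, "K_A": 0.025, "qs_glu_crit": 1.00, "n": 1.11, "qs_lac_noglu": 0.040},
      "nrmse_pct": 12.8
    }
  }
}
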