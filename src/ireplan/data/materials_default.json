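{
  "schema_version": 1,
  "tissues": {
    "liver": {
      "name": "liver",
      "sigma0_S_per_m": 0.091,
      "sigma_f_S_per_m": 0.45,
      "E_rev_V_per_cm": 350.0,
      "E_irr_V_per_cm": 700.0,
      "alphaT_per_K": 0.015,
      "k_W_per_mK": 0.52,
      "rho_kg_per_m3": 1079.0,
      "c_J_per_kgK": 3540.0,
      "perfusion_per_s": 0.018,
      "metabolic_q_W_per_m3": 10740.0
    },
    "tumor": {
      "name": "tumor",
      "sigma0_S_per_m": 0.4,
      "sigma_f_S_per_m": 1.6,
      "E_rev_V_per_cm": 400.0,
      "E_irr_V_per_cm": 800.0,
      "alphaT_per_K": 0.015,
      "k_W_per_mK": 0.52,
      "rho_kg_per_m3": 1079.0,
      "c_J_per_kgK": 3540.0,
      "perfusion_per_s": 0.009,
      "metabolic_q_W_per_m3": 10740.0
    },
    "vessel": {
      "name": "vessel",
      "sigma0_S_per_m": 0.7,
      "sigma_f_S_per_m": 1.05,
      "E_rev_V_per_cm": 350.0,
      "E_irr_V_per_cm": 700.0,
      "alphaT_per_K": 0.015,
      "k_W_per_mK": 0.52,
      "rho_kg_per_m3": 1079.0,
      "c_J_per_kgK": 3540.0,
      "perfusion_per_s": 0.018,
      "metabolic_q_W_per_m3": 10740.0
    },
    "electrode": {
      "name": "electrode",
      "sigma0_S_per_m": 1000000.0,
      "sigma_f_S_per_m": 1000000.0,
      "E_rev_V_per_cm": 1e9,
      "E_irr_V_per_cm": 1e9,
      "alphaT_per_K": 0.0,
      "k_W_per_mK": 15.0,
      "rho_kg_per_m3": 6000.0,
      "c_J_per_kgK": 500.0,
      "perfusion_per_s": 0.0,
      "metabolic_q_W_per_m3": 0.0
    }
  },
  "blood": {
    "rho_b_kg_per_m3": 1060.0,
    "c_b_J_per_kgK": 3840.0,
    "T_b_K": 310.0
  },
  "arrhenius": {
    "Ea_J_per_mol": 506000.0,
    "zeta_per_s": 2.984e80,
    "R_J_per_molK": 8.314
  }
}
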