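{
 "comment": "Tissue regulation constants (mM), conserved pools (mM), default initial matrix/buffer composition (mM), and protocol defaults. Regulatory binding constants are tissue-specific: succinate binds the malate/Pi dicarboxylate carrier most tightly in heart, while matrix malate binds the succinate/Pi carrier most weakly in heart.",
 "regulation": {
  "heart": {
   "K_MAL_dccs": 15.0,
   "K_SUC_dccm": 0.25,
   "K_OXA_sdh": 0.0002,
   "K_MAL_sdh": 2.0
  },
  "cortex": {
   "K_MAL_dccs": 0.5,
   "K_SUC_dccm": 5.0,
   "K_OXA_sdh": 0.005,
   "K_MAL_sdh": 2.0
  },
  "om": {
   "K_MAL_dccs": 1.0,
   "K_SUC_dccm": 2.0,
   "K_OXA_sdh": 0.005,
   "K_MAL_sdh": 2.0
  }
 },
 "pools": {
  "pyridine": 3.0,
  "ubiquinone": 1.5,
  "cytochrome_c": 1.0,
  "adenine_matrix": 10.0,
  "coenzyme_a": 1.0,
  "guanine_matrix": 1.0
 },
 "initial_matrix": {
  "PYR_m": 0.01,
  "CIT_m": 0.05,
  "AKG_m": 0.25,
  "SUC_m": 0.1,
  "FUM_m": 0.03,
  "MAL_m": 0.1,
  "OXA_m": 0.0001,
  "GLU_m": 1.0,
  "ASP_m": 0.5,
  "ACoA_m": 0.05,
  "SCoA_m": 0.05,
  "CoA_m": 0.9,
  "NAD_m": 0.15,
  "NADH_m": 2.85,
  "UQ_m": 1.2,
  "UQH2_m": 0.3,
  "ADP_m": 9.0,
  "ATP_m": 1.0,
  "GDP_m": 0.7,
  "GTP_m": 0.3,
  "Pi_m": 1.0
 },
 "initial_ims": {
  "CytCred_i": 0.1,
  "CytCox_i": 0.9
 },
 "initial_buffer": {
  "PYR_e": 0.0,
  "GLU_e": 0.0,
  "AKG_e": 0.0,
  "SUC_e": 0.0,
  "MAL_e": 0.0,
  "CIT_e": 0.0,
  "ASP_e": 0.0,
  "ADP_e": 0.0,
  "ATP_e": 0.0,
  "Pi_e": 5.0,
  "O2_e": 0.4
 },
 "dpsi_initial_mV": 150.0,
 "compartments": {
  "V_e_mL": 2.0,
  "V_m_uL_per_mg": 1.0,
  "V_ims_fraction_of_Vm": 0.1
 },
 "protein_density_mg_per_mL": {
  "A": {
   "heart": 0.05,
   "cortex": 0.2,
   "om": 0.2
  },
  "B": {
   "heart": 0.1,
   "cortex": 0.2,
   "om": 0.2
  }
 },
 "protocol": {
  "substrate_time_min": 2.0,
  "adp_spacing_min": 3.0,
  "tail_min": 4.0,
  "state2_window_min": 1.0,
  "adp_doses_A_mM": [
   0.025,
   0.05,
   0.075,
   0.1,
   0.15,
   0.25
  ],
  "adp_dose_B_mM": {
   "heart": 0.2,
   "cortex": 0.1,
   "om": 0.1
  },
  "substrates": {
   "PM": {
    "PYR_e": 5.0,
    "MAL_e": 2.5
   },
   "GM": {
    "GLU_e": 5.0,
    "MAL_e": 2.5
   },
   "AM": {
    "AKG_e": 5.0,
    "MAL_e": 2.5
   },
   "SUC": {
    "SUC_e": 10.0
   },
   "SUC+ROT": {
    "SUC_e": 10.0
   }
  },
  "first_adp_delay_min": 8.0
 }
}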