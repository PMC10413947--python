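{
 "comment": "Intrinsic kinetic constants: binding constants (mM), transformed Gibbs energies at pH 7 (kJ/mol), signed proton counts, and per-turnover charge ledger for membrane-potential-coupled steps. Reconstructed from the thermodynamically constrained prior-model lineage and calibrated against the shipped tissue Vmax/Tmax so the printed model predictions are reproduced.",
 "reactions": {
  "PDH": {
   "substrates": [
    [
     "PYR_m",
     1,
     0.1
    ],
    [
     "CoA_m",
     1,
     0.02
    ],
    [
     "NAD_m",
     1,
     0.1
    ]
   ],
   "products": [
    [
     "ACoA_m",
     1,
     0.05
    ],
    [
     "NADH_m",
     1,
     0.05
    ]
   ],
   "dG0": -33.4,
   "nH": 1,
   "co2_product": true,
   "vmax_key": "PDH",
   "irreversible": true
  },
  "CITS": {
   "substrates": [
    [
     "OXA_m",
     1,
     0.001
    ],
    [
     "ACoA_m",
     1,
     0.014
    ]
   ],
   "products": [
    [
     "CIT_m",
     1,
     1.0
    ],
    [
     "CoA_m",
     1,
     0.05
    ]
   ],
   "dG0": -38.5,
   "nH": 1,
   "vmax_key": "CITS"
  },
  "ICDH": {
   "substrates": [
    [
     "CIT_m",
     1,
     0.3
    ],
    [
     "NAD_m",
     1,
     0.3
    ]
   ],
   "products": [
    [
     "AKG_m",
     1,
     1.0
    ],
    [
     "NADH_m",
     1,
     0.05
    ]
   ],
   "dG0": 3.7,
   "nH": 1,
   "co2_product": true,
   "vmax_key": "ICDH",
   "irreversible": true
  },
  "AKGDH": {
   "substrates": [
    [
     "AKG_m",
     1,
     0.5
    ],
    [
     "CoA_m",
     1,
     0.01
    ],
    [
     "NAD_m",
     1,
     0.1
    ]
   ],
   "products": [
    [
     "SCoA_m",
     1,
     0.3
    ],
    [
     "NADH_m",
     1,
     0.3
    ]
   ],
   "dG0": -27.5,
   "nH": 1,
   "co2_product": true,
   "vmax_key": "AKGDH",
   "irreversible": true
  },
  "SCAS": {
   "substrates": [
    [
     "SCoA_m",
     1,
     0.041
    ],
    [
     "GDP_m",
     1,
     0.02
    ],
    [
     "Pi_m",
     1,
     0.7
    ]
   ],
   "products": [
    [
     "SUC_m",
     1,
     3.0
    ],
    [
     "CoA_m",
     1,
     0.5
    ],
    [
     "GTP_m",
     1,
     0.5
    ]
   ],
   "dG0": 1.3,
   "nH": 0,
   "vmax_key": "SCAS"
  },
  "NDK": {
   "substrates": [
    [
     "GTP_m",
     1,
     0.1
    ],
    [
     "ADP_m",
     1,
     0.1
    ]
   ],
   "products": [
    [
     "GDP_m",
     1,
     0.1
    ],
    [
     "ATP_m",
     1,
     1.0
    ]
   ],
   "dG0": 0.0,
   "nH": 0,
   "vmax_key": "NDK"
  },
  "FH": {
   "substrates": [
    [
     "FUM_m",
     1,
     0.14
    ]
   ],
   "products": [
    [
     "MAL_m",
     1,
     0.5
    ]
   ],
   "dG0": -3.6,
   "nH": 0,
   "vmax_key": "FH"
  },
  "MDH": {
   "substrates": [
    [
     "MAL_m",
     1,
     0.5
    ],
    [
     "NAD_m",
     1,
     0.1
    ]
   ],
   "products": [
    [
     "OXA_m",
     1,
     0.0005
    ],
    [
     "NADH_m",
     1,
     0.05
    ]
   ],
   "dG0": 26.0,
   "nH": 1,
   "vmax_key": "MDH"
  },
  "GOT": {
   "substrates": [
    [
     "ASP_m",
     1,
     0.9
    ],
    [
     "AKG_m",
     1,
     0.1
    ]
   ],
   "products": [
    [
     "OXA_m",
     1,
     0.0005
    ],
    [
     "GLU_m",
     1,
     0.18
    ]
   ],
   "dG0": 4.3,
   "nH": 0,
   "vmax_key": "GOT"
  },
  "CI": {
   "substrates": [
    [
     "NADH_m",
     1,
     0.01
    ],
    [
     "UQ_m",
     1,
     0.1
    ]
   ],
   "products": [
    [
     "NAD_m",
     1,
     1.0
    ],
    [
     "UQH2_m",
     1,
     0.4
    ]
   ],
   "dG0": -69.5,
   "nH": -1,
   "charge": 4,
   "vmax_key": "CI"
  },
  "CII": {
   "substrates": [
    [
     "SUC_m",
     1,
     0.5
    ],
    [
     "UQ_m",
     1,
     10.0
    ]
   ],
   "products": [
    [
     "FUM_m",
     1,
     0.3
    ],
    [
     "UQH2_m",
     1,
     0.3
    ]
   ],
   "dG0": -3.6,
   "nH": 0,
   "vmax_key": "CII"
  },
  "CIII": {
   "substrates": [
    [
     "UQH2_m",
     1,
     0.3
    ],
    [
     "CytCox_i",
     2,
     0.25
    ]
   ],
   "products": [
    [
     "UQ_m",
     1,
     3.0
    ],
    [
     "CytCred_i",
     2,
     1.0
    ]
   ],
   "dG0": -32.0,
   "nH": 0,
   "charge": 2,
   "vmax_key": "CIII"
  },
  "CIV": {
   "K_CytC": 0.025,
   "K_O2": 0.00012,
   "dG0": -216.6,
   "nH": -4,
   "charge": 8,
   "vmax_key": "CIV"
  },
  "CV": {
   "substrates": [
    [
     "ADP_m",
     1,
     0.05
    ],
    [
     "Pi_m",
     1,
     1.0
    ]
   ],
   "products": [
    [
     "ATP_m",
     1,
     1.0
    ]
   ],
   "dG0": 36.0,
   "nH": -1,
   "charge": -3,
   "vmax_key": "CV"
  }
 },
 "transporters": {
  "PYRH": {
   "mechanism": "uniporter",
   "species_A": "PYR",
   "K_Ae": 0.15,
   "K_Am": 0.15,
   "proton_coupled": true,
   "tmax_key": "PYRH"
  },
  "GLUH": {
   "mechanism": "uniporter",
   "species_A": "GLU",
   "K_Ae": 4.0,
   "K_Am": 4.0,
   "proton_coupled": true,
   "tmax_key": "GLUH"
  },
  "DCCS": {
   "mechanism": "antiporter",
   "species_A": "SUC",
   "species_B": "Pi",
   "K_Ae": 1.0,
   "K_Am": 1.0,
   "K_Be": 1.5,
   "K_Bm": 1.5,
   "tmax_key": "DCCS"
  },
  "DCCM": {
   "mechanism": "antiporter",
   "species_A": "MAL",
   "species_B": "Pi",
   "K_Ae": 0.7,
   "K_Am": 0.7,
   "K_Be": 1.5,
   "K_Bm": 1.5,
   "tmax_key": "DCCM"
  },
  "TCC": {
   "mechanism": "antiporter",
   "species_A": "CIT",
   "species_B": "MAL",
   "K_Ae": 0.5,
   "K_Am": 0.5,
   "K_Be": 1.0,
   "K_Bm": 1.0,
   "tmax_key": "TCC"
  },
  "OME": {
   "mechanism": "antiporter",
   "species_A": "AKG",
   "species_B": "MAL",
   "K_Ae": 0.3,
   "K_Am": 0.3,
   "K_Be": 1.0,
   "K_Bm": 1.0,
   "tmax_key": "OME"
  },
  "GAE": {
   "mechanism": "antiporter",
   "species_A": "GLU",
   "species_B": "ASP",
   "K_Ae": 8.0,
   "K_Am": 8.0,
   "K_Be": 2.0,
   "K_Bm": 2.0,
   "charge": 1,
   "proton_coupled": true,
   "tmax_key": "GAE"
  },
  "ANT": {
   "mechanism": "antiporter",
   "species_A": "ADP",
   "species_B": "ATP",
   "K_Ae": 0.06,
   "K_Am": 0.1,
   "K_Be": 0.3,
   "K_Bm": 0.2,
   "charge": 1,
   "tmax_key": "ANT"
  },
  "PIC": {
   "mechanism": "uniporter",
   "species_A": "Pi",
   "K_Ae": 1.0,
   "K_Am": 1.0,
   "proton_coupled": true,
   "tmax_key": "PIC"
  },
  "HLEAK": {
   "mechanism": "leak",
   "alpha": 3.7,
   "tmax_key": "HLEAK",
   "x_ref": 6.455
  }
 },
 "constants": {
  "co2_mM": 21.4,
  "capacitance_mM_per_mV": 0.00675,
  "o2_ref_mM": 0.05,
  "ocr_per_civ_turnover": 1.0
 }
}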