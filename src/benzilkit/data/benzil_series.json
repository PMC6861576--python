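{
  "schema": "benzilkit.molecule_summary.v1",
  "comment": "Electronic-structure summaries for benzil and four para-disubstituted analogues, transcribed from the published B3LYP/cc-pVDZ and CAM-B3LYP/cc-pVDZ (TD-DFT, methanol IEFPCM) results. Energies in eV, wavelengths in nm, dipoles in Debye, NLO scalars in esu.",
  "molecules": [
    {
      "id": "BZL",
      "name": "benzil (diphenylethane-1,2-dione)",
      "e_homo": -6.596043,
      "e_lumo": -2.62862,
      "ip_vertical": 8.748,
      "ea_vertical": 6.065,
      "dipole_debye": 2.4212,
      "excitations": [
        {
          "lambda_nm": 276.39,
          "f": 0.608,
          "composition": [
            ["HOMO-3", "LUMO", 13.0],
            ["HOMO-2", "LUMO", 67.0],
            ["HOMO", "LUMO", 15.0]
          ]
        }
      ],
      "nlo": {
        "mu_debye": 2.4212,
        "alpha_esu": 2.275e-23,
        "beta_esu": 1.927e-30,
        "gamma_esu": -3.807e-37
      },
      "method_note": "B3LYP/cc-pVDZ ground state; CAM-B3LYP/cc-pVDZ TD-DFT in methanol (IEFPCM)"
    },
    {
      "id": "DMB",
      "name": "1,2-bis(4-methylphenyl)ethane-1,2-dione",
      "e_homo": -6.423523,
      "e_lumo": -2.46399,
      "ip_vertical": 8.689,
      "ea_vertical": 5.880,
      "dipole_debye": 2.7404,
      "excitations": [
        {
          "lambda_nm": 286.99,
          "f": 0.8355,
          "composition": [
            ["HOMO-1", "LUMO", 78.0],
            ["HOMO", "LUMO+1", 17.0]
          ]
        }
      ],
      "nlo": {
        "mu_debye": 2.7404,
        "alpha_esu": 2.757e-23,
        "beta_esu": 3.989e-30,
        "gamma_esu": -14.386e-37
      },
      "method_note": "B3LYP/cc-pVDZ ground state; CAM-B3LYP/cc-pVDZ TD-DFT in methanol (IEFPCM)"
    },
    {
      "id": "DFB",
      "name": "4,4'-difluorobenzil",
      "e_homo": -6.794959,
      "e_lumo": -2.7293,
      "ip_vertical": 8.681,
      "ea_vertical": 5.702,
      "dipole_debye": 1.4873,
      "excitations": [
        {
          "lambda_nm": 271.83,
          "f": 0.7299,
          "composition": [
            ["HOMO-1", "LUMO", 83.0],
            ["HOMO", "LUMO+1", 13.0]
          ]
        }
      ],
      "nlo": {
        "mu_debye": 1.4873,
        "alpha_esu": 2.305e-23,
        "beta_esu": 3.716e-30,
        "gamma_esu": -13.540e-37
      },
      "method_note": "B3LYP/cc-pVDZ ground state; CAM-B3LYP/cc-pVDZ TD-DFT in methanol (IEFPCM)"
    },
    {
      "id": "DCB",
      "name": "4,4'-dichlorobenzil",
      "e_homo": -6.82217,
      "e_lumo": -1.75405,
      "ip_vertical": 8.174,
      "ea_vertical": 5.708,
      "dipole_debye": 1.3013,
      "excitations": [
        {
          "lambda_nm": 277.26,
          "f": 0.9581,
          "composition": [
            ["HOMO-1", "LUMO", 81.0],
            ["HOMO", "LUMO+1", 15.0]
          ]
        }
      ],
      "nlo": {
        "mu_debye": 1.3013,
        "alpha_esu": 2.745e-23,
        "beta_esu": 6.704e-30,
        "gamma_esu": -20.195e-37
      },
      "method_note": "B3LYP/cc-pVDZ ground state; CAM-B3LYP/cc-pVDZ TD-DFT in methanol (IEFPCM)"
    },
    {
      "id": "DBB",
      "name": "4,4'-dibromobenzil",
      "e_homo": -6.846388,
      "e_lumo": -2.84359,
      "ip_vertical": 8.694,
      "ea_vertical": 5.905,
      "dipole_debye": 1.3607,
      "excitations": [
        {
          "lambda_nm": 279.96,
          "f": 1.036,
          "composition": [
            ["HOMO-1", "LUMO", 79.0],
            ["HOMO", "LUMO+1", 15.0]
          ]
        }
      ],
      "nlo": {
        "mu_debye": 1.3607,
        "alpha_esu": 2.966e-23,
        "beta_esu": 8.295e-30,
        "gamma_esu": -25.090e-37
      },
      "method_note": "B3LYP/cc-pVDZ ground state; CAM-B3LYP/cc-pVDZ TD-DFT in methanol (IEFPCM)"
    }
  ]
}
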