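{
  "schema": "benzilkit.torsion_metadata.v1",
  "comment": "Published relaxed potential-energy-scan summary for the central C4-C6-C5-C3 dihedral of the benzil series. Raw scan energies were not published; only barrier heights (kJ/mol) and grid-level extrema angles (degrees) are recorded. Synthetic profiles constructed to these amplitudes exercise the analysis code.",
  "dihedral_spec": "C4-C6-C5-C3",
  "molecules": {
    "BZL": {"barrier_kj_mol": 16.3175, "max_angle_deg": 40.0, "min_angle_deg": 130.0},
    "DMB": {"barrier_kj_mol": 8.2860, "max_angle_deg": 30.0, "min_angle_deg": 140.0},
    "DFB": {"barrier_kj_mol": 17.4132, "max_angle_deg": 40.0, "min_angle_deg": 140.0},
    "DCB": {"barrier_kj_mol": 16.4048, "max_angle_deg": 40.0, "min_angle_deg": 140.0},
    "DBB": {"barrier_kj_mol": 8.3755, "max_angle_deg": 30.0, "min_angle_deg": 130.0}
  },
  "barrier_order_descending": ["DFB", "DCB", "BZL", "DBB", "DMB"]
}
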