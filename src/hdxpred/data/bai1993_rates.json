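{
  "provenance": "Reference intrinsic amide exchange parameters for unstructured peptides, transcribed from the published poly-DL-alanine calibration of Bai, Milne, Mayne & Englander (Proteins 17:75-86, 1993) with the titration handling of the Englander-laboratory reference spreadsheet. Log-factors are decadic; rates are per minute at the 293 K reference temperature for protein-H exchanging into D2O (H-to-D direction).",
  "direction": "H_to_D",
  "reference_temperature_K": 293.0,
  "log10_kA_ref": 1.62,
  "log10_kB_ref": 10.05,
  "log10_kW_ref": -1.5,
  "pKD_water": 15.05,
  "activation_energy_cal_per_mol": {"acid": 14000.0, "base": 17000.0, "water": 19000.0},
  "gas_constant_cal_per_mol_K": 1.987,
  "side_chain_pKD": {"D": 4.48, "E": 4.93, "H": 7.42},
  "comment_factors": "Per side chain: [lambda_acid, rho_acid, lambda_base, rho_base]; lambda applies to the residue's own amide NH, rho to the amide NH of the following residue. Water-catalysed exchange uses the base factors. Titratable side chains (D, E, H) carry separate protonated/deprotonated rows blended by Henderson-Hasselbalch populations at the working pD; cystine (oxidized Cys) and cis-proline rows are selectable variants. Terminal-group factors: the protonated N-terminal amine contributes rho factors to the second residue's amide; the deprotonated C-terminal carboxylate contributes lambda factors to the last residue's amide (the acidic COOH form is not modelled, valid above ~pH 5).",
  "factors": {
    "A":  [ 0.00,  0.00,  0.00,  0.00],
    "R":  [-0.59, -0.32,  0.08,  0.22],
    "N":  [-0.58, -0.13,  0.49,  0.32],
    "D_protonated":   [-0.90, -0.12,  0.69,  0.60],
    "D_deprotonated": [ 0.90,  0.58,  0.10, -0.18],
    "C":  [-0.54, -0.46,  0.62,  0.55],
    "C_oxidized": [-0.74, -0.58,  0.55,  0.46],
    "G":  [-0.22,  0.22,  0.27,  0.17],
    "Q":  [-0.47, -0.27,  0.06,  0.20],
    "E_protonated":   [-0.60, -0.27,  0.24,  0.39],
    "E_deprotonated": [-0.90,  0.31, -0.11, -0.15],
    "H_protonated":   [-0.80, -0.51,  0.80,  0.83],
    "H_deprotonated": [ 0.00,  0.00, -0.10,  0.14],
    "I":  [-0.91, -0.59, -0.73, -0.23],
    "L":  [-0.57, -0.13, -0.58, -0.21],
    "K":  [-0.56, -0.29, -0.04,  0.12],
    "M":  [-0.64, -0.28, -0.01,  0.11],
    "F":  [-0.52, -0.43, -0.24,  0.06],
    "P":  [null, -0.19, null, -0.24],
    "P_cis": [null, -0.85, null,  0.60],
    "S":  [-0.44, -0.39,  0.37,  0.30],
    "T":  [-0.79, -0.47, -0.07,  0.20],
    "W":  [-0.40, -0.44, -0.41, -0.11],
    "Y":  [-0.41, -0.37, -0.27,  0.05],
    "V":  [-0.74, -0.30, -0.70, -0.14],
    "N_terminal_amine":       [null, -1.32, null,  1.62],
    "C_terminal_carboxylate": [ 0.96,  null, -1.80,  null]
  }
}
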