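# Synthetic-scenario parameters for the donor / chloranilic-acid (CLA)
# charge-transfer system: CT band at 530 nm, association constant and molar
# absorptivity of the 1:1 complex, direct-transition band gap, titration and
# Job's-series conditions, and the microwell calibration line.
name: cla
lambda_max_nm: 530.0
association_constant: 147.0
molar_absorptivity: 12900.0
band_gap_ev: 1.9
acceptor_total_molar: 4.79e-3
donor_concs_molar: [3.67e-5, 5.5e-5, 7.3e-5, 9.1e-5, 1.06e-4, 1.22e-4]
jobs_total_molar: 2.0e-3
donor_band_centers_nm: [225.0, 253.0, 310.0]
donor_band_widths_nm: [8.0, 9.0, 12.0]
donor_band_heights_au: [0.9, 0.7, 0.5]
acceptor_band_centers_nm: [301.0, 420.0]
acceptor_band_widths_nm: [12.0, 18.0]
acceptor_band_heights_au: [0.6, 0.3]
ct_band_width_nm: 30.0
ct_band_height_au: 0.8
calibration:
  slope: 0.0289
  intercept: 0.0887
  levels_ug_ml: [5, 20, 40, 60, 80, 100, 120]
  replicates: 3
  blanks: 3
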