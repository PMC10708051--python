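# Synthetic-scenario parameters for the donor / DDQ (2,3-dichloro-5,6-
# dicyano-1,4-benzoquinone) charge-transfer system: CT band at 470 nm.
name: ddq
lambda_max_nm: 470.0
association_constant: 137.0
molar_absorptivity: 20700.0
band_gap_ev: 2.1
acceptor_total_molar: 4.41e-3
donor_concs_molar: [2.45e-5, 4.4e-5, 6.4e-5, 8.3e-5, 1.03e-4, 1.22e-4]
jobs_total_molar: 2.0e-3
donor_band_centers_nm: [225.0, 253.0, 310.0]
donor_band_widths_nm: [8.0, 9.0, 12.0]
donor_band_heights_au: [0.9, 0.7, 0.5]
acceptor_band_centers_nm: [351.0]
acceptor_band_widths_nm: [15.0]
acceptor_band_heights_au: [0.5]
ct_band_width_nm: 28.0
ct_band_height_au: 0.7
calibration:
  slope: 0.0117
  intercept: 0.1361
  levels_ug_ml: [5, 50, 100, 150, 200, 250, 300]
  replicates: 3
  blanks: 3
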