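# Analytical Eco-Scale penalty ledger for the microwell charge-transfer
# spectrophotometric assay (100 uL methanol + 100 uL acceptor reagent per
# sample, absorbance plate reader, untreated waste < 1 mL per sample).
method: microwell CT spectrophotometric assay
items:
  - category: reagent_amount
    description: "Solvent (methanol), <1 mL per sample"
    pp: 1
  - category: reagent_amount
    description: "Reagent (acceptor solution), <1 mL per sample"
    pp: 1
  - category: reagent_hazard
    description: "Solvent: methanol"
    pp: 3
  - category: reagent_hazard
    description: "Reagent: chloranilic acid / DDQ"
    pp: 3
  - category: instrument_energy
    description: "Microplate reader"
    pp: 0
  - category: occupational
    description: "Analytical process hermetic"
    pp: 0
  - category: occupational
    description: "Emission of vapors and gases into the air"
    pp: 0
  - category: waste_production
    description: "Waste production, <1 mL per sample"
    pp: 1
  - category: waste_treatment
    description: "No waste treatment involved"
    pp: 3
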