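# Fermentation species in the ionization state predominant at pH 7.
# Formulas track C/H/O only; charge is the formal charge of that form.
species:
  - {name: glucose,  formula: C6H12O6, charge: 0,  phase: aq}
  - {name: butyrate, formula: C4H7O2,  charge: -1, phase: aq}
  - {name: acetate,  formula: C2H3O2,  charge: -1, phase: aq}
  - {name: lactate,  formula: C3H5O3,  charge: -1, phase: aq}
  - {name: formate,  formula: CHO2,    charge: -1, phase: aq}
  - {name: CO2,      formula: CO2,     charge: 0,  phase: g}
  - {name: H2,       formula: H2,      charge: 0,  phase: g}
  - {name: H2O,      formula: H2O,     charge: 0,  phase: l}
  - {name: "H+",     formula: H,       charge: 1,  phase: aq}
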