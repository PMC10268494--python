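# Standard transformed Gibbs energies of formation, kJ/mol, at 298.15 K,
# pH 7, ionic strength 0.  Derived from the classical anaerobe-bioenergetics
# compilation of standard formation energies by adding N_H * RT*ln(10)*pH
# (39.9563 kJ/mol per hydrogen atom at pH 7); the proton entry is 0 by
# convention, so transformed reaction energies are plain coefficient sums.
reference_temperature_K: 298.15
reference_pH: 7.0
source: "Thauer/Jungermann/Decker-style formation energies, pH-7 transformed"
species:
  glucose: -437.744
  butyrate: -72.936
  acetate: -249.541
  lactate: -317.398
  formate: -311.084
  CO2: -394.360
  H2: 79.913
  H2O: -157.257
  "H+": 0.0
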