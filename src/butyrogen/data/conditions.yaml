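# Representative physiological conditions for the human colon, used as the
# default evaluation point for condition-adjusted Gibbs energies.  These are
# literature-typical values (documented in docs/methods.md), not measurements:
# colonic solutes in mol/L, headspace-style gas partial pressures in atm.
temperature_K: 310.15
pH: 7.0
concentrations_M:
  glucose: 1.0e-2
  acetate: 3.0e-2
  butyrate: 1.0e-2
  lactate: 1.0e-3
  formate: 1.0e-3
p_CO2_atm: 0.3
p_H2_atm: 0.15
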