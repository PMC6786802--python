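# Nicotine modulation of I_KAch: two-population model parameters.
# Concentrations and dissociation constants in nM.
# The acetylcholine-induced component carries a voltage override at -110 mV
# (h_2_1 reduced from 0.085 to 0.037), expressing the shift of the
# concentration dependence towards inhibition at strongly negative voltages.
drug: nicotine
units: nM
voltage: -50
components:
  I_KAch_CONST:
    f_1: 0.68
    K_1: 50
    K_2: 50
    K_3: 1
    K_4: inf
    h_0_1: 0.008
    h_1_1: 0.107
    h_2_1: 0.036
    h_0_2: 0.06
    h_1_2: 0.049
    h_2_2: 0
  I_KAch_ACH:
    f_1: 0.68
    K_1: 0.2
    K_2: 0.2
    K_3: 110
    K_4: 520
    h_0_1: 0.065
    h_1_1: 0.085
    h_2_1: 0.085
    h_0_2: 0.45
    h_1_2: 0.41
    h_2_2: 0.025
    overrides:
      -110: {h_2_1: 0.037}
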