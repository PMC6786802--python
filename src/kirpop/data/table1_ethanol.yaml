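# Ethanol modulation of I_KAch: two-population model parameters.
# Concentrations and dissociation constants in mM.
drug: ethanol
units: mM
voltage: -110
components:
  I_KAch_CONST:
    f_1: 0.68
    K_1: 6
    K_2: 6
    K_3: 0.5
    K_4: 150
    h_0_1: 0.013
    h_1_1: 0.2
    h_2_1: 0.035
    h_0_2: 0.09
    h_1_2: 0.09
    h_2_2: 0.09
  I_KAch_ACH:
    f_1: 0.68
    K_1: 36
    K_2: 36
    K_3: 0.4
    K_4: 150
    h_0_1: 0.13
    h_1_1: 0.85
    h_2_1: 0.09
    h_0_2: 0.9
    h_1_2: 0.7
    h_2_2: 0.05
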