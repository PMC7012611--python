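# Two-population circuit (PC = E, PV = I).
# J in uA.ms/cm^2, rows postsynaptic; tau in ms; null tau where J = 0.
name: two_pop
topology: two_pop
populations: [E, I]
polarity: {E: 1, I: -1}
r0: 5.0
J:
  E: {E: 29.0, I: 30.0}
  I: {E: 36.0, I: 36.0}
J0: {E: 17.0, I: 17.0}
tau:
  E: {E: 4.0, I: 2.0}
  I: {E: 2.0, I: 2.0}
neuron:
  C_M: 1.0
  g_leak: {E: 0.05, I: 0.1}
  V_th: -50.0
  V_R: -70.0
sizes:
  N: 76800
  weights: {E: 3, I: 1}
  K: 500
opto:
  targets: [I]
  I0: 8.0
  Gamma0: 0.5
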