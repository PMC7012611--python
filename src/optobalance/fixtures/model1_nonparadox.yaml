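# Four-population circuit with V1-like architecture (PC, PV, SOM, VIP),
# parameter set in the strong-recurrent-excitation regime (J_EE > J_EE*):
# PV photostimulation is predicted to be non-paradoxical.
name: model1_nonparadox
topology: model1
populations: [E, I, S, V]
polarity: {E: 1, I: -1, S: -1, V: -1}
r0: 5.0
J:
  E: {E: 20.0, I: 26.4, S: 41.0, V: 0.0}
  I: {E: 44.0, I: 28.0, S: 35.6, V: 0.0}
  S: {E: 24.0, I: 0.0, S: 0.0, V: 14.0}
  V: {E: 12.0, I: 35.2, S: 35.0, V: 0.0}
J0: {E: 34.0, I: 27.0, S: 0.0, V: 39.0}
tau:
  E: {E: 4.0, I: 2.0, S: 2.0, V: null}
  I: {E: 2.0, I: 2.0, S: 4.0, V: null}
  S: {E: 2.0, I: null, S: null, V: 4.0}
  V: {E: 4.0, I: 2.0, S: 4.0, V: null}
neuron:
  C_M: 1.0
  g_leak: {E: 0.05, I: 0.1, S: 0.05, V: 0.05}
  V_th: -50.0
  V_R: -70.0
sizes:
  N: 76800
  weights: {E: 9, I: 1, S: 1, V: 1}
  K: 500
opto:
  targets: [I]
  I0: 8.0
  Gamma0: 0.5
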