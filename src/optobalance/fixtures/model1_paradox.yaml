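# Four-population circuit with V1-like architecture (PC, PV, SOM, VIP),
# parameter set in the weak-recurrent-excitation regime (J_EE < J_EE*):
# PV photostimulation is predicted to be paradoxical.
name: model1_paradox
topology: model1
populations: [E, I, S, V]
polarity: {E: 1, I: -1, S: -1, V: -1}
r0: 5.0
J:
  E: {E: 17.4, I: 34.4, S: 32.8, V: 0.0}
  I: {E: 36.6, I: 29.2, S: 28.8, V: 0.0}
  S: {E: 24.2, I: 0.0, S: 0.0, V: 16.8}
  V: {E: 31.2, I: 31.0, S: 14.6, V: 0.0}
J0: {E: 52.0, I: 39.0, S: 0.0, V: 30.0}
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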