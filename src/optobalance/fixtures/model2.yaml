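# Four-population circuit (PC, PV, SOM, X) in which SOM neurons receive
# inputs only from PC and PV, and the unidentified inhibitory class X does
# not project to SOM. The balance of PC and PV inputs onto SOM forces
# proportional PC/PV rate changes; the SOM-X-PC-SOM loop makes PV
# photostimulation paradoxical.
name: model2
topology: model2
populations: [E, I, S, X]
polarity: {E: 1, I: -1, S: -1, X: -1}
r0: 5.0
J:
  E: {E: 20.0, I: 30.0, S: 32.0, X: 36.0}
  I: {E: 40.0, I: 28.0, S: 16.0, X: 32.0}
  S: {E: 26.0, I: 12.0, S: 0.0, X: 0.0}
  X: {E: 24.0, I: 0.0, S: 36.0, X: 22.0}
J0: {E: 48.0, I: 29.0, S: 0.0, X: 24.0}
tau:
  E: {E: 4.0, I: 2.0, S: 2.0, X: 4.0}
  I: {E: 2.0, I: 2.0, S: 4.0, X: 4.0}
  S: {E: 2.0, I: 2.0, S: null, X: null}
  X: {E: 2.0, I: null, S: 4.0, X: 2.0}
neuron:
  C_M: 1.0
  g_leak: {E: 0.05, I: 0.1, S: 0.05, X: 0.05}
  V_th: -50.0
  V_R: -70.0
sizes:
  N: 76800
  weights: {E: 9, I: 1, S: 1, X: 1}
  K: 500
opto:
  targets: [I]
  I0: 8.0
  Gamma0: 0.5
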