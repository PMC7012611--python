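# optobalance

Balanced cortical circuits under optogenetic perturbation: mean-field
theory, spiking-network simulation and spike-train analysis for the
*paradoxical effect* — the observation that photo-exciting parvalbumin
(PV) interneurons can *decrease* their population firing rate.

The package is written for computational neuroscientists who want to ask:
given a circuit of principal cells (PC) and several GABAergic interneuron
classes (PV, SOM, VIP, or an unidentified class X), when does PV
photostimulation suppress the PV population itself, and what does that
reveal about the architecture?

## The model

Neurons are leaky integrate-and-fire units,

    C_M dV/dt = -g_leak (V - V_R) + I_rec + Λ_ext + Λ_opto ,

wired at random with probability `K/N_β` per ordered pair and coupled
through exponential synapses. Interactions follow the strong-coupling
scaling `j_αβ = J_αβ / √K`, so for large `K` the network settles into a
*balanced state*: excitation and inhibition cancel, and the population
rates `r_α` solve the linear **balance equations**

    2 J_α0 r_0 + I_opto,α + Σ_β J_αβ ε_β r_β = 0 ,

with `ε_β = ±1` the presynaptic polarity and `I_opto = I_0 ln(1 + Γ/Γ_0)`
the photocurrent at laser intensity `Γ`. When the drive silences a
population the system switches to a reduced set of equations, making rates
piecewise linear in `I_opto`. The linear response is the susceptibility
`χ = -A⁻¹` (with `A_αβ = ε_β J_αβ`); the sign of `χ_II` decides the
paradox. Closed-form criteria per architecture:

- **two populations** — paradoxical iff `J_EE > 0` (with `det A > 0`),
  i.e. exactly in the inhibition-stabilized regime;
- **V1-like four-population circuit** (PC, PV, SOM, VIP; VIP projects only
  to SOM) — paradoxical iff `J_EE < J_EE* = J_VE J_ES / J_VS`: *weak*
  recurrent excitation, so the disinhibitory loop PC→VIP→SOM→PC dominates;
- **SOM–X circuit** (SOM fed only by PC and PV; X spares SOM) —
  paradoxical iff `J_EX J_XS > J_XX J_ES`, independent of `J_EE`; the SOM
  balance `J_SE r_E = J_SI r_I` pins PC and PV to proportional changes.

Five parameter fixtures ship with the package (`two_pop`, `two_pop_noEE`,
`model1_nonparadox`, `model1_paradox`, `model2`), together with a spiking
simulator, an electrophysiology-style analysis chain (spike-width
classification, average-then-normalize population rates, neuron-level
bootstrap, initial slopes and FS/PC slope ratios, response-category
fractions) and a synthetic-recording generator with known ground truth.

## Worked example

```python
>>> import optobalance as ob
>>> spec, sizes, opto = ob.load_architecture("model2")
>>> st = ob.solve_balance(ob.balance_problem(spec, I_opto=0.0), range(4))
>>> st.rates.round(2)                  # baseline rates (Hz) for E, I, S, X
array([3.04, 6.58, 6.27, 3.97])
>>> audit = ob.paradox_audit(spec)
>>> audit["chi_II"], audit["paradoxical"]
(-0.0372, True)
```

The PC population fires at 3.0 Hz at baseline, and `χ_II < 0` says a weak
photocurrent into PV *lowers* the PV rate — the loop criterion
`J_EX J_XS = 1296 > 704 = J_XX J_ES` confirms it. Running
`python examples/paradox_audit.py` prints the same audit for all five
circuits:

```
two_pop            chi_II= -0.8056  paradoxical=True   det=36
two_pop_noEE       chi_II= +0.0000  paradoxical=False  det=1.08e+03
model1_nonparadox  chi_II= +0.0140  paradoxical=False  J_EE*= 14.06 vs J_EE= 20.0
model1_paradox     chi_II= -0.0655  paradoxical=True   J_EE*= 70.09 vs J_EE= 17.4
model2             chi_II= -0.0372  paradoxical=True   loop criteria={'paradox': True, ...}
```

The other scripts in `examples/` each exercise one capability: the
piecewise mean-field sweep (`balance_sweep.py`), a reduced-scale spiking
run with balanced-state statistics (`simulate_circuit.py`), the full
analysis of a synthetic recording (`analyze_synthetic_recording.py`), and
a side-by-side theory/simulation comparison (`theory_vs_simulation.py`).

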