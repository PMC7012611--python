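"""Mean-field rates of the SOM-X circuit as the optogenetic drive grows.

Solves the balance equations along a photocurrent grid and prints the
piecewise-linear population rates, the breakpoints where populations
silence, and the proportional PC/PV suppression forced by the SOM balance.
"""

import numpy as np

import optobalance as ob

spec, _, opto = ob.load_architecture("model2")
grid = np.linspace(0.0, 120.0, 25)          # photocurrent, nA/cm^2
sweep = ob.sweep_opto(spec, I_grid=grid)

print("I_opto [nA/cm^2]   " + "  ".join(f"r_{n:>2s}" for n in spec.names) + "   active")
for k, I in enumerate(grid):
    rates = "  ".join(f"{r:5.2f}" for r in sweep.rates[k])
    act = "+".join(spec.names[i] for i in sorted(sweep.active_sets[k]))
    print(f"{I:14.1f}   {rates}   {act}")

print("\nbreakpoints (active set changes), nA/cm^2:",
      [round(b, 3) for b in sweep.breakpoints])
ratio = ob.proportionality_ratio(spec)
print(f"while SOM is active, r_I / r_E is pinned to J_SE/J_SI = {ratio['ratio']:.3f}:")
all4 = [k for k, s in enumerate(sweep.active_sets) if len(s) == 4]
print("  observed ratios:", np.round(sweep.rates[all4, 1] / sweep.rates[all4, 0], 3))
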