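# Methods

## Scope and model

`optobalance` implements a mean-field and spiking account of how cortical
circuits of principal cells (PC, label `E`) and GABAergic interneuron
classes — parvalbumin-positive (PV, `I`), somatostatin-positive (SOM, `S`)
and either VIP (`V`) or an unidentified inhibitory class (`X`) — respond
to optogenetic excitation of the PV population. Three architectures are
covered:

- a two-population PC/PV circuit;
- a V1-like four-population circuit in which VIP projects only to SOM,
  SOM neurons do not inhibit each other, PV does not project to SOM, and
  SOM receives no feedforward drive;
- a SOM–X circuit in which SOM receives input only from PC and PV, and X
  (recurrently coupled, driven by PC and SOM) spares SOM.

All neurons within a population are identical; connectivity is
unstructured (independent Bernoulli with probability `K/N_β` per ordered
pair, no self-connections, no multiple contacts). This reflects the
experimental situation the models address — a laser spot much wider than
the interaction range — and is a deliberate simplification: no spatial
structure, no interlaminar pathways, no short-term plasticity, no
conductance-based synapses, no per-neuron parameter heterogeneity.

## Units

Two internally consistent conventions are used and converted explicitly:

- **Theory side** — rates in Hz, currents in nA/cm², interaction
  strengths `J` in µA·ms/cm². With these units `J_αβ · r_β` and
  `2 J_α0 r_0` are both in nA/cm², and the photocurrent amplitude
  `I_0 = 8 nA/cm²` enters the balance equations directly. The absolute
  current scale cannot be pinned more tightly than this from the source
  material (surface-density vs absolute units are mixed there); all
  dimensionless predictions are unaffected, but the absolute mapping from
  laser intensity to firing-rate change may carry a scale factor on Γ.
- **Simulation side** — time in ms, voltage in mV, `C_M` in µF/cm²,
  `g_leak` in mS/cm², currents in µA/cm². The finite-size couplings are
  `j = J/√K`; the feedforward drive is the deterministic constant current
  `Λ_ext = 2 K j_0 r_0` (no external Poisson spikes — the expression is
  used verbatim), and the optogenetic drive is `Λ_opto = √K · I_opto`.

The photocurrent law is `I_opto = I_0 ln(1 + Γ/Γ_0)` with the natural
logarithm (a base change only rescales `Γ_0 = 0.5 mW/mm²`).

## Balance theory

For an active set `A` of populations the rates solve the linear system
`c + A_sub r = 0` with `A_αβ = ε_β J_αβ` and `c_α = 2 J_α0 r_0 + I_opto,α`.
A state is accepted when all active rates are strictly positive and every
silent population receives hyperpolarizing net input. Numerical
conventions: rates within 1e-12 of zero are treated as zero; silent-input
consistency requires input < +1e-12; a (near-)singular active block raises
a dedicated degenerate-determinant signal rather than returning a state
(rates are then not pinned by balance — the fine-tuned case).

`consistent_states` enumerates all 2ⁿ subsets exhaustively (n ≤ 5 in
practice). Sweeps follow the state continuous with the previous grid point
and fall back to the largest active set, reporting multiplicity;
active-set changes are located by bisection to |ΔI| ≤ 1e-8 nA/cm².

The susceptibility is `χ = -A_sub⁻¹`, embedded with zero rows/columns for
silent populations (their rate is pinned at zero under small
perturbations). Stability is checked only through the necessary
rate-divergence condition, implemented as `det(-A) > 0`; for the
even-dimensional reference circuits this is identical to `det(A) > 0`,
and for odd dimensions it carries the correct sign (a single
self-inhibiting population, `det A = -J_II < 0`, is stable). The full
dynamical stability problem, which involves the synaptic time constants,
is out of scope.

`paradox_audit` evaluates the closed-form criteria (`J_EE` vs
`J_EE* = J_VE J_ES / J_VS`; `J_EX J_XS` vs `J_XX J_ES`, plus the
feedforward-monotonicity companion `J_IX J_XS > J_XX J_IS`; `J_EE > 0`
with `det A > 0` for two populations) and cross-checks every boolean
against `sign(χ_II)`, warning on disagreement. Unsupported topologies get
the generic `sign(χ_II)` result.

## Spiking simulation

Leaky integrate-and-fire voltages are integrated with a second-order
Runge-Kutta (Heun) step; threshold crossings are detected at the end of
the step without spike-time interpolation (equality with threshold counts
as a spike), and spikes are recorded at the end-of-step time. The
exponential synaptic traces are advanced *exactly* (factor `exp(-dt/τ)`
per step, jump `1/τ` per presynaptic spike) rather than inside the RK2
stages: this is mathematically equivalent to the kernel-sum definition
and avoids integrator error on the stiff synaptic variable. All traces of
presynaptic population β converging on one neuron share a time constant
and are aggregated into a single state variable per (neuron, β) channel.

Initial conditions: V uniform on [V_R, V_th), traces at zero; a 0.5–1 s
warmup is discarded. No refractory period and no synaptic delays are
modelled (none are specified for these circuits). Any |V| > 1000 mV
aborts the run with a diagnostic.

Connectivity realizations draw each neuron's in-degree from the exact
binomial and then a uniform distinct presynaptic subset — equivalent to
independent Bernoulli wiring — and are deterministic given the seed.
Blocks with `J_αβ = 0` carry no synapses and are skipped.

## Problem sizes

Publication scale is N = 76800, K = 500, 100 s of simulated activity and
dt = 0.01 ms (available through
`ExperimentConfig(paper_scale=True)`; CPU-hours per intensity point). The
test suite uses reduced scales chosen as the package's own trade-off
between statistics and runtime:

- qualitative paradox surrogates: N = 9600, K = 250, 4 s after 0.5 s
  warmup, dt = 0.02 ms; probe intensities were chosen **a priori from the
  mean-field solution** (inside the all-active segment, predicted PV-rate
  change large against counting noise): Γ = 3 mW/mm² for the
  two-population circuits (~15 nA/cm², well below the 34 nA/cm²
  PC-silencing breakpoint) and Γ = 20 mW/mm² (~30 nA/cm²) for the
  four-population circuits;
- convergence-with-K checks on a fixed-N/K ladder (K = 64, 128, 256,
  N = 24K);
- time-step robustness at dt = 0.01 vs 0.005 ms on an 8 s run (shorter
  runs confound the ~1 % discretization effect with temporal sampling
  noise; different connectivity seeds differ by ~20 % at this scale, so
  all dt comparisons share one realization).

At these scales finite-K corrections to the balance rates are large
(tens of percent — they scale as 1/√K and are documented as strong even
at K = 2000), so only signs, orderings and proportionality relations are
asserted against theory, never absolute rates. Very small, fast-driven
two-population nets (K ≈ 50) can synchronize into bursts that overflow
the integrator at dt = 0.02 ms; tiny plumbing tests therefore run at the
default dt = 0.01 ms.

## Spike-train analysis

Units are classified by trough-to-peak spike width: fast-spiking
(putatively PV+) below 0.35 ms, putative pyramidal above 0.45 ms,
boundary and intermediate widths excluded (strict inequalities). Rates
are counts over the 1 s stimulation window and the 500 ms pre-stimulus
window. The per-unit baseline pools the pre-stimulus windows of *all*
trials (the upcoming stimulus cannot affect them, and pooling halves the
baseline noise); each response curve is anchored by an intensity-0
reference row whose normalized value is exactly 1 — the no-stimulation
condition *is* baseline. Population normalized rates average rates across
units first and normalize afterwards, which weights units by their firing
rate and is not the mean of per-unit ratios.

Uncertainty is bootstrap over neurons (whole units resampled with
replacement; default 10 000 replicates, seeded). Initial response slopes
are unweighted ordinary least squares of normalized rate vs laser
intensity over points at or below a stated maximum (weighting by trial
counts is a possible alternative; unweighted was chosen as the estimator
is applied to balanced designs). The FS/PC slope ratio resamples the two
classes independently; its SEM is the spread of the resampled-ratio
distribution. Response categories per unit: silenced (stimulation-window
rate < 0.1 Hz, evaluated regardless of baseline and taking precedence),
then increase / decrease / no-change by a ±0.1 Hz rate change.

## Synthetic recordings

The generator emulates the statistical structure the analysis assumes:
units per class (default 52 PC / 8 FS, a barrel-cortex-sized dataset;
other presets cover 26/9 and 62/12 configurations), lognormal baselines
(default median 5 Hz, σ_log chosen per experiment), spike widths uniform
inside the class bands, an intensity grid (defaults: 0.5–12 or 0.3–15
mW/mm²) with 20 trials per intensity (a typical session size; the true
per-intensity trial counts of such experiments are rarely reported),
1.3 s stimulation epochs analysed over 1 s, 500 ms baselines, ~7 s
inter-trial intervals. Each unit's normalized response is a shared
population template scaled by a Normal(1, σ_gain) unit gain, optionally
sign-flipped in a programmed fraction of units to create incongruous
responders; requested rates are clipped at zero before the Poisson
sampler ever sees them.

Spiking is homogeneous Poisson within each window: the analysis consumes
window counts only, so finer ISI structure would add cost without
changing any downstream statistic. The ~40 Hz temporal modulation of a
real photostimulus and the masking flash are likewise integrated over by
the windows and not modelled. What passing tests show is therefore that
the *analysis chain* is correct and recovers programmed population
slopes, ratios and category fractions under realistic counting noise and
heterogeneity — not that real recordings satisfy the generator's
assumptions (no waveform variability, no behavioural covariates, no
cross-trial nonstationarity).

Ground truth comes in two forms: the *realized* truth attached to each
generated recording (computed from the drawn baselines and gains with the
same average-then-normalize convention as the analysis) and an
expectation-level `ground_truth(config)` that ignores clipping and uses
the mean gain `1 - 2p` under sign-flip fraction p. Recovery tests compare
against the realized truth: with few units per class (8 FS is typical)
the realized mean gain deviates from 1 by design, and the neuron-level
bootstrap quantifies exactly that unit-sampling uncertainty.

`from_simulation` converts an intensity sweep of the spiking network into
the recording format: stimulation epochs are consecutive slices of the
constant-Γ run and each trial's pre-stimulus window is the matching slice
of the Γ = 0 run, mirroring the experimental design in which every
baseline window is unstimulated. E maps to PC and I to FS with synthetic
widths inside the class bands; other populations are not probed, as in
the experiments.

## Known limitations

- Printed magnitudes of χ_II reported alongside the reference parameter
  sets (e.g. 1.6 and −5.1) are not reproducible under any unit convention
  tried here; the implied normalization is not derivable from the
  available material, so only signs are asserted. In this package's
  units (Hz per nA/cm²) the corresponding values are +0.014 and −0.066.
- The printed baseline rates 6.7/6.4/3.8 Hz for PV/SOM/X of the SOM–X
  circuit are mutually inconsistent with its connection table, whose SOM
  balance forces r_I/r_E = 26/12; the tables are treated as ground truth,
  giving (3.04, 6.58, 6.27, 3.97) Hz.
- Loop-gain decompositions of χ are validated numerically (criteria vs
  sign of χ_II), not re-derived symbolically; finite-K analytic
  corrections are not implemented.
- Absolute Γ-to-rate mapping carries a possible scale factor on Γ (see
  Units); comparisons across intensity are unaffected.
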