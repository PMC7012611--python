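"""Large-N,K balance theory: rates, piecewise states, susceptibility, criteria.

In the strong-coupling limit the net input into every active population must
stay finite, which pins the population rates to the linear *balance
equations*

    2 J_a0 r0 + I_opto_a + sum_b J_ab eps_b r_b = 0 ,

one equation per active population.  Populations driven below zero rate are
silent; they are consistent only if their net input is hyperpolarizing.  As
the optogenetic drive grows, the set of active populations changes at
*breakpoints*, so rates are piecewise linear in the drive.

The susceptibility matrix chi = -A^(-1) (A restricted to the active set,
A_ab = eps_b J_ab) gives the linear response of the rates to small extra
inputs; its II element decides whether photostimulating PV is paradoxical.

Units follow :mod:`optobalance.circuits`: rates in Hz, currents in nA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .circuits import CircuitSpec, OptoSpec, effective_matrix, opto_drive

__all__ = [
    "BalanceProblem",
    "BalanceState",
    "SweepResult",
    "DegenerateCircuitError",
    "balance_problem",
    "solve_balance",
    "consistent_states",
    "sweep_opto",
    "susceptibility",
    "paradox_audit",
    "stability_check",
    "proportionality_ratio",
]

RATE_TOL = 1e-12    # rates above -RATE_TOL are clipped to zero
INPUT_TOL = 1e-12   # silent populations need net input < +INPUT_TOL
BREAKPOINT_TOL = 1e-8


class DegenerateCircuitError(np.linalg.LinAlgError):
    """The balance system restricted to the active set has a (near-)zero
    determinant — the fine-tuned case in which rates are not pinned by the
    balance conditions."""


@dataclass(frozen=True)
class BalanceProblem:
    """Signed interaction matrix A and input vector c of the balance system."""

    A: np.ndarray       # (n, n), uA.ms/cm^2, A = J * eps
    c: np.ndarray       # (n,), nA/cm^2: 2 J0 r0 + I_opto
    names: tuple[str, ...]


@dataclass(frozen=True)
class BalanceState:
    """One (partially) balanced solution.

    ``rates`` are in Hz with zeros for silent populations;
    ``silent_inputs`` holds the net input of each silent population
    (NaN for active ones); ``consistent`` requires nonnegative active rates
    and hyperpolarizing silent inputs.
    """

    active: frozenset[int]
    rates: np.ndarray
    silent_inputs: np.ndarray
    consistent: bool
    residual: float

    @property
    def n_active(self) -> int:
        return len(self.active)


@dataclass
class SweepResult:
    """Rates along an optogenetic-drive grid, with the piecewise structure."""

    I_opto: np.ndarray            # nA/cm^2
    Gamma: np.ndarray | None      # mW/mm^2 (None for a direct current grid)
    rates: np.ndarray             # (n_grid, n_pop), Hz
    normalized: np.ndarray        # rates / baseline rates (NaN if baseline 0)
    active_sets: list[frozenset[int]]
    breakpoints: list[float]      # I_opto values where the active set changes
    multiplicity: np.ndarray      # number of consistent states per grid point
    names: tuple[str, ...]


def balance_problem(
    spec: CircuitSpec,
    I_opto: float | np.ndarray = 0.0,
    opto: OptoSpec | None = None,
) -> BalanceProblem:
    """Assemble A and c.  ``I_opto`` may be a scalar applied to the opto
    targets (default: population I) or a full per-population vector."""
    A = effective_matrix(spec)
    c = 2.0 * spec.J0 * spec.r0
    I = np.asarray(I_opto, dtype=float)
    if I.ndim == 0:
        targets = (opto.targets if opto is not None else ("I",))
        vec = np.zeros(spec.n_pop)
        for t in targets:
            if t in spec.names:
                vec[spec.index(t)] = float(I)
        I = vec
    return BalanceProblem(A=A, c=c + I, names=spec.names)


def solve_balance(problem: BalanceProblem, active: Sequence[int] | frozenset[int]) -> BalanceState:
    """Solve the balance equations restricted to ``active``.

    Rates of silent populations are zero; their net inputs are computed and
    the consistency flag is set (active rates nonnegative, silent inputs
    hyperpolarizing).  Raises :class:`DegenerateCircuitError` if the active
    block is singular.
    """
    n = len(problem.c)
    act = sorted(active)
    sil = [i for i in range(n) if i not in active]
    rates = np.zeros(n)
    residual = 0.0
    if act:
        block = problem.A[np.ix_(act, act)]
        if abs(np.linalg.det(block)) < 1e-12 * max(1.0, np.abs(block).max()) ** len(act):
            raise DegenerateCircuitError(
                f"degenerate determinant for active set {tuple(problem.names[i] for i in act)}"
            )
        r_act = np.linalg.solve(block, -problem.c[act])
        rates[act] = r_act
        residual = float(np.abs(problem.c[act] + block @ r_act).max())
    silent_inputs = np.full(n, np.nan)
    if sil:
        silent_inputs[sil] = problem.c[sil] + problem.A[np.ix_(sil, act)] @ rates[act] \
            if act else problem.c[sil]
    rates_ok = np.all(rates[act] >= -RATE_TOL) if act else True
    rates[np.abs(rates) <= RATE_TOL] = 0.0
    inputs_ok = np.all(silent_inputs[sil] < INPUT_TOL) if sil else True
    return BalanceState(
        active=frozenset(act), rates=rates, silent_inputs=silent_inputs,
        consistent=bool(rates_ok and inputs_ok and np.all(rates[act] > 0) if act
                        else bool(inputs_ok)),
        residual=residual,
    )


def consistent_states(problem: BalanceProblem) -> list[BalanceState]:
    """All self-consistent (partially) balanced states, by exhaustive
    enumeration of the 2^n active subsets (including the all-silent state),
    ordered by active-set size descending."""
    n = len(problem.c)
    states = []
    for k in range(n, -1, -1):
        for subset in combinations(range(n), k):
            try:
                st = solve_balance(problem, subset)
            except DegenerateCircuitError:
                continue
            if st.consistent:
                states.append(st)
    return states


def susceptibility(
    spec: CircuitSpec | np.ndarray,
    active: Sequence[int] | frozenset[int] | None = None,
) -> np.ndarray:
    """chi = -A^(-1) on the active block, embedded with zero rows/columns for
    silent populations (their rate is pinned at zero under small
    perturbations).  Units: Hz per nA/cm^2."""
    A = effective_matrix(spec) if isinstance(spec, CircuitSpec) else np.asarray(spec, float)
    n = A.shape[0]
    act = sorted(active) if active is not None else list(range(n))
    block = A[np.ix_(act, act)]
    if abs(np.linalg.det(block)) < 1e-12 * max(1.0, np.abs(block).max()) ** len(act):
        raise DegenerateCircuitError("degenerate determinant in susceptibility")
    chi = np.zeros((n, n))
    chi[np.ix_(act, act)] = -np.linalg.inv(block)
    return chi


def stability_check(spec: CircuitSpec) -> dict:
    """Necessary condition for stability of the balanced state: det(A) > 0.

    This guards only against rate divergence; the full dynamical stability
    (which involves the synaptic time constants) is not assessed here.
    """
    A = effective_matrix(spec)
    det = float(np.linalg.det(A))
    # guard against rate divergence: det(-A) > 0, which for the
    # even-dimensional reference circuits is exactly det(A) > 0
    return {"det": det, "necessary_ok": float(np.linalg.det(-A)) > 0}


def proportionality_ratio(spec: CircuitSpec, state: BalanceState | None = None) -> dict:
    """The rate pair forced proportional by the SOM balance equation.

    The SOM population receives no feedforward or optogenetic drive, so its
    balance equation ties its two input populations together: in the V1-like
    circuit (PC and VIP inputs) r_V / r_E = J_SE / J_SV; in the circuit where
    SOM receives PC and PV, r_I / r_E = J_SE / J_SI.  Not applicable when
    SOM is silent.
    """
    names = spec.names
    if spec.topology == "model1":
        pair, ratio = ("E", "V"), spec.J[names.index("S"), names.index("E")] / \
            spec.J[names.index("S"), names.index("V")]
    elif spec.topology == "model2":
        pair, ratio = ("E", "I"), spec.J[names.index("S"), names.index("E")] / \
            spec.J[names.index("S"), names.index("I")]
    else:
        raise ValueError(f"no proportionality prediction for topology {spec.topology!r}")
    out = {"pair": pair, "ratio": float(ratio), "applicable": True}
    if state is not None:
        s_idx = names.index("S")
        if s_idx not in state.active:
            out["applicable"] = False
    return out


def paradox_audit(spec: CircuitSpec, opto: OptoSpec | None = None) -> dict:
    """Paradoxical-effect criteria for the supported topologies.

    two_pop:  paradoxical iff J_EE > 0 (with det A > 0).
    model1:   paradoxical iff J_EE < J_EE* = J_VE J_ES / J_VS  (the gain of
              the PC->VIP->SOM disinhibitory pathway against direct
              recurrent excitation).
    model2:   paradoxical iff J_EX J_XS > J_XX J_ES (gain of the
              SOM->X->PC->SOM loop); the feedforward-monotonicity constraint
              J_IX J_XS > J_XX J_IS is evaluated alongside.

    Every boolean is cross-checked against sign(chi_II); unsupported
    topologies fall back to the generic sign(chi_II) result with a warning
    entry.
    """
    names = spec.names
    chi = susceptibility(spec)
    i_I = names.index("I") if "I" in names else None
    chi_II = float(chi[i_I, i_I]) if i_I is not None else float("nan")
    report: dict = {
        "topology": spec.topology,
        "chi_II": chi_II,
        "paradoxical": bool(chi_II < 0),
        "det": stability_check(spec)["det"],
        "margins": {},
        "warnings": [],
    }

    def J(a: str, b: str) -> float:
        return float(spec.J[names.index(a), names.index(b)])

    if spec.topology == "two_pop":
        report["two_pop_criterion"] = bool(J("E", "E") > 0 and report["det"] > 0)
        report["margins"]["J_EE"] = J("E", "E")
        _check(report, report["two_pop_criterion"], chi_II)
    elif spec.topology == "model1":
        jee_star = J("V", "E") * J("E", "S") / J("V", "S")
        report["jee_star"] = jee_star
        report["model1_paradox"] = bool(J("E", "E") < jee_star)
        report["margins"]["jee_star_minus_jee"] = jee_star - J("E", "E")
        _check(report, report["model1_paradox"], chi_II)
    elif spec.topology == "model2":
        lhs_p, rhs_p = J("E", "X") * J("X", "S"), J("X", "X") * J("E", "S")
        lhs_f, rhs_f = J("I", "X") * J("X", "S"), J("X", "X") * J("I", "S")
        report["model2_loop_criteria"] = {
            "paradox": bool(lhs_p > rhs_p),
            "ff_monotonic": bool(lhs_f > rhs_f),
        }
        report["margins"]["loop_minus_direct"] = lhs_p - rhs_p
        report["margins"]["ff_loop_minus_direct"] = lhs_f - rhs_f
        _check(report, report["model2_loop_criteria"]["paradox"], chi_II)
    else:
        report["warnings"].append(
            f"unsupported topology {spec.topology!r}: generic sign(chi_II) only"
        )
    return report


def _check(report: dict, criterion_bool: bool, chi_II: float) -> None:
    if criterion_bool != (chi_II < 0):
        report["warnings"].append(
            f"criterion ({criterion_bool}) disagrees with sign(chi_II) ({chi_II:.4g})"
        )


# ---------------------------------------------------------------------------
# sweeps

def _state_at(spec: CircuitSpec, I: float, opto: OptoSpec | None,
              prev_active: frozenset[int] | None) -> tuple[BalanceState, int]:
    problem = balance_problem(spec, I, opto)
    states = consistent_states(problem)
    if not states:
        raise RuntimeError(f"no consistent balanced state at I_opto={I:.6g}")
    if prev_active is not None:
        for st in states:
            if st.active == prev_active:
                return st, len(states)
    return states[0], len(states)


def sweep_opto(
    spec: CircuitSpec,
    I_grid: np.ndarray | None = None,
    Gamma_grid: np.ndarray | None = None,
    opto: OptoSpec | None = None,
) -> SweepResult:
    """Piecewise-linear rates along a drive grid.

    Exactly one of ``I_grid`` (photocurrent, nA/cm^2) or ``Gamma_grid``
    (laser intensity, mW/mm^2, mapped through the logarithmic photocurrent
    law of ``opto``) must be given.  At each point the consistent state
    continuous with the previous grid point is followed (falling back to the
    largest active set); active-set changes are located by bisection.
    """
    from .circuits import opto_current  # local import to avoid cycle at module load

    if (I_grid is None) == (Gamma_grid is None):
        raise ValueError("give exactly one of I_grid or Gamma_grid")
    if Gamma_grid is not None:
        Gamma_grid = np.asarray(Gamma_grid, dtype=float)
        if opto is None:
            opto = OptoSpec()
        I_grid = np.asarray(opto_current(Gamma_grid, opto), dtype=float)
    else:
        I_grid = np.asarray(I_grid, dtype=float)

    rates = np.zeros((len(I_grid), spec.n_pop))
    active_sets: list[frozenset[int]] = []
    multiplicity = np.zeros(len(I_grid), dtype=int)
    prev: frozenset[int] | None = None
    for k, I in enumerate(I_grid):
        st, mult = _state_at(spec, float(I), opto, prev)
        rates[k] = st.rates
        active_sets.append(st.active)
        multiplicity[k] = mult
        prev = st.active

    baseline = rates[np.argmin(np.abs(I_grid))] if len(I_grid) else None
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(baseline > 0, rates / baseline, np.nan)

    breakpoints = []
    for k in range(1, len(I_grid)):
        if active_sets[k] != active_sets[k - 1]:
            breakpoints.append(
                _bisect_breakpoint(spec, opto, float(I_grid[k - 1]), float(I_grid[k]),
                                   active_sets[k - 1])
            )
    return SweepResult(
        I_opto=I_grid, Gamma=Gamma_grid, rates=rates, normalized=normalized,
        active_sets=active_sets, breakpoints=breakpoints,
        multiplicity=multiplicity, names=spec.names,
    )


def _bisect_breakpoint(spec: CircuitSpec, opto: OptoSpec | None,
                       lo: float, hi: float, active_lo: frozenset[int]) -> float:
    """Bisect on the active-set change to |dI| <= BREAKPOINT_TOL."""
    while hi - lo > BREAKPOINT_TOL:
        mid = 0.5 * (lo + hi)
        st, _ = _state_at(spec, mid, opto, active_lo)
        if st.active == active_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
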