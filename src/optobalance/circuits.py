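"""Circuit architectures, parameter fixtures and finite-size scaling.

A :class:`CircuitSpec` is the single source of truth for a network
architecture: the ordered populations with their polarities, the
dimensionless interaction strengths ``J`` (uA.ms/cm^2, rows postsynaptic),
the feedforward strengths ``J0``, the synaptic time constants ``tau`` (ms,
NaN wherever ``J`` is zero) and the single-neuron constants.

Unit conventions
----------------
The mean-field ("theory") side works with population rates in Hz and
currents in nA/cm^2: with ``J`` in uA.ms/cm^2 and rates in Hz the product
``J * r`` is in nA/cm^2, so the feedforward term ``2 * J0 * r0`` and the
optogenetic current ``I0 * log(1 + Gamma/Gamma0)`` with ``I0`` = 8 nA/cm^2
are directly commensurable.  The spiking ("simulation") side works in ms,
mV and uA/cm^2; :func:`scale_to_finite_K` converts between the two by the
strong-coupling rule ``j = J / sqrt(K)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PopulationLabel",
    "NeuronParams",
    "CircuitSpec",
    "SizeSpec",
    "OptoSpec",
    "FiniteCouplings",
    "Diagnostic",
    "FIXTURE_NAMES",
    "load_architecture",
    "dump_architecture",
    "opto_current",
    "opto_drive",
    "scale_to_finite_K",
    "effective_matrix",
    "validate_spec",
]

FIXTURE_NAMES = (
    "two_pop",
    "two_pop_noEE",
    "model1_nonparadox",
    "model1_paradox",
    "model2",
)

#: structural zeros per topology: entries of J that the architecture forbids,
#: as (postsynaptic, presynaptic) name pairs; "0" denotes the feedforward column.
_STRUCTURAL_ZEROS = {
    "two_pop": (),
    "model1": (
        ("E", "V"), ("I", "V"),            # VIP projects only to SOM
        ("S", "I"), ("S", "S"), ("V", "V"),  # no PV->SOM, no SOM-SOM / VIP-VIP mutual inhibition
        ("S", "0"),                          # SOM receives no feedforward drive
    ),
    "model2": (
        ("S", "S"), ("S", "X"),  # SOM receives only PC and PV input
        ("X", "I"),              # PV does not project to X
        ("S", "0"),
    ),
}

#: connections absent from the reference architectures but reported in some
#: anatomical studies; their presence is a warning, not an error.
_TOLERATED_EXTRAS = {"model1": (("S", "I"),)}


@dataclass(frozen=True)
class PopulationLabel:
    """A population name with its synaptic polarity (+1 excitatory, -1 inhibitory)."""

    name: str
    polarity: int

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError(f"polarity must be +1 or -1, got {self.polarity}")


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire constants for one population.

    C_M in uF/cm^2, g_leak in mS/cm^2, voltages in mV.  The rheobase current
    is ``g_leak * (V_th - V_R)`` (uA/cm^2).
    """

    C_M: float = 1.0
    g_leak: float = 0.05
    V_th: float = -50.0
    V_R: float = -70.0

    def __post_init__(self) -> None:
        if not self.V_th > self.V_R:
            raise ValueError("V_th must exceed V_R")
        if self.C_M <= 0 or self.g_leak <= 0:
            raise ValueError("C_M and g_leak must be positive")

    @property
    def rheobase(self) -> float:
        return self.g_leak * (self.V_th - self.V_R)


@dataclass
class CircuitSpec:
    """Dimensionless-theory parameters of a circuit architecture."""

    populations: tuple[PopulationLabel, ...]
    J: np.ndarray          # (n, n), uA.ms/cm^2, rows postsynaptic
    J0: np.ndarray         # (n,), uA.ms/cm^2
    tau: np.ndarray        # (n, n), ms; NaN where J == 0
    neuron: tuple[NeuronParams, ...]
    r0: float = 5.0        # external rate, Hz
    name: str = "custom"
    topology: str = "generic"

    def __post_init__(self) -> None:
        n = len(self.populations)
        self.J = np.asarray(self.J, dtype=float)
        self.J0 = np.asarray(self.J0, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.J.shape != (n, n) or self.tau.shape != (n, n) or self.J0.shape != (n,):
            raise ValueError("J, tau must be (n, n) and J0 (n,) for n populations")
        if len(self.neuron) != n:
            raise ValueError("one NeuronParams per population required")

    @property
    def n_pop(self) -> int:
        return len(self.populations)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)

    @property
    def polarities(self) -> np.ndarray:
        return np.array([p.polarity for p in self.populations], dtype=float)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def with_J(self, J: np.ndarray, name: str | None = None) -> "CircuitSpec":
        """Copy of this spec with a replacement interaction matrix."""
        return replace(self, J=np.asarray(J, dtype=float),
                       name=name or self.name)


@dataclass(frozen=True)
class SizeSpec:
    """Finite-network size: total count, population fractions, mean in-degree."""

    N: int
    fractions: tuple[float, ...]
    K: int

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("population fractions must sum to 1")
        if self.K < 1 or self.N < 1:
            raise ValueError("N and K must be positive")

    @property
    def counts(self) -> np.ndarray:
        counts = np.array([round(f * self.N) for f in self.fractions], dtype=int)
        counts[-1] += self.N - counts.sum()  # absorb rounding in the last population
        return counts

    def scaled(self, N: int | None = None, K: int | None = None) -> "SizeSpec":
        return SizeSpec(N=N if N is not None else self.N,
                        fractions=self.fractions,
                        K=K if K is not None else self.K)


@dataclass(frozen=True)
class OptoSpec:
    """Optogenetic drive: targeted populations and the intensity-to-current law.

    The photocurrent is ``I_opto = I0 * ln(1 + Gamma / Gamma0)`` with ``I0``
    in nA/cm^2 and the laser intensity ``Gamma`` in mW/mm^2 (natural log; a
    base change only rescales Gamma0).
    """

    targets: tuple[str, ...] = ("I",)
    I0: float = 8.0
    Gamma0: float = 0.5


@dataclass(frozen=True)
class FiniteCouplings:
    """Finite-K simulation parameters derived from a CircuitSpec.

    j = J / sqrt(K) (uA.ms/cm^2); lam_ext = 2 K j0 r0 (uA/cm^2, with r0 in
    ms^-1); the optogenetic amplitude is sqrt(K) * I_opto.
    """

    K: int
    j: np.ndarray
    j0: np.ndarray
    lam_ext: np.ndarray

    def lam_opto(self, I_opto_nA: float | np.ndarray) -> np.ndarray:
        """Optogenetic input amplitude (uA/cm^2) from I_opto in nA/cm^2."""
        return math.sqrt(self.K) * np.asarray(I_opto_nA, dtype=float) * 1e-3


@dataclass(frozen=True)
class Diagnostic:
    level: str   # "error" | "warning"
    field: str
    message: str


# ---------------------------------------------------------------------------
# loading / serialization

def _fixture_text(name: str) -> str:
    return (resources.files("optobalance") / "fixtures" / f"{name}.yaml").read_text()


def load_architecture(
    name_or_config: str | Path | Mapping,
) -> tuple[CircuitSpec, SizeSpec, OptoSpec]:
    """Load a named fixture, a YAML/JSON file path, or a config mapping.

    Named fixtures (``two_pop``, ``two_pop_noEE``, ``model1_nonparadox``,
    ``model1_paradox``, ``model2``) reproduce the reference parameter tables
    exactly.  Raises ``ValueError`` with field-by-field diagnostics if the
    config violates the spec invariants.
    """
    if isinstance(name_or_config, Mapping):
        cfg = dict(name_or_config)
    else:
        key = str(name_or_config)
        if key in FIXTURE_NAMES:
            cfg = yaml.safe_load(_fixture_text(key))
        else:
            path = Path(key)
            if not path.exists():
                raise ValueError(
                    f"unknown architecture {key!r}: not a fixture "
                    f"{FIXTURE_NAMES} and not an existing file"
                )
            cfg = yaml.safe_load(path.read_text())
    return _parse_config(cfg)


def _parse_config(cfg: Mapping) -> tuple[CircuitSpec, SizeSpec, OptoSpec]:
    names = list(cfg["populations"])
    pol = cfg.get("polarity", {})
    pops = tuple(PopulationLabel(n, int(pol.get(n, -1 if n != "E" else 1))) for n in names)
    n = len(names)

    def matrix(block: Mapping, fill: float) -> np.ndarray:
        M = np.full((n, n), fill, dtype=float)
        for i, post in enumerate(names):
            row = block.get(post, {})
            for j_, pre in enumerate(names):
                v = row.get(pre)
                if v is not None:
                    M[i, j_] = float(v)
        return M

    J = matrix(cfg["J"], 0.0)
    tau = matrix(cfg.get("tau", {}), np.nan)
    J0 = np.array([float(cfg["J0"].get(nm, 0.0)) for nm in names])

    neuron_cfg = cfg.get("neuron", {})
    gl = neuron_cfg.get("g_leak", {})
    if not isinstance(gl, Mapping):
        gl = {nm: gl for nm in names}
    neuron = tuple(
        NeuronParams(
            C_M=float(neuron_cfg.get("C_M", 1.0)),
            g_leak=float(gl.get(nm, 0.05)),
            V_th=float(neuron_cfg.get("V_th", -50.0)),
            V_R=float(neuron_cfg.get("V_R", -70.0)),
        )
        for nm in names
    )

    # couplings may be given dimensionless (J) or finite-size (j, with K);
    # normalize to J = j * sqrt(K)
    if cfg.get("couplings") == "finite":
        K = int(cfg["sizes"]["K"])
        J = J * math.sqrt(K)
        J0 = J0 * math.sqrt(K)

    spec = CircuitSpec(
        populations=pops, J=J, J0=J0, tau=tau, neuron=neuron,
        r0=float(cfg.get("r0", 5.0)),
        name=str(cfg.get("name", "custom")),
        topology=str(cfg.get("topology", "generic")),
    )

    sizes_cfg = cfg.get("sizes", {})
    weights = sizes_cfg.get("weights")
    if weights is not None:
        w = np.array([float(weights[nm]) for nm in names])
        fractions = tuple(w / w.sum())
    else:
        fractions = tuple(float(sizes_cfg["fractions"][nm]) for nm in names)
    sizes = SizeSpec(N=int(sizes_cfg.get("N", 76800)), fractions=fractions,
                     K=int(sizes_cfg.get("K", 500)))

    opto_cfg = cfg.get("opto", {})
    opto = OptoSpec(
        targets=tuple(opto_cfg.get("targets", ("I",))),
        I0=float(opto_cfg.get("I0", 8.0)),
        Gamma0=float(opto_cfg.get("Gamma0", 0.5)),
    )

    diags = [d for d in validate_spec(spec) if d.level == "error"]
    if diags:
        raise ValueError(
            "invalid circuit config:\n" + "\n".join(f"  {d.field}: {d.message}" for d in diags)
        )
    return spec, sizes, opto


def dump_architecture(spec: CircuitSpec, sizes: SizeSpec, opto: OptoSpec) -> dict:
    """Serialize an architecture to a config mapping (round-trips with load)."""
    names = spec.names
    tau = {
        post: {pre: (None if np.isnan(spec.tau[i, j]) else float(spec.tau[i, j]))
               for j, pre in enumerate(names)}
        for i, post in enumerate(names)
    }
    return {
        "name": spec.name,
        "topology": spec.topology,
        "populations": list(names),
        "polarity": {p.name: p.polarity for p in spec.populations},
        "r0": spec.r0,
        "J": {post: {pre: float(spec.J[i, j]) for j, pre in enumerate(names)}
              for i, post in enumerate(names)},
        "J0": {nm: float(spec.J0[i]) for i, nm in enumerate(names)},
        "tau": tau,
        "neuron": {
            "C_M": spec.neuron[0].C_M,
            "g_leak": {nm: spec.neuron[i].g_leak for i, nm in enumerate(names)},
            "V_th": spec.neuron[0].V_th,
            "V_R": spec.neuron[0].V_R,
        },
        "sizes": {"N": sizes.N,
                  "fractions": {nm: sizes.fractions[i] for i, nm in enumerate(names)},
                  "K": sizes.K},
        "opto": {"targets": list(opto.targets), "I0": opto.I0, "Gamma0": opto.Gamma0},
    }


# ---------------------------------------------------------------------------
# operations

def opto_current(Gamma: float | np.ndarray, opto: OptoSpec) -> float | np.ndarray:
    """Photocurrent I_opto = I0 * ln(1 + Gamma/Gamma0), in nA/cm^2.

    ``Gamma`` is the laser intensity in mW/mm^2; must be nonnegative.
    """
    G = np.asarray(Gamma, dtype=float)
    if np.any(G < 0):
        raise ValueError("laser intensity Gamma must be nonnegative")
    out = opto.I0 * np.log1p(G / opto.Gamma0)
    return float(out) if np.isscalar(Gamma) or out.ndim == 0 else out


def opto_drive(spec: CircuitSpec, opto: OptoSpec, Gamma: float) -> np.ndarray:
    """Per-population photocurrent vector (nA/cm^2); zero off-target."""
    I = np.zeros(spec.n_pop)
    for t in opto.targets:
        I[spec.index(t)] = opto_current(Gamma, opto)
    return I


def scale_to_finite_K(spec: CircuitSpec, K: int) -> FiniteCouplings:
    """Finite-size couplings under the strong-coupling 1/sqrt(K) scaling.

    j = J/sqrt(K); the feedforward drive is the deterministic constant
    current lam_ext = 2 K j0 r0 (r0 converted to ms^-1, so lam_ext is in
    uA/cm^2).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    sk = math.sqrt(K)
    j = spec.J / sk
    j0 = spec.J0 / sk
    lam_ext = 2.0 * K * j0 * (spec.r0 * 1e-3)
    return FiniteCouplings(K=K, j=j, j0=j0, lam_ext=lam_ext)


def effective_matrix(spec: CircuitSpec) -> np.ndarray:
    """Signed interaction matrix A with A[a, b] = polarity(b) * J[a, b]."""
    return spec.J * spec.polarities[np.newaxis, :]


def validate_spec(spec: CircuitSpec) -> list[Diagnostic]:
    """Diagnostics report: strength signs, tau/J consistency, structural zeros.

    Returns an empty list for all shipped fixtures.  Violations are reported
    field by field; architecturally absent connections that some anatomical
    studies do report (e.g. a PV->SOM connection in the V1-like circuit) are
    warnings rather than errors.
    """
    diags: list[Diagnostic] = []
    names = spec.names
    n = spec.n_pop

    n_exc = sum(1 for p in spec.populations if p.polarity == 1)
    if n_exc != 1:
        diags.append(Diagnostic("warning", "populations",
                                f"{n_exc} excitatory populations (reference circuits have 1)"))

    for i in range(n):
        for j_ in range(n):
            fld = f"J[{names[i]},{names[j_]}]"
            if spec.J[i, j_] < 0:
                diags.append(Diagnostic("error", fld, "negative strength"))
            has_tau = not np.isnan(spec.tau[i, j_])
            if spec.J[i, j_] > 0 and not has_tau:
                diags.append(Diagnostic("error", f"tau[{names[i]},{names[j_]}]",
                                        "missing time constant for nonzero J"))
            if spec.J[i, j_] == 0 and has_tau:
                diags.append(Diagnostic("error", f"tau[{names[i]},{names[j_]}]",
                                        "time constant given for zero J"))
            if not np.isnan(spec.tau[i, j_]) and spec.tau[i, j_] <= 0:
                diags.append(Diagnostic("error", f"tau[{names[i]},{names[j_]}]",
                                        "nonpositive time constant"))
    if np.any(spec.J0 < 0):
        diags.append(Diagnostic("error", "J0", "negative feedforward strength"))
    if spec.r0 < 0:
        diags.append(Diagnostic("error", "r0", "negative external rate"))

    tolerated = _TOLERATED_EXTRAS.get(spec.topology, ())
    for post, pre in _STRUCTURAL_ZEROS.get(spec.topology, ()):
        if post not in names or (pre not in names and pre != "0"):
            continue
        i = names.index(post)
        val = spec.J0[i] if pre == "0" else spec.J[i, names.index(pre)]
        if val != 0:
            level = "warning" if (post, pre) in tolerated else "error"
            fld = f"J[{post},{pre}]" if pre != "0" else f"J0[{post}]"
            diags.append(Diagnostic(level, fld,
                                    f"structural zero of the {spec.topology} architecture violated"))
    return diags
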