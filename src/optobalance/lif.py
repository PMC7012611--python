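"""Finite-size spiking simulation of the balanced circuits.

Networks of leaky integrate-and-fire neurons with sparse Erdos-Renyi
connectivity (connection probability K/N_b per ordered pair, no
self-connections), exponential synapses, a constant feedforward drive
``2 K j_a0 r0`` and a constant optogenetic drive ``sqrt(K) I_opto`` into the
targeted population.  Voltage dynamics between spikes:

    C_M dV/dt = -g_leak (V - V_R) + I_rec + lam_ext + lam_opto

integrated with a second-order Runge-Kutta scheme without spike-time
interpolation (exact exponential update for the synaptic traces).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _kernels
from .circuits import (
    CircuitSpec, OptoSpec, SizeSpec, opto_current, scale_to_finite_K,
)

__all__ = [
    "ConnectivityRealization",
    "SimConfig",
    "SpikeData",
    "ActivitySummary",
    "SimSweepResult",
    "build_connectivity",
    "simulate",
    "summarize_activity",
    "intensity_sweep_sim",
]


@dataclass
class SimConfig:
    """Integration settings.  Times in ms."""

    dt: float = 0.01
    duration: float = 100_000.0   # analysed span, excluding warmup
    warmup: float = 1_000.0       # discarded transient
    seed: int = 0
    max_rate_cap: float = 400.0   # Hz; sizes the spike-recording buffer

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class ConnectivityRealization:
    """Sparse directed adjacency (postsynaptic x presynaptic) with its seed."""

    adjacency: sp.csc_matrix   # shape (N, N); CSC gives outgoing lists per presyn
    pop_of: np.ndarray         # int32[N]
    counts: np.ndarray         # neurons per population
    K: int
    seed: int

    @property
    def N(self) -> int:
        return self.adjacency.shape[0]

    def in_degrees(self, post: int, pre: int) -> np.ndarray:
        """Realized in-degrees of population ``post`` from population ``pre``."""
        offs = np.concatenate([[0], np.cumsum(self.counts)])
        block = self.adjacency[offs[post]:offs[post + 1], offs[pre]:offs[pre + 1]]
        return np.asarray(block.sum(axis=1)).ravel()


@dataclass
class SpikeData:
    """Spike events of one run (times in ms, relative to the end of warmup)."""

    ids: np.ndarray            # int32, neuron ids
    times: np.ndarray          # float64, sorted within neuron
    pop_of: np.ndarray         # int32[N]
    names: tuple[str, ...]
    duration: float            # analysed span (ms)
    config: SimConfig

    @property
    def N(self) -> int:
        return len(self.pop_of)

    def counts_per_neuron(self) -> np.ndarray:
        return np.bincount(self.ids, minlength=self.N)

    def rates_per_neuron(self) -> np.ndarray:
        """Single-neuron rates in Hz."""
        return self.counts_per_neuron() / self.duration * 1e3

    def population_rates(self) -> np.ndarray:
        """Population-averaged rates in Hz."""
        r = self.rates_per_neuron()
        return np.array([r[self.pop_of == p].mean() for p in range(len(self.names))])

    def spike_times_of(self, neuron: int) -> np.ndarray:
        return np.sort(self.times[self.ids == neuron])


@dataclass
class ActivitySummary:
    pop_rates: np.ndarray        # Hz
    single_rates: np.ndarray     # Hz per neuron
    isi_cv: np.ndarray           # population-mean ISI CV (NaN if too few ISIs)
    rate_hist: dict              # per population: (counts, bin edges)
    names: tuple[str, ...]


def _sample_in_edges(rng: np.random.Generator, n_pre: int, p: float,
                     exclude: int | None) -> np.ndarray:
    """Distinct presynaptic partners: Binomial(n_pre, p) in-degree, then a
    uniform distinct subset (equivalent to independent Bernoulli wiring)."""
    m = n_pre - (1 if exclude is not None else 0)
    d = rng.binomial(m, p)
    if d == 0:
        return np.empty(0, dtype=np.int64)
    if d > m:
        d = m
    # rejection sampling of a distinct subset; cheap for d << m, exact always
    if d > m // 2:
        pick = rng.permutation(m)[:d]
    else:
        pick = np.unique(rng.integers(0, m, size=int(d * 1.5) + 8))
        while len(pick) < d:
            pick = np.unique(np.concatenate(
                [pick, rng.integers(0, m, size=int(d * 1.5) + 8)]))
        pick = rng.permutation(pick)[:d]
    if exclude is not None:
        pick = np.where(pick >= exclude, pick + 1, pick)
    return pick


def build_connectivity(
    spec: CircuitSpec, sizes: SizeSpec, seed: int = 0
) -> ConnectivityRealization:
    """Draw the random adjacency: each ordered pair (post i in a, pre j in b)
    is connected independently with probability K/N_b, self-connections
    excluded, for every block with a nonzero interaction."""
    counts = sizes.counts
    if np.any(sizes.K > counts[np.any(spec.J > 0, axis=0)]):
        raise ValueError("K exceeds the size of a presynaptic population")
    offs = np.concatenate([[0], np.cumsum(counts)])
    N = int(offs[-1])
    pop_of = np.empty(N, dtype=np.int32)
    for p, (lo, hi) in enumerate(zip(offs[:-1], offs[1:])):
        pop_of[lo:hi] = p

    rng = np.random.default_rng(seed)
    rows, cols = [], []
    for a in range(spec.n_pop):
        for b in range(spec.n_pop):
            if spec.J[a, b] == 0:
                continue
            p_conn = sizes.K / counts[b]
            for i in range(counts[a]):
                exclude = i if a == b else None
                pre = _sample_in_edges(rng, counts[b], p_conn, exclude)
                rows.append(np.full(len(pre), offs[a] + i, dtype=np.int64))
                cols.append(pre + offs[b])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    adj = sp.csc_matrix(
        (np.ones(len(r), dtype=np.int8), (r, c)), shape=(N, N)
    )
    return ConnectivityRealization(adjacency=adj, pop_of=pop_of, counts=counts,
                                   K=sizes.K, seed=seed)


def simulate(
    spec: CircuitSpec,
    sizes: SizeSpec,
    opto: OptoSpec | None = None,
    Gamma: float = 0.0,
    config: SimConfig | None = None,
    conn: ConnectivityRealization | None = None,
) -> SpikeData:
    """Integrate the network and return its spikes (post-warmup).

    The optogenetic drive for laser intensity ``Gamma`` is the constant
    current ``sqrt(K) * I0 * ln(1 + Gamma/Gamma0)`` into the target
    populations.  Initial voltages are uniform on [V_R, V_th); synaptic
    traces start at zero.  Raises ``RuntimeError`` on numeric blow-up
    (|V| > 1000 mV) or spike-buffer overflow.
    """
    config = config or SimConfig()
    opto = opto or OptoSpec()
    if conn is None:
        conn = build_connectivity(spec, sizes, seed=config.seed)
    N = conn.N
    n_pop = spec.n_pop

    fin = scale_to_finite_K(spec, sizes.K)
    eps = spec.polarities
    w = fin.j * eps[np.newaxis, :]
    with np.errstate(divide="ignore"):
        jump = np.where(np.isnan(spec.tau), 0.0, 1.0 / spec.tau)
        decay = np.where(np.isnan(spec.tau), 1.0, np.exp(-config.dt / spec.tau))

    lam = fin.lam_ext.copy()
    if Gamma > 0:
        I_nA = opto_current(Gamma, opto)
        for t in opto.targets:
            lam[spec.index(t)] += float(fin.lam_opto(I_nA))

    gl = np.array([nr.g_leak for nr in spec.neuron])
    V_th = spec.neuron[0].V_th
    V_R = spec.neuron[0].V_R
    C_M = spec.neuron[0].C_M

    rng = np.random.default_rng(config.seed + 1)
    V = rng.uniform(V_R, V_th, size=N)
    s = np.zeros((N, n_pop))

    n_steps = int(round((config.duration + config.warmup) / config.dt))
    warmup_steps = int(round(config.warmup / config.dt))
    cap = int(config.max_rate_cap * 1e-3 * config.duration * N) + 1000
    rec_ids = np.empty(cap, dtype=np.int32)
    rec_times = np.empty(cap, dtype=np.float64)

    csc = conn.adjacency
    n_rec, status = _kernels.run_network(
        conn.pop_of, csc.indptr.astype(np.int64), csc.indices.astype(np.int32),
        w, jump, decay, gl, lam, C_M, V_th, V_R,
        config.dt, n_steps, warmup_steps, V, s, rec_ids, rec_times,
    )
    if status == _kernels.STATUS_BLOWUP:
        raise RuntimeError(
            "numeric blow-up: |V| exceeded 1000 mV — check couplings and dt"
        )
    if status == _kernels.STATUS_OVERFLOW:
        raise RuntimeError(
            f"spike buffer overflow (mean rate above {config.max_rate_cap} Hz cap)"
        )
    return SpikeData(
        ids=rec_ids[:n_rec].copy(), times=rec_times[:n_rec].copy(),
        pop_of=conn.pop_of, names=spec.names,
        duration=config.duration, config=config,
    )


def summarize_activity(
    spikes: SpikeData,
    window: tuple[float, float] | None = None,
    min_isis: int = 10,
    hist_bins: int = 30,
) -> ActivitySummary:
    """Population rates, single-neuron rates, ISI CV and rate histograms.

    ``window`` restricts the analysis to [t0, t1] ms (post-warmup clock);
    the CV is averaged over neurons with at least ``min_isis`` intervals.
    """
    if window is None:
        t0, t1 = 0.0, spikes.duration
    else:
        t0, t1 = window
        if not (0 <= t0 < t1 <= spikes.duration):
            raise ValueError("window must be a nonempty span within the run")
    mask = (spikes.times >= t0) & (spikes.times <= t1)
    ids, times = spikes.ids[mask], spikes.times[mask]
    span = t1 - t0
    counts = np.bincount(ids, minlength=spikes.N)
    single = counts / span * 1e3

    order = np.lexsort((times, ids))
    ids_s, times_s = ids[order], times[order]
    cv = np.full(spikes.N, np.nan)
    starts = np.searchsorted(ids_s, np.arange(spikes.N))
    ends = np.searchsorted(ids_s, np.arange(spikes.N), side="right")
    for nrn in range(spikes.N):
        tt = times_s[starts[nrn]:ends[nrn]]
        if len(tt) >= min_isis + 1:
            isi = np.diff(tt)
            m = isi.mean()
            if m > 0:
                cv[nrn] = isi.std() / m

    n_pop = len(spikes.names)
    pop_rates = np.array([single[spikes.pop_of == p].mean() for p in range(n_pop)])
    isi_cv = np.array([
        np.nanmean(cv[spikes.pop_of == p]) if np.any(~np.isnan(cv[spikes.pop_of == p]))
        else np.nan
        for p in range(n_pop)
    ])
    rate_hist = {
        spikes.names[p]: np.histogram(single[spikes.pop_of == p], bins=hist_bins)
        for p in range(n_pop)
    }
    return ActivitySummary(pop_rates=pop_rates, single_rates=single, isi_cv=isi_cv,
                           rate_hist=rate_hist, names=spikes.names)


@dataclass
class SimSweepResult:
    """Population and single-neuron responses along a laser-intensity grid."""

    Gamma: np.ndarray
    pop_rates: np.ndarray        # (n_gamma, n_pop), Hz
    normalized: np.ndarray       # pop rate / baseline pop rate (NaN if baseline 0)
    single_rates: np.ndarray     # (n_gamma, N), Hz
    single_normalized: np.ndarray  # per-neuron normalized (NaN where baseline 0)
    names: tuple[str, ...]
    pop_of: np.ndarray
    spikes: list[SpikeData] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        cols = {"Gamma": self.Gamma}
        for p, nm in enumerate(self.names):
            cols[f"rate_{nm}"] = self.pop_rates[:, p]
            cols[f"norm_{nm}"] = self.normalized[:, p]
        return pd.DataFrame(cols)


def intensity_sweep_sim(
    spec: CircuitSpec,
    sizes: SizeSpec,
    opto: OptoSpec,
    Gammas,
    config: SimConfig | None = None,
    keep_spikes: bool = False,
) -> SimSweepResult:
    """One simulation per laser intensity on a shared connectivity realization.

    The grid must include Gamma = 0; population and per-neuron rates are
    normalized to that baseline run (undefined where the baseline rate is
    zero, reported as NaN).
    """
    Gammas = np.asarray(Gammas, dtype=float)
    if not np.any(Gammas == 0):
        raise ValueError("the intensity grid must include the baseline Gamma = 0")
    config = config or SimConfig()
    conn = build_connectivity(spec, sizes, seed=config.seed)

    single = np.zeros((len(Gammas), conn.N))
    runs: list[SpikeData] = []
    for k, G in enumerate(Gammas):
        sd = simulate(spec, sizes, opto, Gamma=float(G), config=config, conn=conn)
        single[k] = sd.rates_per_neuron()
        if keep_spikes:
            runs.append(sd)

    n_pop = spec.n_pop
    pop_rates = np.stack([
        [single[k][conn.pop_of == p].mean() for p in range(n_pop)]
        for k in range(len(Gammas))
    ])
    base_idx = int(np.flatnonzero(Gammas == 0)[0])
    base_pop = pop_rates[base_idx]
    base_single = single[base_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(base_pop > 0, pop_rates / base_pop, np.nan)
        single_norm = np.where(base_single > 0, single / base_single, np.nan)
    return SimSweepResult(
        Gamma=Gammas, pop_rates=pop_rates, normalized=normalized,
        single_rates=single, single_normalized=single_norm,
        names=spec.names, pop_of=conn.pop_of, spikes=runs,
    )
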