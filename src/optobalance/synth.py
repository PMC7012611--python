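"""Synthetic trial-structured recordings with known ground truth.

The generator emulates the statistical structure of silicon-probe
recordings during full-field photostimulation of PV interneurons: a few
tens of units per cell class, lognormal baseline rates, a grid of laser
intensities with ~20 trials each, 1.3 s stimulation epochs delivered at
~7 s intervals, and heterogeneous per-unit responses (a shared population
template scaled by a normally distributed unit gain, optionally with a
fraction of sign-flipped "incongruous" units).  Spiking within each
analysis window is homogeneous Poisson — the downstream analysis only uses
window counts, so finer ISI structure is irrelevant.

``from_simulation`` adapts network-simulation sweeps into the same
recording format so the full analysis pipeline can be run end to end on
simulated circuits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .analysis import Recording, _ols_slope
from .lif import SimSweepResult

__all__ = [
    "ClassConfig",
    "SyntheticConfig",
    "GroundTruth",
    "S1_INTENSITIES",
    "ALM_INTENSITIES",
    "linear_template",
    "generate_recording",
    "ground_truth",
    "from_simulation",
]

S1_INTENSITIES = (0.5, 1.2, 2.2, 5.0, 12.0)                       # mW/mm^2
ALM_INTENSITIES = (0.3, 0.5, 1.0, 1.5, 2.0, 3.3, 5.0, 8.0, 15.0)  # mW/mm^2

FS_WIDTH_BAND = (0.15, 0.33)   # ms, inside the fast-spiking band
PC_WIDTH_BAND = (0.47, 0.80)   # ms, inside the putative-pyramidal band


def linear_template(slope: float, intensities: Sequence[float]) -> np.ndarray:
    """Normalized-rate template 1 + slope * Gamma on the given grid."""
    return 1.0 + slope * np.asarray(intensities, dtype=float)


@dataclass
class ClassConfig:
    """Per-cell-class generator settings.

    ``template`` is the population normalized-rate curve on the intensity
    grid; each unit's curve is 1 + gain * (template - 1) with
    gain ~ Normal(1, gain_sigma), sign-flipped with probability
    ``incongruous_fraction``.  Baseline rates are lognormal (median,
    sigma of log); spike widths uniform within the class band.
    """

    n_units: int
    template: np.ndarray
    baseline_median: float = 5.0
    baseline_sigma_log: float = 1.0
    gain_sigma: float = 0.3
    incongruous_fraction: float = 0.0
    width_band: tuple[float, float] = PC_WIDTH_BAND


@dataclass
class SyntheticConfig:
    """Recording-level generator settings (durations in ms)."""

    intensities: tuple[float, ...] = S1_INTENSITIES
    pc: ClassConfig | None = None
    fs: ClassConfig | None = None
    trials_per_intensity: int = 20
    stim_duration: float = 1300.0
    analysis_window: float = 1000.0
    baseline_window: float = 500.0
    inter_trial_interval: float = 7000.0

    def __post_init__(self) -> None:
        # default unit counts follow the S1 dataset: 52 putative PCs, 8 FS
        flat = np.ones(len(self.intensities))
        if self.pc is None:
            self.pc = ClassConfig(n_units=52, template=flat.copy(),
                                  width_band=PC_WIDTH_BAND)
        if self.fs is None:
            self.fs = ClassConfig(n_units=8, template=flat.copy(),
                                  width_band=FS_WIDTH_BAND)
        for cls in (self.pc, self.fs):
            if len(np.asarray(cls.template)) != len(self.intensities):
                raise ValueError("template length must match the intensity grid")
        if self.trials_per_intensity < 1:
            raise ValueError("need at least one trial per intensity")


@dataclass
class GroundTruth:
    """Programmed quantities implied by a generator draw.

    ``population_normalized`` uses the realized per-unit baselines and
    gains with the same average-then-normalize convention as the analysis;
    slopes are ordinary-least-squares over the grid points at or below
    ``slope_max_intensity`` with the (0, 1) reference included.
    """

    intensities: np.ndarray
    population_normalized: dict[str, np.ndarray]
    population_slope: dict[str, float]
    slope_ratio: float
    expected_fractions: pd.DataFrame
    slope_max_intensity: float
    unit_rates: dict[str, np.ndarray]       # (n_units, n_intensities) true stim rates
    unit_baselines: dict[str, np.ndarray]


def _truth_from_rates(
    intensities: np.ndarray,
    rates: dict[str, np.ndarray],
    baselines: dict[str, np.ndarray],
    slope_max_intensity: float,
    threshold: float = 0.1,
) -> GroundTruth:
    pop_norm, slopes = {}, {}
    x_full = np.concatenate([[0.0], intensities])
    sel = x_full <= slope_max_intensity
    frac_rows = []
    for cls in rates:
        curve = rates[cls].mean(axis=0) / baselines[cls].mean()
        pop_norm[cls] = curve
        y_full = np.concatenate([[1.0], curve])
        slopes[cls] = _ols_slope(x_full[sel], y_full[sel])
        for gi, g in enumerate(intensities):
            r = rates[cls][:, gi]
            d = r - baselines[cls]
            silenced = r < threshold
            inc = ~silenced & (d > threshold)
            dec = ~silenced & (d < -threshold)
            frac_rows.append((cls, g, inc.mean(), dec.mean(),
                              (~silenced & ~inc & ~dec).mean(), silenced.mean()))
    ratio = (slopes.get("FS", np.nan) / slopes["PC"]
             if slopes.get("PC") not in (0.0, None) else float("nan"))
    fracs = pd.DataFrame(frac_rows, columns=["cell_class", "intensity", "increase",
                                             "decrease", "no_change", "silenced"])
    return GroundTruth(
        intensities=intensities, population_normalized=pop_norm,
        population_slope=slopes, slope_ratio=float(ratio),
        expected_fractions=fracs, slope_max_intensity=slope_max_intensity,
        unit_rates=rates, unit_baselines=baselines,
    )


def generate_recording(
    config: SyntheticConfig,
    seed: int = 0,
    slope_max_intensity: float | None = None,
) -> tuple[Recording, GroundTruth]:
    """Draw a synthetic recording and its realized ground truth.

    Deterministic given the seed.  Per trial, spikes are homogeneous
    Poisson: at the unit's baseline rate in the pre-stimulus window and at
    its modulated rate (clipped at zero — the sampler is never asked for a
    negative intensity) during the stimulation epoch.
    """
    rng = np.random.default_rng(seed)
    gammas = np.asarray(config.intensities, dtype=float)
    if slope_max_intensity is None:
        slope_max_intensity = float(gammas.max())

    # trial table
    n_tr = config.trials_per_intensity
    trial_int = np.repeat(gammas, n_tr)
    rng.shuffle(trial_int)  # intensities delivered in random order
    trials = pd.DataFrame({"trial_id": np.arange(len(trial_int)), "intensity": trial_int})

    units_rows = []
    spikes_frames = []
    rates: dict[str, np.ndarray] = {}
    baselines: dict[str, np.ndarray] = {}
    uid = 0
    for cls_name, cls in (("PC", config.pc), ("FS", config.fs)):
        tmpl = np.asarray(cls.template, dtype=float)
        b = rng.lognormal(np.log(cls.baseline_median), cls.baseline_sigma_log,
                          size=cls.n_units)
        g = rng.normal(1.0, cls.gain_sigma, size=cls.n_units)
        flip = rng.random(cls.n_units) < cls.incongruous_fraction
        g = np.where(flip, -g, g)
        w = rng.uniform(*cls.width_band, size=cls.n_units)
        r = np.clip(b[:, None] * (1.0 + g[:, None] * (tmpl[None, :] - 1.0)), 0.0, None)
        rates[cls_name] = r
        baselines[cls_name] = b

        gi_map = {g: i for i, g in enumerate(gammas)}
        gi_of_trial = np.array([gi_map[g] for g in trials["intensity"]])
        for u in range(cls.n_units):
            units_rows.append((uid, w[u], cls_name))
            for t_id, gi in zip(trials["trial_id"].to_numpy(), gi_of_trial):
                tt = _poisson_times(rng, b[u], -config.baseline_window, 0.0)
                ts = _poisson_times(rng, r[u, gi], 0.0, config.stim_duration)
                times = np.concatenate([tt, ts])
                if len(times):
                    spikes_frames.append((
                        np.full(len(times), uid), np.full(len(times), t_id), times))
            uid += 1

    units = pd.DataFrame(units_rows, columns=["unit_id", "width_ms", "true_class"])
    if spikes_frames:
        spikes = pd.DataFrame({
            "unit_id": np.concatenate([f[0] for f in spikes_frames]),
            "trial_id": np.concatenate([f[1] for f in spikes_frames]),
            "time_ms": np.concatenate([f[2] for f in spikes_frames]),
        })
    else:
        spikes = pd.DataFrame(columns=["unit_id", "trial_id", "time_ms"])
    rec = Recording(units=units, trials=trials, spikes=spikes)
    truth = _truth_from_rates(gammas, rates, baselines, slope_max_intensity)
    return rec, truth


def _poisson_times(rng: np.random.Generator, rate_hz: float,
                   t0: float, t1: float) -> np.ndarray:
    if rate_hz < 0:
        raise ValueError("negative rate requested from the Poisson sampler")
    n = rng.poisson(rate_hz * (t1 - t0) / 1e3)
    return np.sort(rng.uniform(t0, t1, size=n))


def ground_truth(config: SyntheticConfig,
                 slope_max_intensity: float | None = None) -> GroundTruth:
    """Expectation-level ground truth implied by the templates alone.

    Uses the population means of the gain distribution (mean 1, or 1 - 2p
    with incongruous fraction p) and ignores rate clipping, so it is exact
    whenever the programmed curves stay positive for typical gains.
    """
    gammas = np.asarray(config.intensities, dtype=float)
    if slope_max_intensity is None:
        slope_max_intensity = float(gammas.max())
    rates, baselines = {}, {}
    for cls_name, cls in (("PC", config.pc), ("FS", config.fs)):
        tmpl = np.asarray(cls.template, dtype=float)
        mean_gain = 1.0 - 2.0 * cls.incongruous_fraction
        b = np.full(cls.n_units, cls.baseline_median *
                    np.exp(cls.baseline_sigma_log ** 2 / 2.0))
        rates[cls_name] = b[:, None] * (1.0 + mean_gain * (tmpl[None, :] - 1.0))
        baselines[cls_name] = b
    return _truth_from_rates(gammas, rates, baselines, slope_max_intensity)


def from_simulation(
    sweep: SimSweepResult,
    trials_per_intensity: int = 20,
    units_per_class: int | None = None,
    stim_duration: float = 1300.0,
    baseline_window: float = 500.0,
    seed: int = 0,
    class_of_population: dict[str, str] | None = None,
) -> Recording:
    """Slice a simulated intensity sweep into a pseudo-trial recording.

    The run at each laser intensity is cut into ``trials_per_intensity``
    stimulation epochs; the matching pre-stimulus baseline segments come
    from the baseline (Gamma = 0) run, mirroring the experimental design in
    which every trial's pre-stimulus window is unstimulated.  Simulated
    populations map onto recorded cell classes (E -> PC, I -> FS by
    default; other populations are not probed) and units receive synthetic
    spike widths drawn inside their class band.  Requires the sweep to have
    been run with ``keep_spikes=True``.
    """
    if not sweep.spikes:
        raise ValueError("sweep carries no spike data; rerun with keep_spikes=True")
    class_of_population = class_of_population or {"E": "PC", "I": "FS"}
    gammas = sweep.Gamma
    base_idx = int(np.flatnonzero(gammas == 0)[0])
    base_run = sweep.spikes[base_idx]

    span = stim_duration + baseline_window
    n_fit = int(base_run.duration // span)
    n_tr = min(trials_per_intensity, n_fit)
    if n_tr < 1:
        raise ValueError("simulated runs are too short for a single pseudo-trial")

    rng = np.random.default_rng(seed)
    probed: list[tuple[int, int, str]] = []   # (neuron, unit_id, class)
    uid = 0
    units_rows = []
    for p, name in enumerate(sweep.names):
        cls = class_of_population.get(name)
        if cls is None:
            continue
        nrns = np.flatnonzero(sweep.pop_of == p)
        if units_per_class is not None and len(nrns) > units_per_class:
            nrns = rng.choice(nrns, size=units_per_class, replace=False)
        band = FS_WIDTH_BAND if cls == "FS" else PC_WIDTH_BAND
        for nrn in nrns:
            probed.append((int(nrn), uid, cls))
            units_rows.append((uid, float(rng.uniform(*band)), cls))
            uid += 1

    def times_by_neuron(run) -> dict[int, np.ndarray]:
        order = np.lexsort((run.times, run.ids))
        ids_s, times_s = run.ids[order], run.times[order]
        wanted = {nrn for nrn, _, _ in probed}
        lo = np.searchsorted(ids_s, sorted(wanted))
        hi = np.searchsorted(ids_s, sorted(wanted), side="right")
        return {nrn: times_s[a:b] for nrn, a, b in zip(sorted(wanted), lo, hi)}

    base_times = times_by_neuron(base_run)
    trial_rows = []
    spike_frames = []
    trial_id = 0
    nonzero = [k for k in range(len(gammas)) if k != base_idx] or [base_idx]
    for k in nonzero:
        run_times = times_by_neuron(sweep.spikes[k])
        for t in range(n_tr):
            t_on = t * span + baseline_window      # stimulus onset within the run
            trial_rows.append((trial_id, float(gammas[k])))
            for nrn, uid_, _cls in probed:
                tb = base_times[nrn]
                tb = tb[np.searchsorted(tb, t_on - baseline_window):
                        np.searchsorted(tb, t_on)] - t_on
                ts = run_times[nrn]
                ts = ts[np.searchsorted(ts, t_on):
                        np.searchsorted(ts, t_on + stim_duration)] - t_on
                times = np.concatenate([tb, ts])
                if len(times):
                    spike_frames.append((
                        np.full(len(times), uid_), np.full(len(times), trial_id), times))
            trial_id += 1

    units = pd.DataFrame(units_rows, columns=["unit_id", "width_ms", "true_class"])
    trials = pd.DataFrame(trial_rows, columns=["trial_id", "intensity"])
    if spike_frames:
        spikes = pd.DataFrame({
            "unit_id": np.concatenate([f[0] for f in spike_frames]),
            "trial_id": np.concatenate([f[1] for f in spike_frames]),
            "time_ms": np.concatenate([f[2] for f in spike_frames]),
        })
    else:
        spikes = pd.DataFrame(columns=["unit_id", "trial_id", "time_ms"])
    return Recording(units=units, trials=trials, spikes=spikes)
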