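"""Electrophysiology-style analysis of trial-structured spike recordings.

A :class:`Recording` holds three tables: units (id, spike width, area),
trials (id, laser intensity) and spikes (unit, trial, time in ms aligned to
photostimulus onset).  Units are classified by trough-to-peak spike width
(fast-spiking, putatively PV+, below 0.35 ms; putative pyramidal above
0.45 ms; intermediate widths excluded).  Responses are quantified as
*normalized spike rates*: the rate in the 1 s stimulation window divided by
the 500 ms pre-stimulus baseline rate.  The population version averages
rates across neurons first and normalizes afterwards.  Uncertainty is
bootstrap over neurons (whole units resampled with replacement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ResponseTable",
    "STIM_WINDOW",
    "BASELINE_WINDOW",
    "classify_unit",
    "windowed_rates",
    "normalize_responses",
    "bootstrap_sem",
    "response_slope",
    "response_fractions",
]

STIM_WINDOW = (0.0, 1000.0)      # ms from stimulus onset
BASELINE_WINDOW = (-500.0, 0.0)  # ms from stimulus onset
FS_MAX_WIDTH = 0.35              # ms, strict
PC_MIN_WIDTH = 0.45              # ms, strict
RATE_CHANGE_THRESHOLD = 0.1      # Hz, response-category boundary


@dataclass
class Recording:
    """Trial-structured spike data.

    units:  columns unit_id, width_ms [, area]
    trials: columns trial_id, intensity (mW/mm^2)
    spikes: columns unit_id, trial_id, time_ms (aligned to stimulus onset)
    """

    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols in ((self.units, {"unit_id", "width_ms"}),
                         (self.trials, {"trial_id", "intensity"}),
                         (self.spikes, {"unit_id", "trial_id", "time_ms"})):
            missing = cols - set(df.columns)
            if missing:
                raise ValueError(f"recording table missing columns {sorted(missing)}")

    def save(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.units.to_csv(d / "units.csv", index=False)
        self.trials.to_csv(d / "trials.csv", index=False)
        self.spikes.to_csv(d / "spikes.csv", index=False)

    @classmethod
    def load(cls, directory) -> "Recording":
        from pathlib import Path
        d = Path(directory)
        return cls(units=pd.read_csv(d / "units.csv"),
                   trials=pd.read_csv(d / "trials.csv"),
                   spikes=pd.read_csv(d / "spikes.csv"))


def classify_unit(width_ms: float) -> str:
    """Spike-width classification: 'FS' (< 0.35 ms), 'PC' (> 0.45 ms), else
    'excluded' (boundary values excluded — strict inequalities)."""
    w = float(width_ms)
    if w <= 0:
        raise ValueError("spike width must be positive")
    if w < FS_MAX_WIDTH:
        return "FS"
    if w > PC_MIN_WIDTH:
        return "PC"
    return "excluded"


def windowed_rates(
    recording: Recording,
    stim_window: tuple[float, float] = STIM_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> pd.DataFrame:
    """Per-unit, per-intensity stimulation and baseline rates (Hz).

    The stimulation-window rate is count/duration averaged over the trials
    of that intensity.  The baseline rate is averaged over *all* trials (the
    pre-stimulus window is unaffected by the upcoming stimulus).  Columns:
    unit_id, cell_class, intensity, stim_rate, base_rate, n_trials.
    """
    if len(recording.trials) == 0:
        raise ValueError("recording has no trials")
    if stim_window[1] <= stim_window[0] or baseline_window[1] <= baseline_window[0]:
        raise ValueError("windows must be nonempty")

    spk = recording.spikes.merge(recording.trials, on="trial_id")
    stim_dur = (stim_window[1] - stim_window[0]) / 1e3
    base_dur = (baseline_window[1] - baseline_window[0]) / 1e3

    unit_ids = recording.units["unit_id"].to_numpy()
    classes = recording.units["width_ms"].map(classify_unit)
    intensities = np.sort(recording.trials["intensity"].unique())
    trials_per_int = recording.trials.groupby("intensity")["trial_id"].count()
    n_trials_total = len(recording.trials)

    in_stim = spk[(spk["time_ms"] >= stim_window[0]) & (spk["time_ms"] < stim_window[1])]
    in_base = spk[(spk["time_ms"] >= baseline_window[0]) & (spk["time_ms"] < baseline_window[1])]

    stim_counts = in_stim.groupby(["unit_id", "intensity"]).size()
    base_counts = in_base.groupby("unit_id").size()

    rows = []
    for uid, cls in zip(unit_ids, classes):
        base_rate = base_counts.get(uid, 0) / (n_trials_total * base_dur)
        for g in intensities:
            n_tr = int(trials_per_int[g])
            stim = stim_counts.get((uid, g), 0) / (n_tr * stim_dur)
            rows.append((uid, cls, g, stim, base_rate, n_tr))
    return pd.DataFrame(
        rows, columns=["unit_id", "cell_class", "intensity",
                       "stim_rate", "base_rate", "n_trials"]
    )


@dataclass
class ResponseTable:
    """Normalized responses at unit and population level.

    ``per_unit``:   unit_id, cell_class, intensity, stim_rate, base_rate,
                    norm_rate (NaN for zero-baseline units).
    ``population``: cell_class, intensity, mean_stim, mean_base, norm_rate
                    (average across units first, then normalize).
    Both include the intensity-0 reference row at normalized value 1.
    """

    per_unit: pd.DataFrame
    population: pd.DataFrame
    zero_baseline_units: tuple = ()


def normalize_responses(rates: Recording | pd.DataFrame,
                        mode: str = "both") -> ResponseTable:
    """Build the response table from a recording (or a windowed-rates frame).

    Per-unit normalized rate is stim/baseline for that unit; units with zero
    baseline are flagged and excluded from per-unit statistics but still
    contribute to the population average.  The population normalized rate is
    mean(stim rates) / mean(baseline rates) — average first, then normalize.
    A reference row at intensity 0 (normalized rate exactly 1, stimulation
    rate equal to baseline by definition) anchors every response curve.
    """
    if isinstance(rates, Recording):
        rates = windowed_rates(rates)
    if mode not in ("per-unit", "population", "both"):
        raise ValueError("mode must be 'per-unit', 'population' or 'both'")
    df = rates[rates["cell_class"] != "excluded"].copy()

    zero_base = tuple(df.loc[df["base_rate"] <= 0, "unit_id"].unique())
    with np.errstate(divide="ignore", invalid="ignore"):
        df["norm_rate"] = np.where(df["base_rate"] > 0,
                                   df["stim_rate"] / df["base_rate"], np.nan)

    # intensity-0 reference rows
    ref = df.drop_duplicates("unit_id")[["unit_id", "cell_class", "base_rate"]].copy()
    ref["intensity"] = 0.0
    ref["stim_rate"] = ref["base_rate"]
    ref["norm_rate"] = np.where(ref["base_rate"] > 0, 1.0, np.nan)
    ref["n_trials"] = 0
    if not np.any(df["intensity"] == 0):
        per_unit = pd.concat([ref, df], ignore_index=True)
    else:
        per_unit = df
    per_unit = per_unit.sort_values(["cell_class", "unit_id", "intensity"],
                                    ignore_index=True)

    grp = per_unit.groupby(["cell_class", "intensity"], as_index=False).agg(
        mean_stim=("stim_rate", "mean"), mean_base=("base_rate", "mean"))
    with np.errstate(divide="ignore", invalid="ignore"):
        grp["norm_rate"] = np.where(grp["mean_base"] > 0,
                                    grp["mean_stim"] / grp["mean_base"], np.nan)
    if len(grp) and not (grp["mean_base"] > 0).any():
        raise ValueError("population normalization requires a unit with baseline > 0")
    return ResponseTable(per_unit=per_unit, population=grp,
                         zero_baseline_units=zero_base)


def bootstrap_sem(
    values: np.ndarray,
    reps: int = 10_000,
    seed: int = 0,
    statistic: Callable[[np.ndarray], float | np.ndarray] | None = None,
    ci: float = 0.95,
) -> dict:
    """Bootstrap over neurons: resample rows with replacement, recompute the
    mean (or ``statistic``), SEM = std of the resampled estimates.

    ``values`` is (n_units,) or (n_units, n_columns); whole rows move
    together, so per-intensity values of one neuron stay paired.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if reps < 100:
        raise ValueError("use at least 100 bootstrap repetitions")
    n = values.shape[0]
    stat = statistic or (lambda v: v.mean(axis=0))
    rng = np.random.default_rng(seed)
    draws = np.asarray([
        stat(values[rng.integers(0, n, size=n)]) for _ in range(reps)
    ])
    alpha = (1.0 - ci) / 2.0
    return {
        "sem": draws.std(axis=0, ddof=0),
        "ci": (np.quantile(draws, alpha, axis=0), np.quantile(draws, 1 - alpha, axis=0)),
        "mean": stat(values),
    }


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    denom = ((x - xm) ** 2).sum()
    if denom == 0:
        return float("nan")
    return float(((x - xm) * (y - ym)).sum() / denom)


def response_slope(
    table: ResponseTable,
    max_intensity: float,
    reps: int = 10_000,
    seed: int = 0,
) -> dict:
    """Initial slope of the normalized rate vs laser intensity, per class.

    Ordinary least squares over the intensities at or below
    ``max_intensity`` (the intensity-0 reference point, normalized value 1,
    included).  The FS/PC ("PV/PC") slope ratio is bootstrapped by
    resampling the FS and PC populations independently; its SEM is the std
    of the resampled-ratio distribution.  A zero PC slope makes the ratio
    undefined (NaN, reported).
    """
    pop = table.population
    pu = table.per_unit
    out: dict = {"population_slope": {}, "population_slope_sem": {},
                 "unit_slopes": {}, "max_intensity": max_intensity}

    sel_int = np.sort(pop["intensity"].unique())
    sel_int = sel_int[sel_int <= max_intensity]
    if len(sel_int) < 2:
        raise ValueError("need at least two intensity points at or below max_intensity")

    rng = np.random.default_rng(seed)
    boot_slopes: dict[str, np.ndarray] = {}
    for cls, sub in pu.groupby("cell_class"):
        piv_stim = sub.pivot_table(index="unit_id", columns="intensity",
                                   values="stim_rate")
        piv_stim = piv_stim[[c for c in piv_stim.columns if c <= max_intensity]]
        base = sub.drop_duplicates("unit_id").set_index("unit_id")["base_rate"]
        base = base.loc[piv_stim.index]
        x = piv_stim.columns.to_numpy(dtype=float)

        def pop_slope(stim_mat: np.ndarray, base_vec: np.ndarray) -> float:
            mb = base_vec.mean()
            if mb <= 0:
                return float("nan")
            return _ols_slope(x, stim_mat.mean(axis=0) / mb)

        S = piv_stim.to_numpy()
        b = base.to_numpy()
        out["population_slope"][cls] = pop_slope(S, b)
        n = len(b)
        bs = np.array([
            pop_slope(S[idx], b[idx])
            for idx in (rng.integers(0, n, size=n) for _ in range(reps))
        ])
        boot_slopes[cls] = bs
        out["population_slope_sem"][cls] = float(np.nanstd(bs))

        with np.errstate(divide="ignore", invalid="ignore"):
            norm = np.where(b[:, None] > 0, S / b[:, None], np.nan)
        out["unit_slopes"][cls] = pd.Series(
            [_ols_slope(x, row) if not np.any(np.isnan(row)) else np.nan
             for row in norm],
            index=piv_stim.index, name="slope")

    if "FS" in boot_slopes and "PC" in boot_slopes:
        s_pc = out["population_slope"]["PC"]
        if s_pc == 0 or np.isnan(s_pc):
            out["slope_ratio"] = float("nan")
            out["slope_ratio_sem"] = float("nan")
        else:
            out["slope_ratio"] = out["population_slope"]["FS"] / s_pc
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = boot_slopes["FS"] / boot_slopes["PC"]
            ratios = ratios[np.isfinite(ratios)]
            out["slope_ratio_sem"] = float(ratios.std()) if len(ratios) else float("nan")
    return out


def response_fractions(
    rates: pd.DataFrame,
    rate_threshold: float = RATE_CHANGE_THRESHOLD,
) -> pd.DataFrame:
    """Fractions of units per class and intensity in the four response
    categories: silenced (stimulation rate below threshold, takes
    precedence), increase / decrease (|change| above threshold), no-change.

    ``rates`` is the windowed-rates frame (or ResponseTable.per_unit).
    Fractions sum to 1 in every class x intensity cell.
    """
    df = rates[rates["cell_class"] != "excluded"]
    df = df[df["intensity"] > 0]
    delta = df["stim_rate"] - df["base_rate"]
    cat = np.where(df["stim_rate"] < rate_threshold, "silenced",
                   np.where(delta > rate_threshold, "increase",
                            np.where(delta < -rate_threshold, "decrease", "no_change")))
    out = (
        df.assign(category=cat)
        .groupby(["cell_class", "intensity"])["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["increase", "decrease", "no_change", "silenced"],
                 fill_value=0.0)
        .reset_index()
    )
    return out
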