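"""Ratiometric Fura-2 trace analysis and responder classification.

Traces are 340/380 nm excitation-ratio time series sampled every 2 s while
neurons receive a sequence of bath applications (low agonist dose, washout,
high dose, washout, then 30 mM KCl to mark the excitable population).  The
analysis chain is:

1. ratio = F340 / F380 per frame;
2. relative trace = ratio normalized to the mean of the five frames
   immediately preceding the first drug application;
3. amplitude fold per stimulus = maximum of the relative trace inside the
   application-plus-washout window;
4. a neuron responds to a stimulus when its amplitude fold reaches a cutoff
   defined as mean + 3 SD of the non-responsive peak distribution (1.15 for
   peaks with mean 1.00 and SD 0.05);
5. high-dose amplitudes are excluded when the trace has not recovered from
   the low dose (desensitization);
6. %responders per mouse = responders normalized to that mouse's KCl
   responders; the mouse, not the neuron, is the unit for group statistics.

Ratios can optionally be converted to absolute [Ca2+]i with the standard
Grynkiewicz relation given instrument calibration parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_CUTOFF",
    "StimApplication",
    "StimulusSchedule",
    "CalibrationParams",
    "compute_ratio",
    "normalize_baseline",
    "calibrate_ca",
    "amplitude_fold",
    "responder_threshold",
    "classify_responders",
    "flag_desensitized",
    "analyze_traces",
    "percent_responders",
    "group_compare",
    "load_traces",
    "load_schedule",
]

#: Responder cutoff on the amplitude fold: mean + 3 SD of non-responsive
#: peaks (1.00 + 3 x 0.05).
DEFAULT_CUTOFF = 1.15


@dataclass(frozen=True)
class StimApplication:
    """One bath application: [onset, offset] plus washout until washout_end."""

    label: str
    onset: float
    offset: float
    washout_end: float

    def __post_init__(self) -> None:
        if not (self.onset < self.offset <= self.washout_end):
            raise ValueError(f"{self.label}: onset < offset <= washout_end required")


@dataclass
class StimulusSchedule:
    """Ordered, non-overlapping applications; KCl must come last."""

    applications: list[StimApplication]

    def __post_init__(self) -> None:
        apps = self.applications
        if not apps:
            raise ValueError("empty schedule")
        for a, b in zip(apps, apps[1:]):
            if b.onset < a.washout_end:
                raise ValueError("overlapping applications")
        if "KCL" not in apps[-1].label.upper():
            raise ValueError("the final application must be KCl")

    @property
    def kcl(self) -> StimApplication:
        return self.applications[-1]

    @property
    def agonist_applications(self) -> list[StimApplication]:
        return self.applications[:-1]

    @classmethod
    def default(cls) -> "StimulusSchedule":
        """Low dose / wash / high dose / wash / KCl, 30 s applications, 2 s frames."""
        return cls(
            [
                StimApplication("AITC_low", 60.0, 90.0, 240.0),
                StimApplication("AITC_high", 240.0, 270.0, 420.0),
                StimApplication("KCl", 420.0, 450.0, 510.0),
            ]
        )


@dataclass(frozen=True)
class CalibrationParams:
    """Grynkiewicz calibration constants for Fura-2.

    Rmin/Rmax are the ratio at zero and saturating Ca2+; Kd is the dye
    dissociation constant (nM); beta is F380(Ca-free)/F380(Ca-bound).
    """

    rmin: float
    rmax: float
    kd: float = 224.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.rmin < self.rmax:
            raise ValueError("Rmin must be < Rmax")
        if self.kd <= 0 or self.beta <= 0:
            raise ValueError("Kd and beta must be positive")


def compute_ratio(f340: np.ndarray, f380: np.ndarray) -> np.ndarray:
    """Elementwise 340/380 excitation ratio."""
    f340 = np.asarray(f340, dtype=float)
    f380 = np.asarray(f380, dtype=float)
    if f340.shape != f380.shape:
        raise ValueError("channel length mismatch")
    bad = np.nonzero(f380 <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive F380 at sample index {bad[0]}")
    return f340 / f380


def normalize_baseline(
    ratio: np.ndarray, time: np.ndarray, stim_onset: float, n_baseline: int = 5
) -> np.ndarray:
    """Divide the trace by the mean of the 5 frames preceding stimulus onset.

    The mean of those five normalized frames is exactly 1.  Requires at
    least ``n_baseline`` pre-stimulus samples.
    """
    ratio = np.asarray(ratio, dtype=float)
    time = np.asarray(time, dtype=float)
    pre = np.nonzero(time < stim_onset)[0]
    if pre.size < n_baseline:
        raise ValueError(
            f"need >= {n_baseline} pre-stimulus samples, have {pre.size}"
        )
    baseline = ratio[pre[-n_baseline:]].mean()
    if baseline <= 0:
        raise ValueError("non-positive baseline")
    return ratio / baseline


def calibrate_ca(ratio_value: float, params: CalibrationParams) -> float:
    """[Ca2+]i in nM via Kd * beta * (R - Rmin) / (Rmax - R).

    Strictly increasing in R on [Rmin, Rmax); R >= Rmax means dye
    saturation and raises.
    """
    r = float(ratio_value)
    if r >= params.rmax:
        raise ValueError(f"ratio {r} at or above Rmax (dye saturated)")
    if r < params.rmin:
        raise ValueError(f"ratio {r} below Rmin")
    return params.kd * params.beta * (r - params.rmin) / (params.rmax - r)


def amplitude_fold(
    relative_trace: np.ndarray, time: np.ndarray, window: StimApplication
) -> float:
    """Peak of the relative trace within [onset, washout_end]."""
    relative_trace = np.asarray(relative_trace, dtype=float)
    time = np.asarray(time, dtype=float)
    mask = (time >= window.onset) & (time <= window.washout_end)
    if not mask.any():
        raise ValueError(f"no samples in window {window.label}")
    return float(relative_trace[mask].max())


def responder_threshold(nonresponder_peaks: Sequence[float]) -> float:
    """Responder cutoff: mean + 3 x sample SD of non-responsive peak folds.

    With peaks of mean 1.00 and SD 0.05 this gives the 1.15-fold cutoff.
    """
    peaks = np.asarray(nonresponder_peaks, dtype=float)
    if peaks.size < 2:
        raise ValueError("need at least 2 non-responder peaks")
    return float(peaks.mean() + 3.0 * peaks.std(ddof=1))


def classify_responders(
    calls: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Set ``is_responder = amplitude_fold >= cutoff`` (inclusive).

    Desensitization-excluded rows keep their classification from the peak
    measured in their own window (held in ``peak_fold``) but report no
    amplitude.
    """
    out = calls.copy()
    peak = out["peak_fold"] if "peak_fold" in out else out["amplitude_fold"]
    out["is_responder"] = peak >= cutoff
    return out


def flag_desensitized(
    relative_trace: np.ndarray,
    time: np.ndarray,
    schedule: StimulusSchedule,
    recovery_fraction: float = 0.5,
    min_prev_fold: float = DEFAULT_CUTOFF,
) -> dict[str, bool]:
    """Mark later agonist doses whose preceding response never washed out.

    A stimulus after the first agonist application is excluded when the
    trace level just before its onset has not fallen below
    ``baseline + recovery_fraction * (previous peak - baseline)`` (baseline
    = 1 on the relative trace).  Exclusion only applies when the preceding
    window actually held a response (previous peak >= ``min_prev_fold``):
    with no prior response there is nothing to desensitize, and on a flat
    trace the recovery requirement would sit inside the noise floor.
    Returns {label: excluded} for every agonist application (the first is
    always False).
    """
    time = np.asarray(time, dtype=float)
    relative_trace = np.asarray(relative_trace, dtype=float)
    flags: dict[str, bool] = {}
    apps = schedule.agonist_applications
    for i, app in enumerate(apps):
        if i == 0:
            flags[app.label] = False
            continue
        prev = apps[i - 1]
        prev_peak = amplitude_fold(relative_trace, time, prev)
        if prev_peak < min_prev_fold:
            flags[app.label] = False
            continue
        pre = np.nonzero(time < app.onset)[0]
        level = relative_trace[pre[-1]] if pre.size else 1.0
        required = 1.0 + recovery_fraction * max(prev_peak - 1.0, 0.0)
        flags[app.label] = bool(level > required)
    return flags


# ---------------------------------------------------------------------------
# batch pipeline


def load_traces(path: str | Path) -> pd.DataFrame:
    """Load a long-format traces CSV.

    Columns: neuron_id, mouse_id, time, then either f340+f380 or ratio.
    """
    df = pd.read_csv(path)
    needed = {"neuron_id", "mouse_id", "time"}
    if not needed <= set(df.columns):
        raise ValueError(f"traces file needs columns {sorted(needed)}")
    if "ratio" not in df.columns and not {"f340", "f380"} <= set(df.columns):
        raise ValueError("traces file needs 'ratio' or 'f340'+'f380' columns")
    return df


def load_schedule(path: str | Path) -> StimulusSchedule:
    """Load a schedule CSV: label, onset, offset, washout_end."""
    df = pd.read_csv(path)
    apps = [
        StimApplication(r.label, float(r.onset), float(r.offset), float(r.washout_end))
        for r in df.itertuples(index=False)
    ]
    return StimulusSchedule(apps)


def analyze_traces(
    traces: pd.DataFrame,
    schedule: StimulusSchedule,
    cutoff: float = DEFAULT_CUTOFF,
    recovery_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-neuron, per-stimulus responder calls from raw traces.

    Returns one row per (neuron, stimulus) with columns neuron_id,
    mouse_id, stimulus, amplitude_fold (NaN when desensitization-excluded),
    peak_fold, is_responder, excluded_desensitized.
    """
    first_onset = schedule.applications[0].onset
    rows = []
    for (neuron, mouse), grp in traces.groupby(["neuron_id", "mouse_id"], sort=True):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy(dtype=float)
        if "ratio" in grp.columns and grp["ratio"].notna().all():
            ratio = grp["ratio"].to_numpy(dtype=float)
        else:
            ratio = compute_ratio(grp["f340"].to_numpy(), grp["f380"].to_numpy())
        rel = normalize_baseline(ratio, t, first_onset)
        desens = flag_desensitized(rel, t, schedule, recovery_fraction)
        for app in schedule.applications:
            peak = amplitude_fold(rel, t, app)
            excluded = desens.get(app.label, False)
            rows.append(
                {
                    "neuron_id": neuron,
                    "mouse_id": mouse,
                    "stimulus": app.label,
                    "amplitude_fold": np.nan if excluded else peak,
                    "peak_fold": peak,
                    "excluded_desensitized": excluded,
                }
            )
    calls = pd.DataFrame(rows)
    return classify_responders(calls, cutoff=cutoff)


def percent_responders(
    calls: pd.DataFrame,
    kcl_label: str = "KCl",
    gate_to_kcl: bool = True,
    amplitude_over: str = "responders",
) -> pd.DataFrame:
    """Per-mouse summary with %responders normalized to KCl responders.

    For each mouse and non-KCl stimulus: 100 x (#responders) / (#KCl
    responders).  With ``gate_to_kcl`` (default) the numerator only counts
    neurons that themselves responded to KCl, keeping the percentage within
    [0, 100].  A mouse with zero KCl responders gets NaN percentages and a
    warning.  ``amplitude_over`` selects whether the mean amplitude fold
    averages responders only or all non-excluded neurons.
    """
    if amplitude_over not in ("responders", "all"):
        raise ValueError("amplitude_over must be 'responders' or 'all'")
    summaries = []
    for mouse, grp in calls.groupby("mouse_id", sort=True):
        kcl = grp[grp["stimulus"] == kcl_label]
        if kcl.empty:
            raise ValueError(f"mouse {mouse}: no {kcl_label} calls")
        kcl_pos = set(kcl.loc[kcl["is_responder"], "neuron_id"])
        n_kcl = len(kcl_pos)
        row: dict[str, object] = {
            "mouse_id": mouse,
            "n_neurons": kcl["neuron_id"].nunique(),
            "n_kcl_responders": n_kcl,
        }
        if n_kcl == 0:
            warnings.warn(
                f"mouse {mouse}: no KCl responders; %responders undefined",
                RuntimeWarning,
                stacklevel=2,
            )
        for stim in calls["stimulus"].unique():
            if stim == kcl_label:
                continue
            sub = grp[grp["stimulus"] == stim]
            resp = sub[sub["is_responder"]]
            if gate_to_kcl:
                resp = resp[resp["neuron_id"].isin(kcl_pos)]
            row[f"pct_responders_{stim}"] = (
                100.0 * len(resp) / n_kcl if n_kcl else np.nan
            )
            pool = resp if amplitude_over == "responders" else sub
            amp = pool["amplitude_fold"].dropna()
            row[f"mean_fold_{stim}"] = amp.mean() if len(amp) else np.nan
        summaries.append(row)
    return pd.DataFrame(summaries)


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "unpaired_t",
) -> tuple[float, float]:
    """Two-sided group comparison on per-mouse (or per-animal) values.

    ``unpaired_t`` is Student's two-sample t-test (equal variances);
    ``oneway_anova`` is the one-way F-test.  The sampling unit is the
    animal, never the neuron.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if test == "unpaired_t":
        res = stats.ttest_ind(a, b)
    elif test == "oneway_anova":
        res = stats.f_oneway(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
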