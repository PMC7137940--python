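"""Raw trace + event log -> per-window metabolic rate records.

Each sealed recording window yields one MO2 record: the OLS slope of
chamber O2 on time, its R^2 (windows below the acceptance threshold are
flagged and excluded downstream), the time-interpolated microbial blank
rate, and the mass-specific metabolic rate

    MO2 = -(b - b_blank) * 3600 * V_eff / W    [mg O2 kg-1 h-1]

where b is the fitted slope (mg l-1 s-1), V_eff the respirometer volume
corrected for fish displacement (l) and W the fish mass (kg).  The slope is
fitted per second and converted explicitly with the 3600 factor so units
stay auditable; O2 declines while the chamber is sealed, so b is negative
and the negated, blank-corrected slope is clamped at zero (a negative
corrected rate signals blank over-correction and is recorded as 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypoxia_metrics import (
    WaterContext,
    classify_normoxia_hypoxia,
    o2_saturation_concentration,
)
from .sim_trial import FishSpec

__all__ = [
    "MeasurementWindow",
    "TraceError",
    "segment_windows",
    "fit_slope",
    "fit_blank_rates",
    "interpolate_blank",
    "compute_mo2",
    "apply_r2_filter",
    "process_trace",
]

logger = logging.getLogger(__name__)

MIN_WINDOW_SAMPLES = 30
RECORD_BOUNDS_S = (180, 300)   # 3-5 min recording span


class TraceError(ValueError):
    """Trace/event-log structure violated the pipeline's preconditions."""


@dataclass
class MeasurementWindow:
    """One recording span and the trace samples inside it."""

    window_index: int
    record_start_s: int
    record_end_s: int
    samples: pd.DataFrame

    @property
    def t_mid_h(self) -> float:
        return 0.5 * (self.record_start_s + self.record_end_s) / 3600.0


def segment_windows(
    trace: pd.DataFrame,
    events: pd.DataFrame,
    min_samples: int = MIN_WINDOW_SAMPLES,
    record_bounds_s: tuple[int, int] = RECORD_BOUNDS_S,
) -> list[MeasurementWindow]:
    """One MeasurementWindow per 'recording' phase, equilibration excluded."""
    if len(events) == 0:
        raise TraceError("empty event log")
    ev = events.sort_values("start_s").reset_index(drop=True)
    prev_end = None
    for row in ev.itertuples():
        if pd.isna(row.phase) or row.phase not in (
            "pre_blank", "flush", "equilibration", "recording", "post_blank"
        ):
            raise TraceError(
                f"unlabelled or unknown phase {row.phase!r} "
                f"[{row.start_s}, {row.end_s})"
            )
        if prev_end is not None and row.start_s < prev_end:
            raise TraceError(
                f"overlapping phases at [{row.start_s}, {row.end_s})"
            )
        prev_end = row.end_s
    t = trace["time_s"].to_numpy()
    if t.min() > ev["start_s"].min() or t.max() + 1 < ev["end_s"].max():
        raise TraceError("event log extends beyond the trace")

    windows = []
    idx = 0
    for row in ev[ev["phase"] == "recording"].itertuples():
        dur = row.end_s - row.start_s
        if not record_bounds_s[0] <= dur <= record_bounds_s[1]:
            raise TraceError(
                f"recording phase [{row.start_s}, {row.end_s}) duration "
                f"{dur}s outside {record_bounds_s}"
            )
        samples = trace[(t >= row.start_s) & (t < row.end_s)]
        if len(samples) < min_samples:
            raise TraceError(
                f"recording window [{row.start_s}, {row.end_s}) has "
                f"{len(samples)} samples (< {min_samples})"
            )
        windows.append(
            MeasurementWindow(idx, int(row.start_s), int(row.end_s), samples)
        )
        idx += 1
    return windows


def fit_slope(t_s: np.ndarray, o2: np.ndarray) -> tuple[float, float]:
    """OLS slope (per second) of O2 on time, and its R^2.

    A zero-variance (constant) trace returns slope 0 with R^2 defined as 0,
    which auto-rejects the window under the acceptance threshold.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(o2, dtype=float)
    if len(t) < 2 or len(np.unique(t)) < 2:
        raise ValueError("need >= 2 distinct time points to fit a slope")
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(tc @ tc)
    syy = float(yc @ yc)
    if syy == 0.0:
        return 0.0, 0.0
    slope = float(tc @ yc) / stt
    r2 = slope * slope * stt / syy
    return slope, float(r2)


def fit_blank_rates(
    trace: pd.DataFrame, events: pd.DataFrame
) -> tuple[float, float]:
    """Slopes (mg l-1 s-1) of the pre- and post-trial fish-absent blanks."""
    t = trace["time_s"].to_numpy()
    rates = {}
    for kind in ("pre_blank", "post_blank"):
        phase = events[events["phase"] == kind]
        if len(phase) != 1:
            raise TraceError(f"expected exactly one {kind} phase")
        start, end = int(phase["start_s"].iloc[0]), int(phase["end_s"].iloc[0])
        sel = (t >= start) & (t < end)
        rates[kind], _ = fit_slope(
            t[sel], trace["chamber_o2_mgL"].to_numpy()[sel]
        )
    return rates["pre_blank"], rates["post_blank"]


def interpolate_blank(
    pre_rate: float, post_rate: float, t_mid_h: float, trial_span_h: float
) -> float:
    """Blank O2 decline rate at a window midpoint, linear in trial time."""
    if not 0.0 <= t_mid_h <= trial_span_h:
        raise ValueError(
            f"t_mid_h {t_mid_h} outside trial span [0, {trial_span_h}]"
        )
    frac = t_mid_h / trial_span_h if trial_span_h > 0 else 0.0
    return pre_rate + frac * (post_rate - pre_rate)


def compute_mo2(slope_b: float, blank_rate: float, fish: FishSpec) -> float:
    """Mass-specific metabolic rate (mg O2 kg-1 h-1) from a window slope."""
    v_eff = fish.effective_volume_l
    if v_eff <= 0:
        raise ValueError("effective respirometer volume must be positive")
    net = -(slope_b - blank_rate)
    if net < 0:
        logger.debug("blank over-correction: clamping negative MO2 to 0")
    return max(0.0, net) * 3600.0 * v_eff / fish.mass_kg


def apply_r2_filter(
    records: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Set the ``accepted`` flag: R^2 >= threshold (inclusive) is accepted.

    Rejected records are retained in the table but must be excluded from
    every downstream estimator.
    """
    out = records.copy()
    out["accepted"] = out["r_squared"] >= threshold
    return out


def process_trace(
    trace: pd.DataFrame,
    events: pd.DataFrame,
    fish: FishSpec,
    ctx: WaterContext,
    r2_threshold: float = 0.8,
    normoxia_sat_pct: float = 80.0,
) -> pd.DataFrame:
    """Full per-window table for one trial.

    Columns: ``window_index, t_mid_h, slope_b, r_squared, blank_rate, mo2,
    mean_o2_mgL, mean_o2_sat_pct, accepted, phase``.
    """
    windows = segment_windows(trace, events)
    pre_rate, post_rate = fit_blank_rates(trace, events)
    trial_end_s = int(
        events.loc[events["phase"] == "post_blank", "start_s"].iloc[0]
    )
    span_h = trial_end_s / 3600.0

    rows = []
    for win in windows:
        t = win.samples["time_s"].to_numpy()
        o2 = win.samples["chamber_o2_mgL"].to_numpy()
        slope, r2 = fit_slope(t, o2)
        blank = interpolate_blank(pre_rate, post_rate, win.t_mid_h, span_h)
        mo2 = compute_mo2(slope, blank, fish)
        mean_o2 = float(o2.mean())
        mean_temp = float(win.samples["temp_C"].to_numpy().mean())
        c_sat = o2_saturation_concentration(
            WaterContext(
                temp_C=mean_temp,
                salinity_psu=ctx.salinity_psu,
                barometric_mmHg=ctx.barometric_mmHg,
            )
        )
        sat_pct = 100.0 * mean_o2 / c_sat
        rows.append(
            {
                "window_index": win.window_index,
                "t_mid_h": win.t_mid_h,
                "slope_b": slope,
                "r_squared": r2,
                "blank_rate": blank,
                "mo2": mo2,
                "mean_o2_mgL": mean_o2,
                "mean_o2_sat_pct": sat_pct,
                "phase": classify_normoxia_hypoxia(sat_pct, normoxia_sat_pct),
            }
        )
    records = pd.DataFrame(rows)
    return apply_r2_filter(records, r2_threshold)
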