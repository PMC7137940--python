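"""MMR, SMR, aerobic scope and post-exercise recovery time.

All estimators operate on accepted (R^2-filtered) normoxic MO2 records:

* MMR — highest metabolic rate within the first 3 h of the trial.
* SMR — mean of the lowest 10% of normoxic measurements, clamped to 5-10
  records (the lowest decile self-selects the late, recovered windows).
* AS  — MMR - SMR, exactly.
* Recovery time — first sustained entry of MO2 into the band
  SMR + band_frac * AS.  "Sustained" means the median of the entering
  record and the next two accepted records is also inside the band, so a
  single transient dip does not count.  If the band is never reached the
  last record's time is returned with ``reached=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TrialMetrics",
    "compute_mmr",
    "compute_smr",
    "compute_recovery_time",
    "summarize_trial",
    "MMR_WINDOW_H",
]

MMR_WINDOW_H = 3.0
SMR_N_MIN, SMR_N_MAX = 5, 10


@dataclass
class TrialMetrics:
    """Normoxic-phase summary for one fish x temperature trial."""

    mmr: float
    smr: float
    aerobic_scope: float
    recovery_time_h: float
    recovery_reached: bool
    smr_n_used: int
    mortality_flag: bool = False


def _accepted(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["accepted"]] if "accepted" in records else records


def compute_mmr(records: pd.DataFrame, window_h: float = MMR_WINDOW_H) -> float:
    """Maximum MO2 over accepted records in the first ``window_h`` hours."""
    acc = _accepted(records)
    early = acc[acc["t_mid_h"] <= window_h]
    if len(early) == 0:
        raise ValueError(
            f"no accepted record in the first {window_h} h: unusable trial"
        )
    return float(early["mo2"].max())


def compute_smr(
    records: pd.DataFrame, normoxia_sat_pct: float = 80.0
) -> tuple[float, int]:
    """(SMR, n_used): mean of the lowest-decile normoxic measurements.

    n_used = clamp(round(0.10 * N), 5, 10) with round-half-up, over the N
    accepted records with mean O2 saturation above the normoxia boundary.
    """
    acc = _accepted(records)
    norm = acc[acc["mean_o2_sat_pct"] > normoxia_sat_pct]
    n = len(norm)
    if n < SMR_N_MIN:
        raise ValueError(
            f"need >= {SMR_N_MIN} accepted normoxic records, got {n}"
        )
    n_used = min(SMR_N_MAX, max(SMR_N_MIN, math.floor(0.10 * n + 0.5)))
    lowest = norm["mo2"].nsmallest(n_used)
    return float(lowest.mean()), n_used


def compute_recovery_time(
    records: pd.DataFrame,
    smr: float,
    aerobic_scope: float,
    band_frac: float = 0.10,
) -> tuple[float, bool]:
    """(hours, reached): first sustained entry into SMR + band_frac * AS."""
    acc = _accepted(records).sort_values("t_mid_h")
    if len(acc) == 0:
        raise ValueError("no accepted records")
    band = smr + band_frac * aerobic_scope
    mo2 = acc["mo2"].to_numpy()
    t = acc["t_mid_h"].to_numpy()
    for i in range(len(mo2)):
        if mo2[i] <= band:
            triplet = sorted(mo2[i : i + 3])
            med = triplet[len(triplet) // 2] if len(triplet) % 2 else (
                0.5 * (triplet[len(triplet) // 2 - 1] + triplet[len(triplet) // 2])
            )
            if med <= band:
                return float(t[i]), True
    return float(t[-1]), False


def summarize_trial(
    records: pd.DataFrame,
    band_frac: float = 0.10,
    normoxia_sat_pct: float = 80.0,
    mortality_flag: bool = False,
) -> TrialMetrics:
    """All normoxic-phase metrics for one trial's record table."""
    acc = _accepted(records)
    norm = acc[acc["phase"] == "normoxic"] if "phase" in acc else acc
    mmr = compute_mmr(norm)
    smr, n_used = compute_smr(norm, normoxia_sat_pct)
    aerobic_scope = mmr - smr
    recovery_h, reached = compute_recovery_time(
        norm, smr, aerobic_scope, band_frac
    )
    return TrialMetrics(
        mmr=mmr,
        smr=smr,
        aerobic_scope=aerobic_scope,
        recovery_time_h=recovery_h,
        recovery_reached=reached,
        smr_n_used=n_used,
        mortality_flag=mortality_flag,
    )
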