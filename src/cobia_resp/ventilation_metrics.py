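"""The VRMG ventilation-volume proxy and the segmented plateau fit.

VRMG combines ventilation rate (buccal movements per minute) with relative
mouth gape: within a trial every gape is divided by the trial-minimum gape
(the calmest state), and the modified gape multiplies the window's
ventilation rate.  VRMG is assumed proportional to ventilation volume and
is normalised to the trial maximum for cross-individual comparison.

A continuous two-segment linear model of log metabolic rate on normalised
VRMG captures how metabolic rate plateaus at the highest ventilation
volumes (oxygen utilisation falls as ventilation rises); the breakpoint is
selected by grid search at 0.01 resolution with ties broken toward the
smaller breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SegmentedFit",
    "mean_gape",
    "compute_vrmg",
    "normalize_vrmg",
    "fit_segmented",
    "ventilation_coverage",
    "MIN_SEGMENTED_PAIRS",
]

MIN_SEGMENTED_PAIRS = 6
BREAK_GRID_STEP = 0.01
MIN_SIDE_POINTS = 2      # candidate breakpoints need >=2 points on each side


@dataclass
class SegmentedFit:
    """Continuous piecewise-linear fit of log MO2 on normalised VRMG."""

    breakpoint: float
    slope_low: float
    slope_high: float
    sse: float


def mean_gape(replicates) -> float:
    """Mouth gape for a window: arithmetic mean of exactly 3 replicates."""
    reps = list(replicates)
    if len(reps) != 3:
        raise ValueError(f"expected exactly 3 gape replicates, got {len(reps)}")
    if any(not r > 0 for r in reps):
        raise ValueError(f"gape replicates must be positive: {reps}")
    return float(sum(reps)) / 3.0


def compute_vrmg(obs: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``vrmg`` column for one trial's observations.

    ``vrmg = (mouth_gape / trial-min mouth_gape) * ventilation_rate``;
    windows lacking either measurement stay NaN.  The minimum-gape window
    has modified gape exactly 1, so its VRMG equals its ventilation rate.
    """
    out = obs.copy()
    complete = out["ventilation_rate"].notna() & out["mouth_gape_cm"].notna()
    if not complete.any():
        raise ValueError("no complete ventilation observation in trial")
    min_gape = float(out.loc[complete, "mouth_gape_cm"].min())
    out["vrmg"] = np.where(
        complete,
        out["mouth_gape_cm"] / min_gape * out["ventilation_rate"],
        np.nan,
    )
    return out


def normalize_vrmg(obs: pd.DataFrame) -> pd.DataFrame:
    """Fill ``vrmg_normalized``: VRMG divided by the trial maximum."""
    out = obs.copy()
    vmax = float(out["vrmg"].max())
    if not vmax > 0:
        raise ValueError("trial maximum VRMG is zero or undefined")
    out["vrmg_normalized"] = out["vrmg"] / vmax
    return out


def _hinge_sse(x: np.ndarray, y: np.ndarray, bp: float):
    """Least-squares continuous two-segment fit at a fixed breakpoint."""
    design = np.column_stack(
        [np.ones_like(x), x, np.maximum(0.0, x - bp)]
    )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def fit_segmented(
    vrmg_normalized: np.ndarray, log_mo2: np.ndarray
) -> SegmentedFit:
    """Grid-search the breakpoint of a continuous two-segment linear model.

    Candidates are the 0.01-grid points strictly inside the observed VRMG
    range with at least two observations on each side; the global-SSE
    minimiser wins, ties going to the smaller breakpoint.
    """
    x = np.asarray(vrmg_normalized, dtype=float)
    y = np.asarray(log_mo2, dtype=float)
    if len(x) < MIN_SEGMENTED_PAIRS:
        raise ValueError(
            f"insufficient ventilation coverage: {len(x)} pairs "
            f"(need >= {MIN_SEGMENTED_PAIRS})"
        )
    xmin, xmax = float(x.min()), float(x.max())
    lo = np.ceil(xmin / BREAK_GRID_STEP) * BREAK_GRID_STEP
    candidates = np.round(
        np.arange(lo, xmax, BREAK_GRID_STEP), 10
    )
    candidates = candidates[(candidates > xmin) & (candidates < xmax)]
    candidates = [
        b
        for b in candidates
        if (x <= b).sum() >= MIN_SIDE_POINTS and (x >= b).sum() >= MIN_SIDE_POINTS
    ]
    if not candidates:
        raise ValueError("no admissible interior breakpoint candidate")

    best = None
    for bp in candidates:   # ascending: first strict improvement keeps ties low
        sse, coef = _hinge_sse(x, y, bp)
        if best is None or sse < best[0] - 1e-10 * max(1.0, best[0]):
            best = (sse, bp, coef)
    sse, bp, coef = best
    return SegmentedFit(
        breakpoint=float(bp),
        slope_low=float(coef[1]),
        slope_high=float(coef[1] + coef[2]),
        sse=sse,
    )


def ventilation_coverage(obs: pd.DataFrame, n_windows: int) -> float:
    """Fraction of measurement windows with a complete ventilation record.

    Segmented fits are only reported for trials with coverage >= 0.30.
    """
    if n_windows <= 0:
        raise ValueError("n_windows must be positive")
    complete = obs["ventilation_rate"].notna() & obs["mouth_gape_cm"].notna()
    return float(complete.sum()) / n_windows
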