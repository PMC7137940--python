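"""Critical-oxygen estimation and dissolved-oxygen physics.

The critical oxygen concentration (C_crit) is the ambient O2 level below
which a fish can no longer sustain its standard metabolic rate (SMR) and
becomes an oxyconformer.  It is estimated here by the regression-intersection
method: find the terminal run of sub-SMR metabolic rate measurements on the
hypoxia ramp, regress metabolic rate on ambient O2 over that run (2-11
points), and intersect the fitted line with SMR.  C_crit converts to a
saturation fraction (S_crit) through the air-equilibrated solubility of O2
and to a partial pressure (P_crit) through the O2 fraction of water-vapour-
corrected air.

Solubility follows the Garcia & Gordon (1992) combined fit to the
Benson & Krause data; water vapour pressure follows Green & Carritt (1967).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WaterContext",
    "CritResult",
    "o2_saturation_concentration",
    "water_vapor_pressure_mmHg",
    "po2_air_saturated",
    "classify_normoxia_hypoxia",
    "find_ccrit",
]

# Garcia & Gordon (1992) "combined fit" coefficients, C* in ml(STP) l-1.
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
_GG_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_GG_C0 = -4.88682e-7
_ML_PER_MG = 1.42905          # mg O2 per ml(STP) O2
_O2_DRY_AIR_FRAC = 0.2095


@dataclass
class WaterContext:
    """Temperature / salinity / pressure context of a trial.

    Houses the "100% saturation at the treatment temperature" and the
    barometric term of the S_crit and P_crit conversions.
    """

    temp_C: float
    salinity_psu: float = 20.0
    barometric_mmHg: float = 760.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.salinity_psu <= 40.0:
            raise ValueError(f"salinity out of range: {self.salinity_psu}")
        if not 600.0 < self.barometric_mmHg < 800.0:
            raise ValueError(
                f"barometric pressure out of range: {self.barometric_mmHg}"
            )


@dataclass
class CritResult:
    """Outcome of the critical-oxygen breakpoint estimation.

    ``flag`` is ``"ok"`` for a clean estimate, ``"not_reached"`` when no
    terminal sub-SMR run of length >= 2 exists (the ramp did not push the
    fish into oxyconformity) and ``"degenerate_slope"`` when the run
    regression had non-positive slope and the estimate fell back to the
    highest-O2 sub-SMR record.
    """

    ccrit_mgL: float
    scrit_frac: float
    pcrit_mmHg: float
    n_points: int
    regression_slope: float
    regression_intercept: float
    flag: str = "ok"

    @property
    def reached(self) -> bool:
        return self.flag != "not_reached"


def water_vapor_pressure_mmHg(temp_C: float, salinity_psu: float = 0.0) -> float:
    """Saturation water vapour pressure (mmHg) over (saline) water."""
    t_k = temp_C + 273.15
    ln_p_atm = (
        24.4543
        - 67.4509 * (100.0 / t_k)
        - 4.8489 * math.log(t_k / 100.0)
        - 0.000544 * salinity_psu
    )
    return 760.0 * math.exp(ln_p_atm)


def o2_saturation_concentration(ctx: WaterContext) -> float:
    """Air-equilibrated dissolved O2 concentration (mg l-1).

    Garcia-Gordon solubility at 1 atm moist air, rescaled for ambient
    barometric pressure by (P - pH2O)/(760 - pH2O).
    """
    t = ctx.temp_C
    if not 0.0 <= t <= 40.0:
        raise ValueError(f"temperature out of solubility-fit range: {t}")
    ts = math.log((298.15 - t) / (273.15 + t))
    ln_c = 0.0
    for i, a in enumerate(_GG_A):
        ln_c += a * ts ** i
    ln_c += ctx.salinity_psu * sum(b * ts ** i for i, b in enumerate(_GG_B))
    ln_c += _GG_C0 * ctx.salinity_psu ** 2
    c_mgL = math.exp(ln_c) * _ML_PER_MG
    p_h2o = water_vapor_pressure_mmHg(t, ctx.salinity_psu)
    return c_mgL * (ctx.barometric_mmHg - p_h2o) / (760.0 - p_h2o)


def po2_air_saturated(ctx: WaterContext) -> float:
    """Partial pressure of O2 (mmHg) in air-equilibrated water."""
    # Context validation (range checks) happens in WaterContext itself.
    p_h2o = water_vapor_pressure_mmHg(ctx.temp_C, ctx.salinity_psu)
    return (ctx.barometric_mmHg - p_h2o) * _O2_DRY_AIR_FRAC


def classify_normoxia_hypoxia(
    mean_o2_sat_pct: float, boundary_pct: float = 80.0
) -> str:
    """Label a measurement window: ``"normoxic"`` iff saturation > 80%."""
    return "normoxic" if mean_o2_sat_pct > boundary_pct else "hypoxic"


def find_ccrit(
    records: pd.DataFrame,
    smr: float,
    ctx: WaterContext,
    max_points: int = 11,
    rel_margin: float = 1e-3,
) -> CritResult:
    """Estimate C_crit from accepted hypoxic records by regression intersection.

    Parameters
    ----------
    records
        Accepted hypoxic MO2 records with columns ``mean_o2_mgL`` and
        ``mo2``; internally ordered by descending ambient O2.
    smr
        The fish's standard metabolic rate (mg O2 kg-1 h-1), > 0.
    ctx
        Water context for the S_crit / P_crit conversions.
    max_points
        Regression uses at most this many of the lowest-O2 run points.

    Notes
    -----
    The terminal run is the longest suffix (in descending-O2 order) whose
    metabolic rates are all strictly below SMR.  "Below" carries a small
    relative margin (``rel_margin``, default 0.1% of SMR): a record at the
    SMR plateau to within that margin has not meaningfully dropped below
    it.  The margin is far inside one record's sensor noise, so it only
    matters in the noise-free limit, where it keeps plateau records out of
    the run.  Exact duplicate (O2, MO2) points are collapsed before the
    regression so repeated measurements do not re-weight the fit.
    """
    if smr <= 0:
        raise ValueError("smr must be positive")
    df = records.sort_values("mean_o2_mgL", ascending=False)
    o2 = df["mean_o2_mgL"].to_numpy(dtype=float)
    mo2 = df["mo2"].to_numpy(dtype=float)

    below = mo2 < smr * (1.0 - rel_margin)
    run_len = 0
    for flag in below[::-1]:
        if not flag:
            break
        run_len += 1
    if run_len < 2:
        return CritResult(
            ccrit_mgL=float("nan"), scrit_frac=float("nan"),
            pcrit_mmHg=float("nan"), n_points=run_len,
            regression_slope=float("nan"),
            regression_intercept=float("nan"), flag="not_reached",
        )

    run_o2 = o2[-run_len:]
    run_mo2 = mo2[-run_len:]
    pts = np.unique(np.column_stack([run_o2, run_mo2]), axis=0)[::-1]
    run_o2, run_mo2 = pts[:, 0], pts[:, 1]
    if len(run_o2) > max_points:
        run_o2 = run_o2[-max_points:]
        run_mo2 = run_mo2[-max_points:]
    n_points = len(run_o2)

    x = run_o2 - run_o2.mean()
    sxx = float(x @ x)
    slope = float(x @ (run_mo2 - run_mo2.mean()) / sxx) if sxx > 0 else 0.0
    intercept = float(run_mo2.mean() - slope * run_o2.mean())

    c_sat = o2_saturation_concentration(ctx)
    po2_sat = po2_air_saturated(ctx)
    if slope <= 0:
        ccrit = float(run_o2[0])   # highest-O2 sub-SMR record
        flag = "degenerate_slope"
    else:
        ccrit = (smr - intercept) / slope
        flag = "ok"
    scrit = ccrit / c_sat
    return CritResult(
        ccrit_mgL=float(ccrit),
        scrit_frac=float(scrit),
        pcrit_mmHg=float(scrit * po2_sat),
        n_points=n_points,
        regression_slope=slope,
        regression_intercept=intercept,
        flag=flag,
    )
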