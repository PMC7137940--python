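"""Batch orchestration, file IO and treatment-level summaries.

The pipeline runs per trial:  simulate (optional) -> per-window MO2 records
-> normoxic metrics (MMR/SMR/AS/recovery) -> critical-oxygen metrics ->
ventilation metrics -> treatment summaries (means, sd, n and percent-change
contrasts between treatment temperatures).  Statistical inference (mixed
models, p-values) is deliberately out of scope; the summaries are
descriptive.

Percent change between treatments a and b is 100 * (mean_b - mean_a) /
mean_a, i.e. the change at the second temperature relative to the first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import SimConfig, default_config, dump_config
from .hypoxia_metrics import CritResult, WaterContext, find_ccrit
from .sim_trial import FishSpec, TrialData, simulate_trial
from .trace_processing import TraceError, fit_slope, process_trace
from .trial_metrics import TrialMetrics, summarize_trial
from .ventilation_metrics import (
    MIN_SEGMENTED_PAIRS,
    SegmentedFit,
    compute_vrmg,
    fit_segmented,
    mean_gape,
    normalize_vrmg,
    ventilation_coverage,
)

__all__ = [
    "TrialOutputs",
    "read_trace_csv",
    "build_ventilation_obs",
    "analyze_ventilation",
    "process_trial",
    "metrics_row",
    "summarize_treatments",
    "run_pipeline",
    "COVERAGE_THRESHOLD",
]

logger = logging.getLogger(__name__)

COVERAGE_THRESHOLD = 0.30

TRACE_COLUMNS = ["time_s", "chamber_o2_mgL", "reservoir_o2_mgL", "temp_C"]

METRIC_COLUMNS = {
    "MMR": "mmr",
    "SMR": "smr",
    "AS": "aerobic_scope",
    "recovery_time": "recovery_time_h",
    "Ccrit": "ccrit_mgL",
    "Scrit": "scrit_pct",
    "Pcrit": "pcrit_mmHg",
}

DEFAULT_PAIRS = ((24.0, 28.0), (24.0, 32.0), (28.0, 32.0))


def read_trace_csv(path) -> pd.DataFrame:
    """Read and validate a trace CSV, naming the offending line on error."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # tokenizer errors already carry line numbers
        raise TraceError(f"{path}: unparseable trace CSV: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"{path}: missing trace columns {missing}")
    for col in TRACE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise TraceError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = coerced
    return df


def build_ventilation_obs(vent_raw: pd.DataFrame) -> pd.DataFrame:
    """Raw camera CSV -> per-window observations with mean mouth gape."""
    out = vent_raw[["window_index", "ventilation_rate"]].copy()
    gapes = []
    rep_cols = ["gape_rep1_cm", "gape_rep2_cm", "gape_rep3_cm"]
    for _, row in vent_raw.iterrows():
        reps = [row[c] for c in rep_cols]
        if any(pd.isna(r) for r in reps):
            gapes.append(np.nan)
        else:
            gapes.append(mean_gape(reps))
    out["mouth_gape_cm"] = gapes
    return out


@dataclass
class VentilationAnalysis:
    obs: pd.DataFrame
    coverage: float
    segmented: SegmentedFit | None
    ols_slope: float
    n_pairs: int


def analyze_ventilation(
    records: pd.DataFrame, vent_raw: pd.DataFrame
) -> VentilationAnalysis:
    """VRMG construction, normalisation and the per-trial plateau fit.

    VRMG and its normalisation use every complete observation (they reflect
    the fish's real extremes); the segmented and OLS fits pair observations
    with *accepted normoxic* MO2 records only, and the segmented fit is
    reported only when coverage >= 30% of the measurement windows.
    """
    obs = build_ventilation_obs(vent_raw)
    n_windows = len(records)
    coverage = ventilation_coverage(obs, n_windows)
    obs = normalize_vrmg(compute_vrmg(obs))

    acc = records[(records["accepted"]) & (records["phase"] == "normoxic")]
    merged = acc.merge(obs, on="window_index", how="inner")
    merged = merged[merged["vrmg_normalized"].notna() & (merged["mo2"] > 0)]
    x = merged["vrmg_normalized"].to_numpy()
    y = np.log(merged["mo2"].to_numpy())

    seg = None
    ols_slope = float("nan")
    if len(x) >= 2 and len(np.unique(x)) >= 2:
        ols_slope, _ = fit_slope(x, y)
    if coverage >= COVERAGE_THRESHOLD and len(x) >= MIN_SEGMENTED_PAIRS:
        try:
            seg = fit_segmented(x, y)
        except ValueError as exc:
            logger.warning("segmented fit skipped: %s", exc)
    return VentilationAnalysis(
        obs=obs,
        coverage=coverage,
        segmented=seg,
        ols_slope=ols_slope,
        n_pairs=len(x),
    )


@dataclass
class TrialOutputs:
    """Everything the pipeline derives from one trial."""

    records: pd.DataFrame
    metrics: TrialMetrics
    crit: CritResult
    ventilation: VentilationAnalysis | None


def process_trial(
    trace: pd.DataFrame,
    events: pd.DataFrame,
    fish: FishSpec,
    ctx: WaterContext,
    config: SimConfig | None = None,
    vent_raw: pd.DataFrame | None = None,
    mortality_flag: bool = False,
) -> TrialOutputs:
    """Run the full analysis for one trial."""
    config = config or default_config()
    records = process_trace(
        trace,
        events,
        fish,
        ctx,
        r2_threshold=config.r2_threshold,
        normoxia_sat_pct=config.normoxia_sat_pct,
    )
    metrics = summarize_trial(
        records,
        band_frac=config.band_frac,
        normoxia_sat_pct=config.normoxia_sat_pct,
        mortality_flag=mortality_flag,
    )
    hyp = records[(records["accepted"]) & (records["phase"] == "hypoxic")]
    crit = find_ccrit(hyp, metrics.smr, ctx)
    vent = None
    if vent_raw is not None and len(vent_raw):
        try:
            vent = analyze_ventilation(records, vent_raw)
        except ValueError as exc:
            logger.warning("ventilation analysis skipped: %s", exc)
    return TrialOutputs(
        records=records, metrics=metrics, crit=crit, ventilation=vent
    )


def metrics_row(
    fish_id: str, temp_C: float, out: TrialOutputs
) -> dict:
    """One per-trial row of the combined metrics table."""
    m, c = out.metrics, out.crit
    return {
        "fish_id": fish_id,
        "temp_C": temp_C,
        "mmr": m.mmr,
        "smr": m.smr,
        "aerobic_scope": m.aerobic_scope,
        "recovery_time_h": m.recovery_time_h,
        "recovery_reached": m.recovery_reached,
        "smr_n_used": m.smr_n_used,
        "mortality_flag": m.mortality_flag,
        "ccrit_mgL": c.ccrit_mgL,
        "scrit_pct": 100.0 * c.scrit_frac,
        "pcrit_mmHg": c.pcrit_mmHg,
        "crit_n_points": c.n_points,
        "crit_flag": c.flag,
    }


def summarize_treatments(
    metrics: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
    metric_columns: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-treatment means/sd/n and percent-change contrasts.

    Mortality-flagged trials are excluded throughout.  Raises on a
    requested treatment with no usable trials for a metric.
    """
    cols = metric_columns or METRIC_COLUMNS
    df = metrics[~metrics["mortality_flag"].astype(bool)]
    temps = sorted({t for pair in pairs for t in pair} | set(df["temp_C"]))

    summary_rows, contrast_rows = [], []
    for name, col in cols.items():
        if col not in df.columns:
            continue
        means = {}
        for temp in temps:
            cell = df.loc[df["temp_C"] == temp, col].dropna()
            if len(cell) == 0:
                raise ValueError(
                    f"no usable trials for metric {name} at {temp} deg C"
                )
            means[temp] = float(cell.mean())
            summary_rows.append(
                {
                    "metric": name,
                    "temp_C": temp,
                    "mean": means[temp],
                    "sd": float(cell.std(ddof=1)) if len(cell) > 1 else 0.0,
                    "n": int(len(cell)),
                }
            )
        for a, b in pairs:
            if a in means and b in means:
                contrast_rows.append(
                    {
                        "metric": name,
                        "temp_a": a,
                        "temp_b": b,
                        "percent_change": 100.0 * (means[b] - means[a]) / means[a],
                    }
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(contrast_rows)


def _config_hash(config: SimConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]


def run_pipeline(
    config: SimConfig,
    seed: int,
    out_dir,
    temps=None,
    n_fish: int = 4,
    write_traces: bool = False,
) -> pd.DataFrame:
    """Simulate, process and summarise a whole experiment.

    Per-trial failures are logged with trial id and stage and the run
    continues.  Outputs (``mo2_records.csv``, ``trial_metrics.csv``,
    ``ventilation.csv``, ``segmented_fits.csv``, ``treatment_summary.csv``,
    ``treatment_contrasts.csv``, ``run.log``) are byte-reproducible for a
    given (config, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    temps = list(temps) if temps is not None else sorted(config.treatments)

    all_records, all_metrics, all_vent, all_seg = [], [], [], []
    trial_ids = []
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(len(temps) * n_fish) % (2**31)
    k = 0
    for temp in temps:
        for fidx in range(n_fish):
            trial_id = f"T{temp:g}_f{fidx}"
            trial_seed = int(trial_seeds[k]); k += 1
            try:
                trial = simulate_trial(config, temp, trial_seed)
            except Exception as exc:
                logger.error("trial %s failed at stage simulate: %s", trial_id, exc)
                continue
            if write_traces:
                tdir = out_dir / "trials" / trial_id
                tdir.mkdir(parents=True, exist_ok=True)
                trial.trace.to_csv(tdir / "trace.csv", index=False)
                trial.events.to_csv(tdir / "events.csv", index=False)
                trial.ventilation.to_csv(tdir / "ventilation.csv", index=False)
                pd.DataFrame([asdict(trial.truth)]).to_csv(
                    tdir / "truth.csv", index=False
                )
            try:
                out = process_trial(
                    trial.trace,
                    trial.events,
                    trial.fish,
                    trial.ctx,
                    config=config,
                    vent_raw=trial.ventilation,
                )
            except Exception as exc:
                logger.error("trial %s failed at stage process: %s", trial_id, exc)
                continue
            trial_ids.append(trial_id)
            rec = out.records.copy()
            rec.insert(0, "trial_id", trial_id)
            all_records.append(rec)
            all_metrics.append(metrics_row(trial_id, temp, out))
            if out.ventilation is not None:
                v = out.ventilation.obs.copy()
                v.insert(0, "trial_id", trial_id)
                all_vent.append(v)
                if out.ventilation.segmented is not None:
                    seg = asdict(out.ventilation.segmented)
                    seg["trial_id"] = trial_id
                    seg["coverage"] = out.ventilation.coverage
                    seg["n_pairs"] = out.ventilation.n_pairs
                    all_seg.append(seg)

    records_df = pd.concat(all_records, ignore_index=True)
    metrics_df = pd.DataFrame(all_metrics)
    records_df.to_csv(out_dir / "mo2_records.csv", index=False)
    metrics_df.to_csv(out_dir / "trial_metrics.csv", index=False)
    if all_vent:
        pd.concat(all_vent, ignore_index=True).to_csv(
            out_dir / "ventilation.csv", index=False
        )
    else:
        logger.warning("no ventilation observations: ventilation outputs absent")
    if all_seg:
        pd.DataFrame(all_seg).to_csv(out_dir / "segmented_fits.csv", index=False)

    if len(temps) > 1:
        pairs = [
            (a, b) for a, b in DEFAULT_PAIRS if a in temps and b in temps
        ] or [(temps[0], temps[-1])]
    else:
        pairs = [(temps[0], temps[0])]
    summary_df, contrasts_df = summarize_treatments(metrics_df, pairs)
    summary_df.to_csv(out_dir / "treatment_summary.csv", index=False)
    contrasts_df.to_csv(out_dir / "treatment_contrasts.csv", index=False)

    log = {
        "package_version": _pkg_version,
        "seed": seed,
        "config_sha256_16": _config_hash(config),
        "temps": [float(t) for t in temps],
        "n_fish": n_fish,
        "trials": trial_ids,
        "inputs": "simulated in memory from (config, seed)",
        "warnings": "see stderr log; machine-parsable flags live in the CSVs",
    }
    (out_dir / "run.log").write_text(json.dumps(log, indent=2) + "\n")
    return metrics_df
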