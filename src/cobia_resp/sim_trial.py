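"""Synthetic intermittent-flow respirometry trials.

Generates the full data footprint of one trial — a 1 Hz oxygen/temperature
trace, the flush/measurement event log, camera-style ventilation
observations with dropout, and the hidden truth table — so every stage of
the analysis pipeline can be verified by parameter recovery.

The simulated fish enters the respirometer at its maximum metabolic rate
(post-chase), decays exponentially toward its standard metabolic rate with
time constant ``tau_h`` (excess post-exercise oxygen consumption), and
becomes a linear oxyconformer once ambient O2 falls below its true critical
concentration.  Chamber oxygen follows an explicit 1 s Euler integration of
the fish + microbial sinks while the chamber is sealed, and relaxes
exponentially toward the reservoir during flushing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import ScheduleConfig, SimConfig
from .hypoxia_metrics import WaterContext, o2_saturation_concentration

__all__ = [
    "FishSpec",
    "SimTruth",
    "Phase",
    "TrialSchedule",
    "ScheduleError",
    "make_schedule",
    "true_mo2",
    "simulate_trace",
    "simulate_ventilation",
    "TrialData",
    "simulate_trial",
    "truth_for_treatment",
]

logger = logging.getLogger(__name__)

WATER_DENSITY_KG_L = 1.0   # fish displacement volume = mass / water density

PHASE_KINDS = ("pre_blank", "flush", "equilibration", "recording", "post_blank")


class ScheduleError(ValueError):
    """A trial schedule violated the apparatus's operating ranges."""


@dataclass
class FishSpec:
    """One experimental animal and its chamber."""

    mass_kg: float
    total_length_cm: float
    treatment_temp_C: float
    respirometer_volume_l: float

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        if self.total_length_cm <= 0:
            raise ValueError("total_length_cm must be positive")
        if self.respirometer_volume_l <= self.displacement_l:
            raise ValueError(
                "respirometer volume must exceed fish displacement volume"
            )

    @property
    def displacement_l(self) -> float:
        return self.mass_kg / WATER_DENSITY_KG_L

    @property
    def effective_volume_l(self) -> float:
        """Respirometer volume corrected for the volume of the fish."""
        return self.respirometer_volume_l - self.displacement_l


@dataclass
class SimTruth:
    """Hidden parameters of a simulated fish, for recovery tests.

    ``recovery_time_true_h`` is the band-entry time of the noiseless decay
    against the pipeline's recovery band (SMR + band_frac * AS):
    tau * ln(1 / band_frac).
    """

    smr_true: float              # mg O2 kg-1 h-1
    mmr_true: float              # mg O2 kg-1 h-1
    tau_h: float                 # EPOC decay time constant (h)
    ccrit_true: float            # mg l-1
    blank_slope_pre: float       # mg l-1 h-1, <= 0
    blank_slope_post: float      # mg l-1 h-1, <= 0
    recovery_time_true_h: float = field(default=float("nan"))
    band_frac: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.smr_true < self.mmr_true:
            raise ValueError("need 0 < smr_true < mmr_true")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        if self.ccrit_true <= 0:
            raise ValueError("ccrit_true must be positive")
        if math.isnan(self.recovery_time_true_h):
            self.recovery_time_true_h = self.tau_h * math.log(1.0 / self.band_frac)


Phase = tuple  # (kind, start_s, end_s), half-open [start, end)


@dataclass
class TrialSchedule:
    """Ordered, contiguous phases plus the hypoxia setpoint timeline.

    Times are seconds on the trial clock: 0 is fish entry, the pre-trial
    blank occupies negative times.
    """

    phases: list[Phase]
    hypoxia_steps: list[tuple[float, int]]   # (saturation setpoint %, start_s)

    def __post_init__(self) -> None:
        prev_end = None
        for kind, start, end in self.phases:
            if kind not in PHASE_KINDS:
                raise ScheduleError(f"unknown phase kind {kind!r}")
            if end <= start:
                raise ScheduleError(f"empty phase {kind} [{start}, {end})")
            if prev_end is not None and start != prev_end:
                raise ScheduleError(
                    f"phases not contiguous at t={start} (previous end {prev_end})"
                )
            prev_end = end
        pcts = [p for p, _ in self.hypoxia_steps]
        if any(b >= a for a, b in zip(pcts, pcts[1:])):
            raise ScheduleError("hypoxia setpoints must be strictly decreasing")

    @property
    def start_s(self) -> int:
        return self.phases[0][1]

    @property
    def end_s(self) -> int:
        return self.phases[-1][2]

    @property
    def trial_end_s(self) -> int:
        """Start of the post-trial blank (fish removal)."""
        for kind, start, _ in self.phases:
            if kind == "post_blank":
                return start
        return self.end_s

    def recording_phases(self) -> list[Phase]:
        return [p for p in self.phases if p[0] == "recording"]

    def setpoint_frac(self, t_s: float) -> float:
        """Reservoir saturation setpoint (fraction of 100%) at time ``t_s``."""
        frac = 1.0
        for pct, start in self.hypoxia_steps:
            if t_s >= start:
                frac = pct / 100.0
        return frac

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phases, columns=["phase", "start_s", "end_s"])


def make_schedule(config: ScheduleConfig) -> TrialSchedule:
    """Build the trial schedule from cycle durations and the hypoxia ramp.

    The first measurement starts immediately at fish entry (the chamber is
    sealed as soon as the fish is in), so the first normoxic cycle has no
    leading flush; every later cycle is flush -> equilibration -> recording.
    Hypoxia setpoints change at the start of the flush that introduces them.
    """
    c = config
    if not 7.0 <= c.flush_min <= 15.0:
        raise ScheduleError(f"flush_min outside 7-15 min: {c.flush_min}")
    if not 4.0 <= c.measure_min <= 7.0:
        raise ScheduleError(f"measure_min outside 4-7 min: {c.measure_min}")
    if not 1.0 <= c.equil_min <= 2.0:
        raise ScheduleError(f"equil_min outside 1-2 min: {c.equil_min}")
    record_min = c.measure_min - c.equil_min
    if not 3.0 <= record_min <= 5.0:
        raise ScheduleError(f"recording span outside 3-5 min: {record_min}")
    if c.blank_h < 3.0:
        raise ScheduleError(f"blank phases must be >= 3 h: {c.blank_h}")
    if c.normoxia_h <= 0:
        raise ScheduleError("normoxia_h must be positive")
    if c.cycles_per_step < 1:
        raise ScheduleError("cycles_per_step must be >= 1")
    pcts = list(c.hypoxia_setpoints_pct)
    if any(not 0 < p < 100 for p in pcts):
        raise ScheduleError("hypoxia setpoints must be in (0, 100)%")
    if any(b >= a for a, b in zip(pcts, pcts[1:])):
        raise ScheduleError("hypoxia setpoints must be strictly decreasing")

    flush_s = int(round(c.flush_min * 60))
    equil_s = int(round(c.equil_min * 60))
    record_s = int(round(record_min * 60))
    blank_s = int(round(c.blank_h * 3600))
    cycle_s = flush_s + equil_s + record_s
    n_norm = max(1, int(round(c.normoxia_h * 3600 / cycle_s)))

    phases: list[Phase] = [("pre_blank", -blank_s, 0)]
    t = 0
    # first cycle: sealed immediately, no flush
    phases.append(("equilibration", t, t + equil_s)); t += equil_s
    phases.append(("recording", t, t + record_s)); t += record_s
    for _ in range(n_norm - 1):
        phases.append(("flush", t, t + flush_s)); t += flush_s
        phases.append(("equilibration", t, t + equil_s)); t += equil_s
        phases.append(("recording", t, t + record_s)); t += record_s

    hypoxia_steps: list[tuple[float, int]] = []
    for pct in pcts:
        hypoxia_steps.append((pct, t))
        for _ in range(c.cycles_per_step):
            phases.append(("flush", t, t + flush_s)); t += flush_s
            phases.append(("equilibration", t, t + equil_s)); t += equil_s
            phases.append(("recording", t, t + record_s)); t += record_s
    phases.append(("post_blank", t, t + blank_s))
    return TrialSchedule(phases=phases, hypoxia_steps=hypoxia_steps)


def true_mo2(t_s, chamber_o2, truth: SimTruth):
    """True instantaneous metabolic rate (mg O2 kg-1 h-1) of the model fish.

    SMR + (MMR - SMR) * exp(-t / tau) while ambient O2 >= true C_crit;
    scaled by the linear oxyconforming factor O2 / C_crit below it.
    Accepts scalars or numpy arrays.
    """
    t_h = np.asarray(t_s, dtype=float) / 3600.0
    o2 = np.asarray(chamber_o2, dtype=float)
    m = truth.smr_true + (truth.mmr_true - truth.smr_true) * np.exp(
        -t_h / truth.tau_h
    )
    conform = np.clip(o2 / truth.ccrit_true, 0.0, 1.0)
    out = m * conform
    return float(out) if out.ndim == 0 else out


def _blank_rate(t_s, truth: SimTruth, trial_end_s: float):
    """Microbial O2 decline (mg l-1 h-1, <= 0), linear in time over the trial."""
    frac = np.clip(np.asarray(t_s, dtype=float) / trial_end_s, 0.0, 1.0)
    return truth.blank_slope_pre + frac * (
        truth.blank_slope_post - truth.blank_slope_pre
    )


def simulate_trace(
    fish: FishSpec,
    truth: SimTruth,
    schedule: TrialSchedule,
    noise_sd: float,
    seed: int,
    ctx: WaterContext | None = None,
    flush_tau_s: float = 60.0,
    diel_amplitude: float = 0.0,
    temp_jitter_sd_C: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrate one trial and return (trace, event log).

    The trace has one row per second: ``time_s, chamber_o2_mgL,
    reservoir_o2_mgL, temp_C``.  Sealed phases use explicit Euler at 1 s:
    dC/dt = -(MO2_true * W + |blank| * V_eff) / (3600 * V_eff); flushes relax
    the chamber toward the reservoir setpoint with time constant
    ``flush_tau_s``.  Identical seeds give bit-identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ctx = ctx or WaterContext(temp_C=fish.treatment_temp_C)
    c_sat = o2_saturation_concentration(ctx)
    v_eff = fish.effective_volume_l
    w = fish.mass_kg
    trial_end = schedule.trial_end_s
    rng = np.random.default_rng(seed)

    def diel(t_arr):
        if diel_amplitude == 0.0:
            return 1.0
        return 1.0 + diel_amplitude * np.cos(2 * np.pi * t_arr / (24 * 3600.0))

    chamber_parts: list[np.ndarray] = []
    c = c_sat  # chamber starts air-equilibrated
    reservoir_parts: list[np.ndarray] = []
    floored = False

    for kind, start, end in schedule.phases:
        t_arr = np.arange(start, end, dtype=float)
        n = len(t_arr)
        setpoint = schedule.setpoint_frac(start)
        reservoir_parts.append(np.full(n, setpoint * c_sat))
        bl = np.abs(_blank_rate(t_arr, truth, trial_end)) / 3600.0
        if kind in ("pre_blank", "post_blank"):
            rate = bl
            vals = c - np.concatenate(([0.0], np.cumsum(rate[:-1])))
            c = c - float(np.sum(rate))
        elif kind == "flush":
            r = setpoint * c_sat
            alpha = 1.0 - 1.0 / flush_tau_s
            vals = r + (c - r) * alpha ** np.arange(n)
            c = r + (c - r) * alpha ** n
        else:  # sealed: equilibration or recording
            m = (
                truth.smr_true
                + (truth.mmr_true - truth.smr_true)
                * np.exp(-t_arr / 3600.0 / truth.tau_h)
            ) * diel(t_arr)
            rate = m * w / v_eff / 3600.0 + bl
            vals = c - np.concatenate(([0.0], np.cumsum(rate[:-1])))
            c_end = c - float(np.sum(rate))
            if min(vals.min(), c_end) >= truth.ccrit_true:
                c = c_end
            else:
                # oxyconforming: the sink depends on current O2, step scalar
                vals = np.empty(n)
                for i in range(n):
                    conform = min(1.0, c / truth.ccrit_true)
                    vals[i] = c
                    c -= (m[i] * conform * w / v_eff / 3600.0 + bl[i])
                    if c < 0.0:
                        c = 0.0
                        floored = True
        chamber_parts.append(vals)

    if floored:
        logger.warning(
            "chamber O2 floored at 0 mg/l: hypoxia ramp over-aggressive "
            "for this fish"
        )

    time_s = np.arange(schedule.start_s, schedule.end_s, dtype=np.int64)
    chamber = np.concatenate(chamber_parts)
    reservoir = np.concatenate(reservoir_parts)
    if noise_sd > 0:
        chamber = chamber + rng.normal(0.0, noise_sd, chamber.size)
        reservoir = reservoir + rng.normal(0.0, noise_sd, reservoir.size)
    temp = np.full(time_s.size, fish.treatment_temp_C)
    if temp_jitter_sd_C > 0:
        temp = temp + rng.normal(0.0, temp_jitter_sd_C, temp.size)
    trace = pd.DataFrame(
        {
            "time_s": time_s,
            "chamber_o2_mgL": np.clip(chamber, 0.0, None),
            "reservoir_o2_mgL": np.clip(reservoir, 0.0, None),
            "temp_C": temp,
        }
    )
    return trace, schedule.to_frame()


def simulate_ventilation(
    truth: SimTruth,
    schedule: TrialSchedule,
    trace: pd.DataFrame,
    dropout_p: float,
    seed: int,
    ctx: WaterContext,
    vr0: float = 40.0,
    mg0: float = 3.0,
    vr_exp_a: float = 2.0,
    gape_gain_g: float = 3.0,
    hypoxia_exp_gamma: float = 0.7,
    hypoxia_exp_delta: float = 0.3,
    lognorm_sd: float = 0.10,
    gape_rep_sd: float = 0.02,
) -> pd.DataFrame:
    """Per-window camera observations of ventilation rate and mouth gape.

    One row per recording window: ``window_index, ventilation_rate,
    gape_rep1_cm, gape_rep2_cm, gape_rep3_cm``; unobserved windows (fish
    off-camera, probability ``dropout_p``) carry NaNs.  The dropout draws
    come from the second child stream of ``SeedSequence(seed)`` (one uniform
    per window, in window order), the observation noise from the first.

    Ventilatory effort follows metabolic *demand* (the post-exercise decay
    component, which stays at SMR level during deep hypoxia) rather than
    realised MO2: below C_crit the fish keeps ventilating hard while its
    achieved uptake collapses, which is exactly the observed decoupling of
    VRMG from metabolic rate under severe hypoxia.
    """
    if not 0.0 <= dropout_p < 1.0:
        raise ValueError("dropout_p must be in [0, 1)")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    noise_ss, drop_ss = ss.spawn(2)
    rng_noise = np.random.default_rng(noise_ss)
    rng_drop = np.random.default_rng(drop_ss)
    c_sat = o2_saturation_concentration(ctx)
    t = trace["time_s"].to_numpy()
    o2_trace = trace["chamber_o2_mgL"].to_numpy()

    windows = schedule.recording_phases()
    observed = rng_drop.random(len(windows)) >= dropout_p
    rows = []
    aspan = truth.mmr_true - truth.smr_true
    for idx, (_, start, end) in enumerate(windows):
        if not observed[idx]:
            rows.append((idx, np.nan, np.nan, np.nan, np.nan))
            continue
        sel = (t >= start) & (t < end)
        mean_o2 = float(o2_trace[sel].mean())
        t_mid = 0.5 * (start + end)
        # demand: the decay component without the oxyconforming collapse
        demand = truth.smr_true + (truth.mmr_true - truth.smr_true) * math.exp(
            -t_mid / 3600.0 / truth.tau_h
        )
        hyp = c_sat / max(mean_o2, 1e-6)
        z = rng_noise.normal(size=5)
        vr = (
            vr0
            * (demand / truth.smr_true) ** vr_exp_a
            * hyp ** hypoxia_exp_gamma
            * math.exp(lognorm_sd * z[0])
        )
        activity = 1.0 + gape_gain_g * max(0.0, demand - truth.smr_true) / aspan
        mg = mg0 * activity * hyp ** hypoxia_exp_delta * math.exp(lognorm_sd * z[1])
        reps = mg * (1.0 + gape_rep_sd * z[2:5])
        rows.append((idx, vr, *reps))
    return pd.DataFrame(
        rows,
        columns=[
            "window_index",
            "ventilation_rate",
            "gape_rep1_cm",
            "gape_rep2_cm",
            "gape_rep3_cm",
        ],
    )


@dataclass
class TrialData:
    """Everything the simulator produces for one fish x temperature trial."""

    fish: FishSpec
    truth: SimTruth
    schedule: TrialSchedule
    ctx: WaterContext
    trace: pd.DataFrame
    events: pd.DataFrame
    ventilation: pd.DataFrame


def truth_for_treatment(
    config: SimConfig, temp_C: float, **overrides
) -> SimTruth:
    """SimTruth for one treatment temperature from the configured calibration."""
    cal = config.treatments[float(temp_C)]
    kwargs = dict(
        smr_true=cal.smr,
        mmr_true=cal.mmr,
        tau_h=config.tau_h,
        ccrit_true=cal.ccrit_mgL,
        blank_slope_pre=config.blank_slope_pre,
        blank_slope_post=config.blank_slope_post,
        band_frac=config.band_frac,
    )
    kwargs.update(overrides)
    return SimTruth(**kwargs)


def simulate_trial(
    config: SimConfig,
    temp_C: float,
    seed: int,
    truth: SimTruth | None = None,
    noise_sd: float | None = None,
) -> TrialData:
    """Simulate one complete trial at a treatment temperature.

    All randomness flows from ``seed``: the trace and the ventilation
    observations draw from separate child streams of one seed sequence.
    """
    schedule = make_schedule(config.schedule)
    ctx = WaterContext(
        temp_C=temp_C,
        salinity_psu=config.salinity_psu,
        barometric_mmHg=config.barometric_mmHg,
    )
    fish = FishSpec(
        mass_kg=config.mass_kg,
        total_length_cm=config.total_length_cm,
        treatment_temp_C=temp_C,
        respirometer_volume_l=config.respirometer_volume_l,
    )
    truth = truth or truth_for_treatment(config, temp_C)
    sd = config.noise_sd_mgL if noise_sd is None else noise_sd
    trace_ss, vent_ss = np.random.SeedSequence(seed).spawn(2)
    trace, events = simulate_trace(
        fish,
        truth,
        schedule,
        noise_sd=sd,
        seed=trace_ss,
        ctx=ctx,
        flush_tau_s=config.flush_tau_s,
        diel_amplitude=config.diel_amplitude,
        temp_jitter_sd_C=config.temp_jitter_sd_C,
    )
    v = config.ventilation
    vent = simulate_ventilation(
        truth,
        schedule,
        trace,
        dropout_p=v.dropout_p,
        seed=vent_ss,
        ctx=ctx,
        vr0=v.vr0_min,
        mg0=v.mg0_cm,
        vr_exp_a=v.vr_exp_a,
        gape_gain_g=v.gape_gain_g,
        hypoxia_exp_gamma=v.hypoxia_exp_gamma,
        hypoxia_exp_delta=v.hypoxia_exp_delta,
        lognorm_sd=v.lognorm_sd,
        gape_rep_sd=v.gape_rep_sd,
    )
    return TrialData(
        fish=fish,
        truth=truth,
        schedule=schedule,
        ctx=ctx,
        trace=trace,
        events=events,
        ventilation=vent,
    )
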