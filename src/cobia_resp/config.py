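"""Configuration objects and YAML (de)serialisation for the pipeline.

Every tunable of the simulator and the analysis lives here with a documented
default, so a single YAML file drives ``simulate``, ``process`` and
``summarize`` runs identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "ScheduleConfig",
    "TreatmentCalibration",
    "VentilationConfig",
    "SimConfig",
    "default_config",
    "load_config",
    "dump_config",
]


@dataclass
class ScheduleConfig:
    """Timing of the intermittent-flow cycle and the hypoxia ramp.

    Durations are constrained to the apparatus's operating ranges:
    flushing 7-15 min, measurement 4-7 min of which 1-2 min is an
    equilibration interval (leaving a 3-5 min recording span), blanks
    at least 3 h on each side of the trial.
    """

    flush_min: float = 10.0          # flushing period (min), 7-15
    measure_min: float = 5.0         # sealed measurement period (min), 4-7
    equil_min: float = 1.0           # equilibration interval (min), 1-2
    normoxia_h: float = 20.0         # normoxic recovery phase length (h)
    blank_h: float = 3.0             # fish-absent blank phase length (h), >= 3
    # Reservoir air-saturation setpoints (%) for the stepwise hypoxia ramp,
    # strictly decreasing.  Spaced tighter near the expected critical region.
    hypoxia_setpoints_pct: Sequence[float] = (
        80.0, 70.0, 60.0, 50.0, 40.0, 33.0, 27.0, 22.0, 18.0, 15.0, 12.0,
    )
    cycles_per_step: int = 2         # measurement cycles held at each setpoint


@dataclass
class TreatmentCalibration:
    """True metabolic parameters of a simulated fish at one temperature.

    Defaults (see :func:`default_config`) follow the study's treatment
    contrasts: SMR rising 32% and 69% above the 24°C baseline at 28 and
    32°C, MMR rising 15% and 54%, and true critical oxygen concentrations
    spanning 1.7-2.4 mg/l across the 24-32°C range.
    """

    smr: float                       # standard metabolic rate (mg O2 kg-1 h-1)
    mmr: float                       # maximum metabolic rate (mg O2 kg-1 h-1)
    ccrit_mgL: float                 # critical O2 concentration (mg l-1)


@dataclass
class VentilationConfig:
    """Camera-observation model for ventilation rate and mouth gape.

    The simulated fish raises ventilation effort superlinearly with
    metabolic rate (``vr_exp_a`` > 1, ``gape_gain_g`` > 0), which produces
    the plateau of log metabolic rate against normalised VRMG seen at high
    ventilation volumes (falling oxygen utilisation), and hyperventilates
    under hypoxia via the ``(C_sat / O2)`` power terms.
    """

    vr0_min: float = 40.0            # baseline ventilation rate (min-1) at SMR
    mg0_cm: float = 3.0              # baseline mouth gape (cm) at SMR
    vr_exp_a: float = 2.5            # VR ~ (demand/SMR)**a
    gape_gain_g: float = 4.0         # MG ~ 1 + g * (demand-SMR)/(MMR-SMR)
    hypoxia_exp_gamma: float = 0.7   # VR ~ (C_sat/O2)**gamma
    hypoxia_exp_delta: float = 0.3   # MG ~ (C_sat/O2)**delta
    lognorm_sd: float = 0.10         # multiplicative log-normal noise sd
    gape_rep_sd: float = 0.02        # fractional sd of the 3 gape replicates
    dropout_p: float = 0.4           # P(window unobserved: fish off-camera)


@dataclass
class SimConfig:
    """Complete simulator + pipeline configuration."""

    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)

    # --- apparatus / sensor ---
    noise_sd_mgL: float = 0.01       # optical-sensor noise sd per 1 s sample
    flush_tau_s: float = 60.0        # chamber-reservoir mixing time constant
    temp_jitter_sd_C: float = 0.0    # optional temperature jitter (off)

    # --- water context ---
    salinity_psu: float = 20.0       # mesohaline estuarine default
    barometric_mmHg: float = 760.0

    # --- fish (defaults mid-range for the 3.1-9.8 kg study animals) ---
    mass_kg: float = 5.0
    total_length_cm: float = 95.0
    respirometer_volume_l: float = 110.0

    # --- physiology ---
    tau_h: float = 2.0               # EPOC exponential decay constant (h)
    blank_slope_pre: float = -0.02   # microbial O2 decline (mg l-1 h-1)
    blank_slope_post: float = -0.04
    diel_amplitude: float = 0.0      # optional night-time SMR modulation (off)
    treatments: dict[float, TreatmentCalibration] = field(
        default_factory=lambda: {
            24.0: TreatmentCalibration(smr=100.0, mmr=250.0, ccrit_mgL=1.7),
            28.0: TreatmentCalibration(smr=132.0, mmr=287.5, ccrit_mgL=1.9),
            32.0: TreatmentCalibration(smr=169.0, mmr=385.0, ccrit_mgL=2.4),
        }
    )

    ventilation: VentilationConfig = field(default_factory=VentilationConfig)

    # --- analysis ---
    r2_threshold: float = 0.8        # regression R^2 acceptance threshold
    band_frac: float = 0.10          # recovery band: SMR + band_frac * AS
    normoxia_sat_pct: float = 80.0   # >80% saturation classed as normoxic


def default_config() -> SimConfig:
    """A fresh configuration populated with every documented default."""
    return SimConfig()


def _to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            out[f.name] = _to_dict(getattr(obj, f.name))
        return out
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def dump_config(config: SimConfig) -> str:
    """Render a configuration as YAML."""
    return yaml.safe_dump(_to_dict(config), sort_keys=False)


def load_config(path_or_text) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file path or YAML text.

    Keys absent from the file keep their defaults.
    """
    if hasattr(path_or_text, "read"):
        raw = yaml.safe_load(path_or_text.read())
    else:
        text = str(path_or_text)
        if "\n" not in text and text.endswith((".yml", ".yaml")):
            with open(text) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(text)
    raw = raw or {}
    cfg = default_config()
    if "schedule" in raw:
        cfg.schedule = ScheduleConfig(**raw.pop("schedule"))
    if "ventilation" in raw:
        cfg.ventilation = VentilationConfig(**raw.pop("ventilation"))
    if "treatments" in raw:
        cfg.treatments = {
            float(t): TreatmentCalibration(**v)
            for t, v in raw.pop("treatments").items()
        }
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown configuration key: {key!r}")
        setattr(cfg, key, value)
    return cfg
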