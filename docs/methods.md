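# Methods

## The measurement model

Intermittent-flow respirometry alternates *flushing* (7–15 min; the chamber
is re-equilibrated with reservoir water) with sealed *measurement* periods
(4–7 min: a 1–2 min equilibration interval followed by 3–5 min of
recording). While sealed, the fish draws chamber O₂ down and the OLS slope
*b* of O₂ on time over the recording span is the rate signal. A window is
accepted only if the regression R² ≥ 0.8 (inclusive); rejected windows are
kept in the record table but excluded from every estimator. A zero-variance
window is defined to have R² = 0 (auto-reject) rather than an undefined
value.

The metabolic rate of a fish of mass `W` (kg) in a chamber of effective
volume `V_eff` (l) is

    MO2 = -(b - b_blank) * 3600 * V_eff / W        [mg O2 kg^-1 h^-1]

Notes on the conventions baked into this equation:

* `b` is fitted per second; the explicit ×3600 keeps the unit conversion
  auditable and produces rates on the familiar 100–400 mg kg⁻¹ h⁻¹ scale.
* O₂ declines while sealed, so `b` < 0; the *negated, blank-corrected*
  slope is used and clamped at 0. A negative corrected rate means the
  blank over-corrected that window; it is recorded as 0 rather than as a
  physically meaningless negative rate.
* `V_eff` = respirometer volume − fish displacement, with displacement =
  mass / 1.0 kg l⁻¹ (the density of water; the fish is almost exactly
  neutrally buoyant seawater itself).
* `b_blank` is interpolated linearly in trial time between the slopes of
  the ≥3 h fish-absent blank phases before and after the trial. Blanks are
  fitted on the full blank phase rather than per-cycle: the phase is two
  orders of magnitude longer than a measurement window, so the slope
  estimate is effectively exact even at sensor noise.

Window times are seconds from fish entry; intervals are half-open
`[start, end)`; the pre-trial blank occupies negative times.

## Normoxic metrics

Over accepted records with >80 % air saturation (the normoxia boundary is
exclusive at 80):

* **MMR** — the maximum MO₂ within the first 3 h. The first measurement
  starts at fish entry (no leading flush), so the first window midpoint
  falls ~3 min in; MMR is still biased low by whatever decay occurs before
  that midpoint. At the default decay constant this latency bias is ~1.5 %
  (measured by the parameter-recovery study; the noiseless fidelity test
  pins it analytically).
* **SMR** — the mean of the lowest `clamp(round(0.1·N), 5, 10)` records
  (round-half-up). All accepted normoxic records enter, including the
  early recovery period: the lowest decile self-selects late windows. Two
  small biases partially cancel: noise selection pulls the lowest decile
  down (≈ −1 % at default noise), while a slow post-exercise decay leaves
  the tail slightly above the true asymptote (+, grows with τ).
* **AS** = MMR − SMR, exact by construction.
* **Recovery time** — SMR is itself a band of typical quiescent values, so
  "reached SMR" is operationalised as the first accepted record with
  MO₂ ≤ SMR + 0.1·AS whose median with the next two accepted records is
  also inside the band (a single transient dip does not count). If the
  band is never reached the last record's time is returned with a
  `reached=False` flag. The band fraction (default 0.10) is a config knob.

## Critical oxygen

On the hypoxia ramp, records are ordered by descending ambient O₂ and the
*terminal run* is the longest suffix with MO₂ below SMR. A line is fitted
to (O₂, MO₂) over the run — truncated to its last (lowest-O₂) 11 points,
minimum 2 — and C_crit is the O₂ where that line reaches SMR. Then
S_crit = C_crit / C_sat and P_crit = S_crit · PO₂_air.

Numerical choices:

* "Below SMR" carries a 0.1 % relative margin. In the exact noise-free
  limit the lowest-decile SMR estimate sits infinitesimally above the true
  plateau, so without the margin *every* plateau record joins the run and
  flattens the regression. The margin is several times smaller than one
  record's noise-induced scatter at the default calibration, so it is
  inert on realistic data.
* Exact duplicate (O₂, MO₂) points are collapsed before the regression, so
  repeating a measurement does not re-weight the fit.
* A run regression with slope ≤ 0 cannot intersect SMR from below; the
  estimate falls back to the highest-O₂ sub-SMR record and is flagged
  `degenerate_slope`. No terminal run of length ≥ 2 yields `not_reached`
  (such fish are excluded from critical-oxygen summaries, as in the
  source protocol).

**Solubility physics.** C_sat uses the García–Gordon (1992) combined fit
to the Benson–Krause data (ml l⁻¹ coefficients × 1.42905), valid 0–40 °C,
with salinity dependence and a barometric rescale by
(P − p_H₂O)/(760 − p_H₂O). Water vapour pressure follows Green & Carritt
(1967). PO₂ of air-saturated water is (P − p_H₂O) · 0.2095. Defaults:
salinity 20 psu (mesohaline estuary), 760 mmHg; both explicit in config —
barometric pressure is per-trial configurable, with no weather lookup.
Sanity anchor: at 28 °C / 760 mmHg, S_crit = 0.26 corresponds to
P_crit ≈ 39.9 mmHg.

## Ventilation

Within a trial, mouth gape (mean of three replicate measurements) is
divided by the trial-minimum gape, multiplied by the window's ventilation
rate to give VRMG, and normalised to the trial maximum. VRMG is invariant
to the gape unit by construction. Observations on R²-rejected windows
still participate in the min/max normalisation (they are real gapes and
rates) but are excluded from fits.

The plateau fit is a continuous two-segment linear model of log MO₂
(natural log; the base only rescales slopes) on normalised VRMG:
breakpoint by grid search at 0.01 resolution over interior candidates with
at least two observations on each side, ties toward the smaller
breakpoint. It is reported only for trials where ≥30 % of measurement
windows carry a complete ventilation observation. The per-trial OLS slope
is reported alongside; mixed-effects modelling across individuals is
deliberately out of scope.

## The simulator

The simulated fish enters the chamber at MMR and relaxes exponentially to
SMR with time constant τ (EPOC decay); below its true C_crit it becomes a
linear oxyconformer (MO₂ scaled by O₂/C_crit through the origin). Chamber
O₂ integrates the fish + microbial sinks by explicit Euler at 1 s —
adequate because sink rates change slowly relative to the step, and exact
for constant sinks — and relaxes exponentially toward the reservoir during
flushes (mixing constant 60 s; the apparatus gives none, this is a
plausible chamber turnover). The microbial blank drifts linearly between
the pre- and post-trial slopes, matching the correction model so the
correction is exact in the noiseless limit. Independent Gaussian sensor
noise (default sd 0.01 mg l⁻¹, an optical-sensor figure chosen so that
clean windows — including the slowest oxyconforming ones — sit at R² ≥ 0.9)
is added per sample; chamber O₂ is floored at 0 with a logged warning. All
randomness flows from one integer seed through named sub-streams (trace
noise, ventilation noise, dropout), so identical seeds give bit-identical
trials.

Default study conditions: treatments 24 / 28 / 32 °C with
SMR 100 / 132 / 169 and MMR 250 / 287.5 / 385 mg kg⁻¹ h⁻¹ (the reported
percent contrasts applied to a base consistent with the reported raw
magnitudes), true C_crit 1.7 / 1.9 / 2.4 mg l⁻¹, fish 5 kg / 95 cm in a
110 l chamber, 20 h of normoxia, blanks −0.02 and −0.04 mg l⁻¹ h⁻¹, and a
stepwise ramp 80→12 % saturation (two cycles per step, spaced tighter near
the critical region). Night-time (diel) SMR modulation exists as an
optional multiplicative factor, default off. Mortality is metadata
supplied by the caller — the pipeline never infers death from a trace.

**EPOC decay constant.** Default τ = 2.0 h, a typical post-exhaustive-
exercise decay scale that genuinely plateaus within the 20 h normoxic
phase — the regime the lowest-decile SMR definition assumes. The observed
mean recovery of ~13.7 h corresponds to much slower decay; for studies of
that regime, `studies.calibrate_tau_for_recovery` root-finds the τ whose
*noiseless pipeline* band-entry time equals a target. The calibration is
deliberately defined through the pipeline's own band (estimated SMR + 10 %
of estimated AS): with slow decay the lowest-decile SMR sits above the
true asymptote, and the band-entry definition absorbs that operational
bias exactly as the measured quantity does. (Equivalently: with slow decay
the pipeline overestimates SMR and underestimates recovery time relative
to the true asymptote — a limitation inherent to measuring SMR after,
rather than before, the chase.)

**Ventilation model.** Ventilation rate VR = VR₀·(demand/SMR)^a·
(C_sat/O₂)^γ and mouth gape MG = MG₀·(1 + g·(demand−SMR)/AS)·(C_sat/O₂)^δ
with multiplicative log-normal noise, where *demand* is the decay
component without the oxyconforming collapse: ventilatory drive follows
oxygen demand, so below C_crit the fish keeps ventilating hard while its
achieved uptake falls — reproducing the observed decoupling of VRMG from
MO₂ under severe hypoxia. Driving effort with realised MO₂ instead would
make VRMG collapse alongside MO₂ and no decoupling could occur. The
effort exponents (a = 2.5, g = 4.0) are calibrated once so the generator
produces the plateau signature (high-VRMG slope < 25 % of the low-VRMG
slope) in ≥80 % of seeded trials; γ = 0.7, δ = 0.3 give ~3–4× hyper-
ventilation at the deepest ramp steps. Each window is independently
unobserved with probability 0.4 (fish off-camera).

## What the simulator does and does not emulate

It reproduces the trial *structure* — cycle timing, blank drift, sensor
noise, EPOC decay, oxyconforming collapse, ventilation dropout — so
passing tests demonstrate that the estimators recover known parameters
under that structure. It does not emulate: spontaneous activity bursts or
diel behaviour (beyond the optional factor), temperature control error,
probe drift or fouling, chamber mixing heterogeneity, individual variation
in the decay shape (single-exponential only), or mortality events. Real
traces violate these idealisations, so recovery errors measured here are
lower bounds on field performance.

## Problem sizes

The default verification sizes are desk-scale by design: parameter
recovery uses 200 seeded trials per treatment (the analysis driver uses
50), printed-value recovery uses medians over 20 seeds per target, the
plateau study 100 observation sets, the slope-CI study 1000 replicates.
At these sizes the full test suite and the acceptance script each complete
in about a minute on one CPU.

## Known limitations

* SMR after exhaustive exercise: with slow EPOC decay the lowest-decile
  SMR overestimates the true asymptote and shortens measured recovery
  (see above); the pipeline surfaces this rather than correcting for it.
* The C_crit regression inherits the 2–11-point convention; how runs
  longer than 11 should be handled is not specified by the protocol, and
  truncation to the lowest-O₂ 11 points is this package's choice.
* Treatment summaries are descriptive (means, sd, n, percent changes);
  no repeated-measures correlation structure, degrees-of-freedom
  machinery or bootstrap uncertainty is fitted.
* The ventilation pairing rule (normalise on all complete observations,
  fit on accepted-window pairs only) is a design choice; the alternative
  (normalise on accepted windows only) changes normalised VRMG when the
  extreme-gape window happens to be R²-rejected.
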