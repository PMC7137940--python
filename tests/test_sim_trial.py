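"""Simulator: schedules, the true metabolic-rate model, traces, ventilation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobia_resp.config import ScheduleConfig, default_config
from cobia_resp.hypoxia_metrics import WaterContext, o2_saturation_concentration
from cobia_resp.sim_trial import (
    FishSpec,
    ScheduleError,
    SimTruth,
    TrialSchedule,
    make_schedule,
    simulate_trace,
    simulate_trial,
    simulate_ventilation,
    true_mo2,
)


def make_truth(**kw):
    base = dict(
        smr_true=100.0,
        mmr_true=250.0,
        tau_h=2.0,
        ccrit_true=1.7,
        blank_slope_pre=-0.02,
        blank_slope_post=-0.04,
    )
    base.update(kw)
    return SimTruth(**base)


class TestSchedule:
    def test_cycle_counts_match_durations(self):
        sched = make_schedule(
            ScheduleConfig(flush_min=10, measure_min=5, equil_min=1,
                           normoxia_h=20,
                           hypoxia_setpoints_pct=(80, 60, 40, 30, 20, 10),
                           cycles_per_step=3)
        )
        recs = sched.recording_phases()
        # 20 h / 15 min cycles = 80 normoxic; 6 steps x 3 cycles hypoxic
        assert len(recs) == 80 + 18
        assert len(sched.hypoxia_steps) == 6
        # hypoxia starts only after the normoxic phase
        assert sched.hypoxia_steps[0][1] >= recs[79][1]

    def test_phases_contiguous_and_blanks_flank_trial(self):
        sched = make_schedule(ScheduleConfig())
        kinds = [p[0] for p in sched.phases]
        assert kinds[0] == "pre_blank" and kinds[-1] == "post_blank"
        starts = [p[1] for p in sched.phases]
        ends = [p[2] for p in sched.phases]
        assert all(s == e for s, e in zip(starts[1:], ends[:-1]))
        # recording always directly preceded by equilibration
        for i, k in enumerate(kinds):
            if k == "recording":
                assert kinds[i - 1] == "equilibration"

    @pytest.mark.parametrize(
        "bad",
        [
            dict(blank_h=2.0),                      # blanks must be >= 3 h
            dict(flush_min=20.0),                   # flush outside 7-15 min
            dict(measure_min=3.0),                  # measurement outside 4-7
            dict(hypoxia_setpoints_pct=(80, 80, 40)),   # non-decreasing
            dict(hypoxia_setpoints_pct=(40, 60)),       # increasing
        ],
    )
    def test_rejects_out_of_range_schedules(self, bad):
        with pytest.raises(ScheduleError):
            make_schedule(ScheduleConfig(**bad))

    def test_setpoint_timeline(self):
        sched = make_schedule(ScheduleConfig())
        assert sched.setpoint_frac(0) == 1.0
        first_pct, first_start = sched.hypoxia_steps[0]
        assert sched.setpoint_frac(first_start) == first_pct / 100.0


class TestTrueMo2:
    def test_limits_and_conforming_line(self):
        truth = make_truth()
        assert true_mo2(0.0, 8.0, truth) == pytest.approx(truth.mmr_true)
        assert true_mo2(1e9, 8.0, truth) == pytest.approx(truth.smr_true)
        # below C_crit at large t: linear through the origin
        assert true_mo2(1e9, truth.ccrit_true / 2, truth) == pytest.approx(
            truth.smr_true / 2
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        t1=st.floats(0, 1e5),
        dt=st.floats(0, 1e5),
        o2=st.floats(1.7, 8.0),
    )
    def test_non_increasing_in_time_under_normoxia(self, t1, dt, o2):
        truth = make_truth()
        assert true_mo2(t1 + dt, o2, truth) <= true_mo2(t1, o2, truth) + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        o2a=st.floats(0.0, 1.7),
        do2=st.floats(0.0, 1.7),
        t=st.floats(0, 1e5),
    )
    def test_non_decreasing_in_o2_below_ccrit(self, o2a, do2, t):
        truth = make_truth()
        hi = min(o2a + do2, truth.ccrit_true)
        assert true_mo2(t, hi, truth) >= true_mo2(t, o2a, truth) - 1e-12

    def test_truth_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_truth(smr_true=300.0)     # SMR above MMR
        with pytest.raises(ValueError):
            make_truth(tau_h=0.0)
        with pytest.raises(ValueError):
            make_truth(ccrit_true=-1.0)


class TestFishSpec:
    def test_displacement_rule(self):
        fish = FishSpec(5.0, 95.0, 24.0, 110.0)
        assert fish.effective_volume_l == pytest.approx(105.0)

    def test_fish_must_fit_in_chamber(self):
        with pytest.raises(ValueError):
            FishSpec(120.0, 95.0, 24.0, 110.0)


class TestSimulateTrace:
    def test_seed_determinism(self, cfg):
        a = simulate_trial(cfg, 24.0, seed=7)
        b = simulate_trial(cfg, 24.0, seed=7)
        pd.testing.assert_frame_equal(a.trace, b.trace)
        pd.testing.assert_frame_equal(a.ventilation, b.ventilation)
        c = simulate_trial(cfg, 24.0, seed=8)
        assert not a.trace["chamber_o2_mgL"].equals(c.trace["chamber_o2_mgL"])

    def test_constant_sink_gives_exactly_linear_decline(self):
        # no EPOC (SMR == MMR), constant blank: the Euler integrator is exact
        truth = make_truth(mmr_true=100.0 + 1e-9, blank_slope_post=-0.02)
        sched = make_schedule(ScheduleConfig(normoxia_h=2.0))
        fish = FishSpec(5.0, 95.0, 24.0, 110.0)
        trace, events = simulate_trace(fish, truth, sched, noise_sd=0.0, seed=0)
        rec = sched.recording_phases()[4]
        t = trace["time_s"].to_numpy()
        sel = (t >= rec[1]) & (t < rec[2])
        o2 = trace.loc[sel, "chamber_o2_mgL"].to_numpy()
        diffs = np.diff(o2)
        expected = -(100.0 * 5.0 / 105.0 + 0.02) / 3600.0
        assert np.allclose(diffs, expected, rtol=1e-6, atol=1e-12)

    def test_pre_blank_drop_matches_blank_rate(self):
        truth = make_truth(blank_slope_pre=-0.05, blank_slope_post=-0.05)
        sched = make_schedule(ScheduleConfig(normoxia_h=1.0))
        fish = FishSpec(5.0, 95.0, 24.0, 110.0)
        trace, _ = simulate_trace(fish, truth, sched, noise_sd=0.0, seed=0)
        t = trace["time_s"].to_numpy()
        o2 = trace["chamber_o2_mgL"].to_numpy()
        i0 = np.searchsorted(t, -3600)
        i1 = np.searchsorted(t, 0)
        assert o2[i0] - o2[i1] == pytest.approx(0.05, rel=1e-3)

    def test_mass_balance_window_drop_equals_integrated_sinks(
        self, trial24_noiseless
    ):
        """Noiseless per-window O2 drop == sum of per-second sink terms."""
        tr = trial24_noiseless
        t = tr.trace["time_s"].to_numpy()
        o2 = tr.trace["chamber_o2_mgL"].to_numpy()
        v_eff = tr.fish.effective_volume_l
        w = tr.fish.mass_kg
        span = tr.schedule.trial_end_s
        recs = tr.schedule.recording_phases()
        for start, end in [(r[1], r[2]) for r in (recs[0], recs[50], recs[-1])]:
            i0, i1 = np.searchsorted(t, [start, end])
            drop = o2[i0] - o2[i1]
            tt = t[i0:i1].astype(float)
            cc = o2[i0:i1]
            m = true_mo2(tt, cc, tr.truth)
            frac = np.clip(tt / span, 0, 1)
            bl = np.abs(
                tr.truth.blank_slope_pre
                + frac * (tr.truth.blank_slope_post - tr.truth.blank_slope_pre)
            )
            sinks = (m * w / v_eff + bl) / 3600.0
            assert drop == pytest.approx(float(sinks.sum()), abs=1e-9)

    def test_overaggressive_ramp_floors_at_zero(self):
        truth = make_truth(ccrit_true=0.05)   # fish consumes through the floor
        sched = make_schedule(
            ScheduleConfig(normoxia_h=1.0, hypoxia_setpoints_pct=(1.0,),
                           cycles_per_step=2)
        )
        fish = FishSpec(9.8, 108.0, 24.0, 110.0)
        trace, _ = simulate_trace(fish, truth, sched, noise_sd=0.0, seed=0)
        assert trace["chamber_o2_mgL"].min() == 0.0


class TestSimulateVentilation:
    def _flat_setup(self, o2_frac=1.0):
        """One recording window with demand == SMR and constant O2."""
        truth = make_truth(tau_h=1e-4)   # EPOC fully decayed by mid-window
        sched = TrialSchedule(
            phases=[("equilibration", 0, 60), ("recording", 60, 300)],
            hypoxia_steps=[],
        )
        ctx = WaterContext(24.0, 20.0, 760.0)
        c_sat = o2_saturation_concentration(ctx)
        trace = pd.DataFrame(
            {
                "time_s": np.arange(0, 300),
                "chamber_o2_mgL": np.full(300, o2_frac * c_sat),
                "reservoir_o2_mgL": np.full(300, c_sat),
                "temp_C": np.full(300, 24.0),
            }
        )
        return truth, sched, trace, ctx

    def test_baseline_rates_at_smr(self):
        truth, sched, trace, ctx = self._flat_setup()
        obs = simulate_ventilation(
            truth, sched, trace, dropout_p=0.0, seed=1, ctx=ctx,
            vr0=40.0, mg0=3.0, hypoxia_exp_gamma=0.0, hypoxia_exp_delta=0.0,
            lognorm_sd=0.0, gape_rep_sd=0.0,
        )
        assert obs["ventilation_rate"].iloc[0] == pytest.approx(40.0)
        assert obs["gape_rep1_cm"].iloc[0] == pytest.approx(3.0)

    def test_hyperventilation_power_law(self):
        truth, sched, trace_full, ctx = self._flat_setup(1.0)
        _, _, trace_half, _ = self._flat_setup(0.5)
        kw = dict(dropout_p=0.0, seed=1, ctx=ctx, vr0=40.0, mg0=3.0,
                  hypoxia_exp_gamma=1.0, hypoxia_exp_delta=0.0,
                  lognorm_sd=0.0, gape_rep_sd=0.0)
        vr_full = simulate_ventilation(truth, sched, trace_full, **kw)
        vr_half = simulate_ventilation(truth, sched, trace_half, **kw)
        assert vr_half["ventilation_rate"].iloc[0] == pytest.approx(
            2.0 * vr_full["ventilation_rate"].iloc[0]
        )

    def test_dropout_count_matches_seeded_bernoulli_draws(self, trial24):
        """The observed-window count equals the generator's own coin flips."""
        tr = trial24
        seed = 977
        obs = simulate_ventilation(
            tr.truth, tr.schedule, tr.trace, dropout_p=0.3, seed=seed,
            ctx=tr.ctx,
        )
        n_windows = len(tr.schedule.recording_phases())
        drop_ss = np.random.SeedSequence(seed).spawn(2)[1]
        expected = int(
            (np.random.default_rng(drop_ss).random(n_windows) >= 0.3).sum()
        )
        assert int(obs["ventilation_rate"].notna().sum()) == expected

    def test_dropout_probability_validated(self, trial24):
        with pytest.raises(ValueError):
            simulate_ventilation(
                trial24.truth, trial24.schedule, trial24.trace,
                dropout_p=1.0, seed=1, ctx=trial24.ctx,
            )
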