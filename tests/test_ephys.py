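"""Capacitance landmarks, pool decomposition, QC taxonomy, AP analysis."""

import numpy as np
import pytest

from conftest import make_capacitance_trace, staircase_cm
from ecphys.ephys import (
    Landmarks,
    PulseProtocol,
    QCThresholds,
    detect_spikes,
    landmark_deltas,
    pool_decomposition,
    potentiation_delta,
    qc_classify,
)
from ecphys.sim import PoolSimConfig, simulate_capacitance, simulate_voltage_trace
from ecphys.traces import TraceError


class TestLandmarks:
    def test_flat_trace_zero_everywhere(self, pool10):
        rec = make_capacitance_trace(pool10, lambda t: np.full_like(t, 10800.0))
        assert landmark_deltas(rec, pool10) == Landmarks(0.0, 0.0, 0.0)

    def test_staircase_short_pulses_sum_exactly(self, pool10):
        """+2 fF after each of 6 short pulses and nothing else: (12, 12, 12)."""
        rec = make_capacitance_trace(pool10, staircase_cm(pool10, 2.0, only_short=True))
        lm = landmark_deltas(rec, pool10)
        assert abs(lm.after_short - 12.0) < 1e-9
        assert abs(lm.after_train - 12.0) < 1e-9
        assert abs(lm.total - 12.0) < 1e-9

    def test_windows_never_cross_pulses(self, pool10):
        # corrupting Cm immediately after the next pulse must not leak into
        # the previous pulse's window
        def fn(times):
            cm = np.full_like(times, 10800.0)
            p7 = pool10.pulses[6]
            cm[times >= p7.end] += 1000.0
            return cm
        rec = make_capacitance_trace(pool10, fn)
        lm = landmark_deltas(rec, pool10)
        assert lm.after_short == pytest.approx(0.0, abs=1e-9)

    def test_pulse_count_mismatch_raises(self, pool10):
        rec = make_capacitance_trace(pool10, lambda t: np.full_like(t, 10800.0))
        with pytest.raises(TraceError, match="pulses"):
            landmark_deltas(rec, PulseProtocol.potentiation15())

    def test_empty_window_named(self, pool10):
        rec = make_capacitance_trace(
            pool10, lambda t: np.full_like(t, 10800.0), sample_interval=10.0
        )
        # drop all pre-train samples
        keep = rec.time >= pool10.pulses[0].start
        from ecphys.traces import CapacitanceRecording
        rec2 = CapacitanceRecording(
            rec.cell_id, rec.time[keep], rec.cm[keep], rec.pulses, rec.cm0
        )
        with pytest.raises(TraceError, match="pre-train reference"):
            landmark_deltas(rec2, pool10)

    def test_noiseless_sim_matches_geometric_oracle(self, pool10):
        cfg = PoolSimConfig(
            irp_size=10.0, rrp_size=50.0, release_fraction_short=0.25,
            release_fraction_long=0.6, noise_sd=0.0, seed=0,
        )
        rec, _ = simulate_capacitance(cfg, pool10)
        lm = landmark_deltas(rec, pool10)
        exp_short = 10.0 * (1 - 0.75**6)
        exp_train = 10.0 + 50.0 * (1 - 0.4**4)
        assert abs(lm.after_short - exp_short) < 0.1
        assert abs(lm.after_train - exp_train) < 0.1


class TestPoolDecomposition:
    def test_normalization_and_incremental_default(self):
        est = pool_decomposition(Landmarks(12.0, 12.0, 12.0), cm0=12.0)
        assert est.irp_ff == 12.0 and est.irp_ff_per_pf == pytest.approx(1.0)
        assert est.rrp_ff == 0.0  # incremental: nothing beyond the IRP

    def test_fig_scale_arithmetic(self):
        est = pool_decomposition(Landmarks(3.5, 94.5, 240.0), cm0=10.8)
        assert est.rrp_ff == pytest.approx(91.0)
        assert est.total_ff == pytest.approx(240.0)

    def test_convention_toggle_differs_by_exactly_irp(self):
        lm = Landmarks(3.5, 94.5, 240.0)
        inc = pool_decomposition(lm, 10.8, convention="incremental")
        cum = pool_decomposition(lm, 10.8, convention="cumulative")
        assert cum.rrp_ff - inc.rrp_ff == pytest.approx(inc.irp_ff)

    def test_monotone_trace_ordering(self, pool10):
        cfg = PoolSimConfig(noise_sd=0.0, sustained_rate=20.0, seed=0)
        rec, _ = simulate_capacitance(cfg, pool10)
        lm = landmark_deltas(rec, pool10)
        assert 0 <= lm.after_short <= lm.after_train <= lm.total


class TestQCTaxonomy:
    def test_flat_cm_with_robust_currents_is_no_exocytosis(self, pool10):
        rng = np.random.default_rng(5)
        rec = make_capacitance_trace(
            pool10,
            lambda t: 10800.0 + 0.5 * rng.standard_normal(t.shape),
            peak_current=-150.0,
        )
        assert qc_classify(rec, pool10) == "no_exocytosis"

    def test_pulse_uncorrelated_random_walk_is_spontaneous(self, pool10):
        rng = np.random.default_rng(17)

        def fn(times):
            t0 = pool10.pulses[0].start
            noise = 0.3 * rng.standard_normal(times.shape)
            walk = np.where(times > t0, 1, 0) * np.cumsum(
                3.0 * rng.standard_normal(times.shape) * (times > t0)
            )
            return 10800.0 + noise + walk

        rec = make_capacitance_trace(pool10, fn, peak_current=-150.0)
        assert qc_classify(rec, pool10) == "spontaneous"

    def test_pulse_locked_staircase_is_provoked(self, pool10):
        rec = make_capacitance_trace(pool10, staircase_cm(pool10, 10.0))
        assert qc_classify(rec, pool10) == "provoked"

    def test_unstable_flag_wins(self, pool10):
        rec = make_capacitance_trace(pool10, staircase_cm(pool10, 10.0))
        assert qc_classify(rec, pool10, unstable=True) == "unstable"

    def test_missing_currents_raise(self, pool10):
        rec, _ = simulate_capacitance(PoolSimConfig(seed=0), pool10)
        from ecphys.traces import CapacitanceRecording, Pulse
        naked = CapacitanceRecording(
            rec.cell_id, rec.time, rec.cm,
            tuple(Pulse(p.start, p.duration, p.v_from, p.v_to) for p in rec.pulses),
            rec.cm0,
        )
        with pytest.raises(TraceError, match="current"):
            qc_classify(naked, pool10)


class TestPotentiation:
    def test_flat_zero(self):
        prot = PulseProtocol.potentiation15()
        rec = make_capacitance_trace(prot, lambda t: np.full_like(t, 10800.0))
        delta, per_pf = potentiation_delta(rec, prot)
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_staircase_sums_all_15_pulses(self):
        prot = PulseProtocol.potentiation15()
        rec = make_capacitance_trace(prot, staircase_cm(prot, 10.0))
        delta, per_pf = potentiation_delta(rec, prot)
        assert delta == pytest.approx(150.0, abs=1e-9)
        assert per_pf == pytest.approx(150.0 / 10.8)

    def test_condition_multiplier_preserved(self):
        """A 2.75x potentiation of per-pulse release scales the train delta 2.75x."""
        prot = PulseProtocol.potentiation15()
        base_step = 121.0 / 15.0
        rec_ctl = make_capacitance_trace(prot, staircase_cm(prot, base_step))
        rec_fi = make_capacitance_trace(prot, staircase_cm(prot, base_step * 2.75))
        d_ctl, _ = potentiation_delta(rec_ctl, prot)
        d_fi, _ = potentiation_delta(rec_fi, prot)
        assert d_ctl == pytest.approx(121.0)
        assert d_fi == pytest.approx(d_ctl * 2.75)


class TestSpikes:
    def test_count_exact_on_noiseless_trace(self):
        vt = simulate_voltage_trace([100, 250, 400, 550, 700], duration=1000,
                                    step=(0.0, 1000.0, 30.0))
        assert detect_spikes(vt).spike_count == 5

    def test_subthreshold_depolarization_not_counted(self):
        vt = simulate_voltage_trace([200], duration=500, baseline=-40.0,
                                    threshold=-35.0, peak=-25.0)
        assert detect_spikes(vt, detection_level=-20.0).spike_count == 0

    def test_half_width_geometric_oracle(self):
        """Constructed half-width 19.1 ms recovered within one sample interval."""
        vt = simulate_voltage_trace([200], duration=500, half_width=19.1,
                                    sample_interval=0.1)
        s = detect_spikes(vt)
        assert s.half_width == pytest.approx(19.1, abs=0.1)
        assert s.threshold == pytest.approx(-23.5, abs=0.5)
        assert s.overshoot == pytest.approx(35.5, abs=0.1)

    def test_robust_to_moderate_noise_with_lockout(self):
        vt = simulate_voltage_trace([100, 300, 500, 700], duration=1000,
                                    noise_sd=2.0, seed=3)
        assert detect_spikes(vt).spike_count == 4

    def test_step_without_samples_errors(self):
        vt = simulate_voltage_trace([100], duration=300, step=(400.0, 500.0, 30.0))
        with pytest.raises(TraceError, match="no samples"):
            detect_spikes(vt)


class TestParameterRecovery:
    def test_median_error_within_noise_bound(self, pool10):
        """Noisy (5 fF) pool sims: median |error| within 2*noise/sqrt(n_window)."""
        errs_irp, errs_rrp = [], []
        for seed in range(40):
            cfg = PoolSimConfig(noise_sd=5.0, seed=seed)
            rec, truth = simulate_capacitance(cfg, pool10)
            lm = landmark_deltas(rec, pool10)
            errs_irp.append(lm.after_short - truth["released_after_shorts"])
            errs_rrp.append(lm.after_train - truth["released_after_train"])
        n_win = 30  # 300-ms window at 10-ms sampling
        bound = 2 * 5.0 / np.sqrt(n_win)
        assert np.median(np.abs(errs_irp)) < bound
        assert np.median(np.abs(errs_rrp)) < bound
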