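"""dF/F extraction, the three responsiveness criteria and trial tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vsnadapt import (
    AnalysisError,
    CellGroundTruth,
    StimulusEvent,
    TraceMatrix,
    build_block_protocol,
    build_decreasing_isi_protocol,
    classify_responsive,
    check_highK_response,
    compute_dff_trace,
    compute_trial_dff,
    confocal_response_table,
    extract_roi_traces,
    peak_amplitude,
    simulate_cell_trace,
)
from vsnadapt.imaging import DffTrace, flag_high_baseline_cells
from vsnadapt.protocols import StimulusProtocol


def _dff_trace(values, baseline_sd=1.0, f0=100.0):
    values = np.asarray(values, dtype=float)
    return DffTrace("c", np.arange(values.size, dtype=float),
                    (values - f0) / f0, f0, baseline_sd)


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        t = np.arange(30.0)
        d = compute_dff_trace(np.full(30, 100.0), t, (0, 10))
        assert np.allclose(d.dff, 0.0)
        assert d.baseline_mean == 100.0

    def test_step_arithmetic(self):
        t = np.arange(30.0)
        v = np.full(30, 100.0)
        v[15:] = 120.0
        d = compute_dff_trace(v, t, (0, 10))
        assert np.allclose(d.dff[15:], 0.2)

    def test_baseline_overlapping_stimulus_rejected(self):
        proto = build_decreasing_isi_protocol([60], 10, initial_rest=5.0)
        t = np.arange(100.0)
        with pytest.raises(AnalysisError):
            compute_dff_trace(np.full(100, 50.0), t, (0, 10), protocol=proto)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(AnalysisError):
            compute_dff_trace(np.zeros(10), t, (0, 5))

    def test_short_baseline_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(AnalysisError):
            compute_dff_trace(np.ones(10), t, (0, 2))

    @given(gain=st.floats(0.1, 50.0))
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(5)
        t = np.arange(60.0)
        v = 100.0 + rng.normal(0, 2, 60).cumsum() * 0.01 + 20 * (t > 30)
        a = compute_dff_trace(v, t, (0, 20))
        b = compute_dff_trace(gain * v, t, (0, 20))
        assert np.allclose(a.dff, b.dff, atol=1e-10)


class TestPeakAmplitude:
    def test_flat_trace_returns_zero(self):
        d = _dff_trace(np.full(50, 100.0))
        val, _ = peak_amplitude(d, (10, 30))
        assert val == 0.0

    def test_single_frame_peak(self):
        v = np.full(50, 100.0)
        v[20] = 180.0
        d = _dff_trace(v)
        val, when = peak_amplitude(d, (10, 30))
        assert val == pytest.approx(0.8)
        assert when == 20.0

    def test_empty_window_rejected(self):
        d = _dff_trace(np.full(50, 100.0))
        with pytest.raises(AnalysisError):
            peak_amplitude(d, (100, 120))


class TestResponsivenessCriteria:
    def _excursion(self, start, n_frames, size_sd=4.0, total=120):
        v = np.full(total, 100.0)
        v[start:start + n_frames] += size_sd  # baseline_sd = 1 raw unit
        return _dff_trace(v)

    def test_long_excursion_in_window_is_responsive(self):
        ev = StimulusEvent("urine", onset=50.0, duration=10.0)
        d = self._excursion(52, 5)
        assert classify_responsive(d, ev, highK_ok=True)

    def test_two_second_excursion_rejected(self):
        ev = StimulusEvent("urine", onset=50.0, duration=10.0)
        d = self._excursion(52, 2)
        assert not classify_responsive(d, ev, highK_ok=True)

    def test_highK_gate_vetoes(self):
        ev = StimulusEvent("urine", onset=50.0, duration=10.0)
        d = self._excursion(52, 5)
        assert not classify_responsive(d, ev, highK_ok=False)

    def test_crossing_must_begin_within_stimulus_window(self):
        ev = StimulusEvent("urine", onset=50.0, duration=10.0)
        late = self._excursion(75, 6)
        assert not classify_responsive(late, ev, highK_ok=True)

    def test_window_beyond_recording_rejected(self):
        ev = StimulusEvent("urine", onset=115.0, duration=10.0)
        d = self._excursion(50, 5)
        with pytest.raises(AnalysisError):
            classify_responsive(d, ev, highK_ok=True)

    def test_highK_check(self):
        ev = StimulusEvent("highK", onset=50.0, duration=10.0)
        big = self._excursion(52, 3, size_sd=10.0)
        assert check_highK_response(big, ev)
        flat = _dff_trace(np.full(120, 100.0))
        assert not check_highK_response(flat, ev)

    def test_missing_highK_event_rejected(self):
        d = _dff_trace(np.full(120, 100.0))
        with pytest.raises(AnalysisError):
            check_highK_response(d, None)

    def test_false_positive_rate_on_pure_noise(self):
        # criterion calibration: <= 1 % of pure-noise traces may pass
        rng = np.random.default_rng(99)
        ev = StimulusEvent("urine", onset=50.0, duration=10.0)
        hits = 0
        n = 1000
        for _ in range(n):
            v = 100.0 + rng.normal(0, 1.0, 120)
            d = compute_dff_trace(v, np.arange(120.0), (35, 45))
            hits += classify_responsive(d, ev, highK_ok=True)
        assert hits / n <= 0.01


class TestTrialDff:
    def _matrix(self, protocol, values):
        return TraceMatrix(["c1"], protocol.frame_times(), values)

    def test_amplitude_arithmetic(self):
        proto = build_block_protocol("accelerating", [60, 30], trials_per_ligand=1,
                                     stim_duration=15, initial_rest=30.0)
        t = proto.frame_times()
        v = np.full((1, t.size), 100.0)
        ev = proto.events[0]
        during = (t >= ev.onset) & (t < ev.offset)
        v[0, during] = 150.0
        table = compute_trial_dff(self._matrix(proto, v), proto)
        first = table[(table.stimulus == ev.stimulus_id) & (table.block == 1) &
                      (table.trial == 1)]
        assert first["dff"].iloc[0] == pytest.approx(0.5)

    def test_null_trial_gives_zero(self):
        proto = build_block_protocol("accelerating", [60, 30], trials_per_ligand=1,
                                     stim_duration=15, initial_rest=30.0)
        t = proto.frame_times()
        v = np.full((1, t.size), 100.0)
        table = compute_trial_dff(self._matrix(proto, v), proto, sd_mult=3.0)
        assert np.allclose(table["dff"], 0.0)
        assert not table["responsive"].any()

    def test_insufficient_prestimulus_stacks_rejected(self):
        proto = build_block_protocol("accelerating", [60, 30], trials_per_ligand=1,
                                     stim_duration=15, initial_rest=3.0)
        t = proto.frame_times()
        v = np.full((1, t.size), 100.0)
        with pytest.raises(AnalysisError):
            compute_trial_dff(self._matrix(proto, v), proto)

    def test_noise_free_population_matches_kernel_oracle(self):
        # long ISIs so indicator tails have fully decayed before each baseline
        proto = build_block_protocol("accelerating", [120, 60], trials_per_ligand=3,
                                     stim_duration=15, initial_rest=60.0)
        truth = CellGroundTruth(
            "c", selectivity_class="both", short_term_depletion=0.3,
            recovery_tau=80.0, noise_sd=0.0, indicator_rise_tau=1.0,
            indicator_decay_tau=2.5,
        )
        trace, t = simulate_cell_trace(truth, proto, 0, ligands=("DCA", "CA"))
        tm = TraceMatrix(["c"], t, trace[None, :])
        table = compute_trial_dff(tm, proto)
        from vsnadapt.synthetic import expected_event_amplitudes

        amps = expected_event_amplitudes(truth, proto, ligands=("DCA", "CA"))
        # during-window kernel attenuation: stacks at 0, 3, 6 s after onset
        c = np.mean(1.0 - np.exp(-np.array([0.0, 3.0, 6.0]) / 1.0))
        got = table.sort_values(["block", "stimulus", "trial"])["dff"].to_numpy()
        want = (amps.sort_values(["block", "stimulus", "trial"])["amplitude"]
                .to_numpy() * c)
        assert np.allclose(got, want, atol=1e-6)


class TestRoiExtraction:
    def test_uniform_stack_constant_trace(self):
        stacks = np.full((4, 8, 8), 100.0)
        masks = np.zeros((8, 8), int)
        masks[2:4, 2:4] = 1
        tm = extract_roi_traces(stacks, masks)
        assert np.allclose(tm.values, 100.0)

    def test_missing_label_rejected(self):
        stacks = np.full((2, 8, 8), 1.0)
        masks = np.zeros((8, 8), int)
        masks[0, 0] = 1
        with pytest.raises(AnalysisError, match="3"):
            extract_roi_traces(stacks, masks, labels=[1, 3])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(AnalysisError):
            extract_roi_traces(np.zeros((2, 8, 8)), np.zeros((4, 4), int))


class TestConfocalTable:
    def test_normalized_ratio_recovers_ground_truth_depletion(self):
        proto = build_decreasing_isi_protocol(
            [180, 60, 30], 10, recovery_probe_isi=180, include_highK=True
        )
        truth = CellGroundTruth(
            "c", short_term_depletion=0.4, recovery_tau=100.0, noise_sd=0.0,
        )
        trace, t = simulate_cell_trace(truth, proto, 0)
        table = confocal_response_table(TraceMatrix(["c"], t, trace[None, :]), proto)
        urine = table[table.stimulus == "urine"].sort_values("trial")
        from vsnadapt.synthetic import expected_event_amplitudes

        amps = expected_event_amplitudes(truth, proto)
        want = amps[amps.stimulus == "urine"]["amplitude"].to_numpy()
        got = urine["dff"].to_numpy()
        # 5e-3: the 10-s re-baseline before a 30-s-ISI stimulus still holds
        # ~exp(-20/4) of the previous transient's tail
        assert np.allclose(got / got[0], want / want[0], atol=5e-3)
        assert urine["responsive"].all()

    def test_trace_csv_roundtrip(self, tmp_path):
        tm = TraceMatrix(["a", "b"], np.arange(5.0),
                         np.arange(10.0).reshape(2, 5) + 100.0)
        path = tmp_path / "traces.csv"
        tm.to_csv(path)
        back = TraceMatrix.from_csv(path)
        assert back.cell_ids == tm.cell_ids
        assert np.allclose(back.values, tm.values)


def test_spontaneously_active_cell_flagged():
    proto = build_decreasing_isi_protocol([60], 10, initial_rest=60.0)
    t = proto.frame_times()
    quiet = np.full(t.size, 100.0)
    active = quiet.copy()
    active[10:20] = 110.0  # 10-SD excursion well before any stimulus
    tm = TraceMatrix(["quiet", "active"], t,
                     np.vstack([quiet + np.random.default_rng(0).normal(0, 1, t.size),
                                active + np.random.default_rng(1).normal(0, 1, t.size)]))
    flagged = flag_high_baseline_cells(tm, proto, (30.0, 55.0))
    assert flagged == ["active"]
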