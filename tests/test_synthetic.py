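"""Generator ground truth: amplitude recursion, mixture rounding,
determinism, movie rendering and spike recordings."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vsnadapt import (
    CellGroundTruth,
    GeneratorConfig,
    SpikeGroundTruth,
    build_decreasing_isi_protocol,
    build_paired_pulse_protocol,
    paper_calibrated_preset,
    preset_protocol,
    simulate_cell_trace,
    simulate_population,
    simulate_spike_recording,
    simulate_stack_movie,
)
from vsnadapt.errors import GeneratorError
from vsnadapt.synthetic import (
    draw_population_truths,
    expected_event_amplitudes,
    largest_remainder_counts,
)


def _protocol(isis=(60.0, 60.0, 60.0), dur=10.0):
    return build_decreasing_isi_protocol(list(isis), dur, initial_rest=60.0)


def _peaks(truth, protocol):
    f, t = simulate_cell_trace(truth, protocol, seed=0)
    dff = f / truth.baseline_f0 - 1.0
    return [
        dff[(t >= ev.onset) & (t <= ev.offset + 20)].max()
        for ev in protocol.events
    ]


class TestAmplitudeRecursion:
    def test_no_adaptation_gives_equal_peaks(self):
        truth = CellGroundTruth("c", base_amplitude=1.0)
        peaks = _peaks(truth, _protocol())
        assert np.allclose(peaks, peaks[0], rtol=1e-6)

    def test_pure_depletion_halves_each_peak(self):
        # d = 0.5 with no recovery: peaks proportional to 1, 0.5, 0.25
        truth = CellGroundTruth(
            "c", short_term_depletion=0.5, recovery_tau=math.inf,
        )
        p = _peaks(truth, _protocol((60.0, 60.0)))
        assert np.allclose(np.array(p) / p[0], [1.0, 0.5, 0.25], atol=1e-6)

    def test_instant_recovery_restores_every_peak(self):
        truth = CellGroundTruth(
            "c", short_term_depletion=0.5, recovery_tau=1.0,
        )
        p = _peaks(truth, _protocol())
        assert np.all(np.abs(np.array(p) / p[0] - 1.0) < 0.01)

    @given(
        d=st.floats(0.0, 0.9),
        tau=st.floats(10.0, 500.0),
        slow=st.floats(0.0, 0.2),
    )
    def test_recursion_matches_independent_stepwise_oracle(self, d, tau, slow):
        protocol = _protocol((180.0, 60.0, 30.0))
        truth = CellGroundTruth(
            "c", short_term_depletion=d, recovery_tau=tau,
            slow_adaptation_rate=slow,
        )
        got = expected_event_amplitudes(truth, protocol)["amplitude"].to_numpy()
        # independent oracle: closed form A_k = A0 (1-slow)^(k-1) R_k
        expected = []
        r = 1.0
        prev_off = None
        for ev in protocol.events:
            if prev_off is not None:
                r = 1.0 - (1.0 - r) * math.exp(-(ev.onset - prev_off) / tau)
            k = len(expected) + 1
            expected.append((1.0 - slow) ** (k - 1) * r)
            r *= 1.0 - d
            prev_off = ev.offset
        assert np.allclose(got, expected, atol=1e-12)

    def test_unresponsive_cells_respond_only_to_highK(self):
        protocol = build_decreasing_isi_protocol([60], 10, include_highK=True)
        truth = CellGroundTruth("c", selectivity_class="unresponsive")
        amps = expected_event_amplitudes(truth, protocol)
        assert (amps.loc[amps.stimulus == "urine", "amplitude"] == 0).all()
        assert (amps.loc[amps.stimulus == "highK", "amplitude"] > 0).all()

    def test_ligand_selective_cells_ignore_other_ligand(self):
        protocol = preset_protocol("accelerating_bile")
        truth = CellGroundTruth("c", selectivity_class="ligandA_only")
        amps = expected_event_amplitudes(truth, protocol, ligands=("DCA", "CA"))
        assert (amps.loc[amps.stimulus == "CA", "amplitude"] == 0).all()
        assert (amps.loc[amps.stimulus == "DCA", "amplitude"] > 0).all()


class TestLargestRemainder:
    def test_adapter_split_is_exact(self):
        assert largest_remainder_counts([227 / 259, 32 / 259], 259) == [227, 32]

    def test_selectivity_split_is_exact(self):
        frac = [135 / 486, 136 / 486, 215 / 486]
        assert largest_remainder_counts(frac, 486) == [135, 136, 215]

    def test_single_cell_goes_to_argmax(self):
        assert largest_remainder_counts([0.2, 0.5, 0.3], 1) == [0, 1, 0]

    @given(
        n=st.integers(1, 500),
        weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
    )
    def test_counts_sum_to_n(self, n, weights):
        fr = np.array(weights) / np.sum(weights)
        counts = largest_remainder_counts(fr, n)
        assert sum(counts) == n
        assert all(c >= 0 for c in counts)


class TestPopulation:
    def test_determinism_bit_identical(self):
        config = paper_calibrated_preset("decreasing_isi_urine")
        config = type(config)(**{**config.__dict__, "seed": 7, "n_cells": 12})
        protocol = _protocol()
        a, ta = simulate_population(config, protocol)
        b, tb = simulate_population(config, protocol)
        assert np.array_equal(a.values, b.values)
        assert ta.equals(tb)

    def test_adding_cells_preserves_existing_traces(self):
        # homogeneous mixture: growing the population must not perturb the
        # per-cell random substreams of existing cells (class labels follow
        # deterministic rounding and may legitimately shift with n)
        base = paper_calibrated_preset("decreasing_isi_urine")
        common = {**base.__dict__, "adapter_fraction": 1.0}
        small = type(base)(**{**common, "seed": 3, "n_cells": 5})
        big = type(base)(**{**common, "seed": 3, "n_cells": 8})
        protocol = _protocol()
        a, _ = simulate_population(small, protocol)
        b, _ = simulate_population(big, protocol)
        assert np.array_equal(a.values, b.values[:5])

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(GeneratorError):
            GeneratorConfig(n_cells=10, class_mixture={"both": 0.5})

    def test_preset_counts_match_mixture(self):
        config = paper_calibrated_preset("decreasing_isi_urine")
        truths = draw_population_truths(config)
        assert sum(t.is_adapter for t in truths) == 227
        assert len(truths) == 259

    def test_unknown_preset_rejected(self):
        with pytest.raises(GeneratorError):
            paper_calibrated_preset("nope")


class TestStackMovie:
    def test_roi_means_reproduce_traces(self):
        protocol = _protocol((60.0,))
        truths = draw_population_truths(
            GeneratorConfig(
                n_cells=5, class_mixture={"both": 1.0}, seed=11,
                common_params={"noise_sd": 0.0},
            )
        )
        stacks, masks = simulate_stack_movie(truths, protocol, seed=11)
        for i, truth in enumerate(truths):
            # noise-free, jitter-free traces are seed independent, so the
            # rendered ROI mean must equal the trace oracle exactly
            trace, _ = simulate_cell_trace(truth, protocol, 0)
            roi_mean = stacks[:, masks == i + 1].mean(axis=1)
            assert np.allclose(roi_mean, trace, atol=1e-9)
        # constant-background sanity: background pixels never change
        assert np.ptp(stacks[:, masks == 0], axis=0).max() == 0.0

    def test_single_noise_free_cell_exact(self):
        protocol = _protocol((60.0,))
        truth = CellGroundTruth("c", noise_sd=0.0)
        stacks, masks = simulate_stack_movie([truth], protocol, seed=0)
        trace, _ = simulate_cell_trace(truth, protocol, 0)
        # disk pixels carry exactly the simulated trace (no noise, but the
        # movie consumes its own per-cell stream; compare via that stream)
        roi = stacks[:, masks == 1]
        assert np.allclose(roi, roi[:, :1])  # uniform across the disk
        assert roi[:, 0].min() >= truth.baseline_f0  # responses only go up

    def test_zero_cells_gives_background_only(self):
        stacks, masks = simulate_stack_movie([], _protocol((60.0,)), seed=0)
        assert masks.max() == 0
        assert np.ptp(stacks) == 0.0

    def test_overcrowded_frame_raises(self):
        truths = [CellGroundTruth(f"c{i}") for i in range(200)]
        with pytest.raises(GeneratorError):
            simulate_stack_movie(truths, _protocol((60.0,)), frame_shape=(32, 32),
                                 seed=0, radius=4.0)


class TestSpikeRecording:
    def test_noise_free_template_count_matches_ground_truth(self):
        proto = build_paired_pulse_protocol([10.0], initial_rest=30.0)
        truth = SpikeGroundTruth(
            spontaneous_rate=2.0, recording_noise_sd=0.0,
        )
        _, current, spikes = simulate_spike_recording(truth, proto, 5000.0, seed=4)
        # count negative template peaks: crossings below half amplitude
        below = current < -0.5 * truth.spike_template_amplitude
        n_events = int(np.sum(np.diff(below.astype(int)) == 1))
        assert n_events == spikes.size

    def test_full_attenuation_silences_second_pulse_evoked_component(self):
        proto = build_paired_pulse_protocol([5.0], initial_rest=60.0)
        truth = SpikeGroundTruth(
            spontaneous_rate=0.0,
            paired_pulse_attenuation={5.0: 0.0},
            recording_noise_sd=0.0,
        )
        _, _, spikes = simulate_spike_recording(truth, proto, 5000.0, seed=1)
        p2 = proto.events[1]
        in_p2 = (spikes >= p2.onset) & (spikes < p2.offset)
        assert in_p2.sum() == 0  # no spontaneous rate, attenuation 0
        p1 = proto.events[0]
        assert ((spikes >= p1.onset) & (spikes < p1.offset)).sum() > 0

    def test_null_stimulus_indistinguishable_from_baseline(self):
        proto = build_paired_pulse_protocol([10.0], initial_rest=200.0)
        truth = SpikeGroundTruth(
            spontaneous_rate=5.0, evoked_rate=0.0, recording_noise_sd=0.0,
            paired_pulse_attenuation={10.0: 1.0},
        )
        _, _, spikes = simulate_spike_recording(truth, proto, 5000.0, seed=2)
        p1 = proto.events[0]
        rate_stim = ((spikes >= p1.onset) & (spikes < p1.offset)).sum() / p1.duration
        rate_base = (spikes < 200.0).sum() / 200.0
        assert abs(rate_stim - rate_base) < 3.0  # both ~5 Hz

    def test_dead_time_enforced(self):
        proto = build_paired_pulse_protocol([5.0], initial_rest=30.0)
        truth = SpikeGroundTruth(spontaneous_rate=20.0, burstiness=4.0)
        _, _, spikes = simulate_spike_recording(truth, proto, 5000.0, seed=3)
        assert np.diff(spikes).min() >= truth.refractory

    def test_determinism(self):
        proto = build_paired_pulse_protocol([5.0])
        truth = SpikeGroundTruth()
        a = simulate_spike_recording(truth, proto, 5000.0, seed=9)
        b = simulate_spike_recording(truth, proto, 5000.0, seed=9)
        assert np.array_equal(a[1], b[1]) and np.array_equal(a[2], b[2])
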