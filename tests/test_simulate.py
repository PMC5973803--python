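"""Generator correctness: Poisson statistics, determinism, protocol rules,
force traces, and up-down sequence behavior."""

import numpy as np
import pytest

import pbspike as pb


class TestSpikeTrainSampler:
    def test_zero_rate_gives_empty_train(self):
        prof = pb.NeuronProfile(baseline_rate=0.0, response_class="nonresponsive")
        tr = pb.simulate_spike_train(prof, [], duration=50.0, seed=1)
        assert tr.n_spikes == 0

    def test_homogeneous_count_matches_poisson_moments(self):
        """5 Hz for 100 s: counts within 500 +/- 3*sqrt(500) for >=99% of seeds."""
        prof = pb.NeuronProfile(baseline_rate=5.0)
        counts = np.array(
            [
                pb.simulate_spike_train(prof, [], 100.0, seed=s).n_spikes
                for s in range(1000)
            ]
        )
        inside = np.abs(counts - 500) <= 3 * np.sqrt(500)
        assert inside.mean() >= 0.99
        assert abs(counts.mean() - 500) < 3  # LLN on the mean too

    def test_evoked_rate_integral(self):
        """One 3 s stimulus at baseline+20 Hz: mean in-stimulus count ~ 3*25."""
        ev = [pb.StimulusEvent(10.0, 13.0, "thermal", "face_ipsi")]
        prof = pb.NeuronProfile(baseline_rate=5.0, evoked_gain=20.0)
        counts = []
        for s in range(400):
            tr = pb.simulate_spike_train(prof, ev, 30.0, seed=s)
            counts.append(
                np.count_nonzero((tr.spike_times >= 10) & (tr.spike_times < 13))
            )
        expected = 3 * 25
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)

    def test_identical_seed_identical_train(self):
        ev, dur = pb.build_events(pb.StimulusProtocol(), seed=4)
        prof = pb.NeuronProfile(baseline_rate=3.0, evoked_gain=30.0,
                                ad_duration=1.0, ad_rate=40.0)
        a = pb.simulate_spike_train(prof, ev, dur, seed=11)
        b = pb.simulate_spike_train(prof, ev, dur, seed=11)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_suppressed_profile_lowers_stimulus_rate(self):
        ev = [pb.StimulusEvent(10.0, 13.0, "thermal", "face_ipsi")]
        prof = pb.NeuronProfile(
            baseline_rate=10.0, response_class="suppressed",
            suppression_fraction=0.1,
        )
        n_stim = 0
        for s in range(200):
            tr = pb.simulate_spike_train(prof, ev, 30.0, seed=s)
            n_stim += np.count_nonzero(
                (tr.spike_times >= 10) & (tr.spike_times < 13)
            )
        # expect ~1 Hz * 3 s * 200 trials = 600 * 0.1
        assert n_stim / 200 == pytest.approx(3.0, rel=0.25)

    def test_exponential_ad_shape_decays(self):
        """Exponential-decay after-discharge: early post-offset counts
        exceed late ones, and the rate integral matches the closed form
        baseline*T + (peak-baseline)*tau*(1-exp(-T/tau))."""
        ev = [pb.StimulusEvent(10.0, 13.0, "thermal", "face_ipsi")]
        prof = pb.NeuronProfile(
            baseline_rate=2.0, evoked_gain=30.0, ad_duration=3.0,
            ad_rate=80.0, ad_shape="exponential",
        )
        early = late = 0
        for s in range(150):
            tr = pb.simulate_spike_train(prof, ev, 30.0, seed=s)
            early += np.count_nonzero((tr.spike_times >= 13.0) & (tr.spike_times < 14.0))
            late += np.count_nonzero((tr.spike_times >= 15.0) & (tr.spike_times < 16.0))
        tau = 3.0 / 3.0
        expected_early = 2.0 + (80.0 - 2.0) * tau * (1 - np.exp(-1 / tau))
        assert early / 150 == pytest.approx(expected_early, rel=0.1)
        assert late < early / 3

    def test_long_run_rate_converges(self):
        """LLN: empirical rate of a homogeneous segment approaches the truth."""
        prof = pb.NeuronProfile(baseline_rate=2.0)
        tr = pb.simulate_spike_train(prof, [], duration=5000.0, seed=3)
        assert tr.mean_rate() == pytest.approx(2.0, rel=0.05)


class TestPopulation:
    def test_zero_incidence_means_no_ground_truth_ad(self):
        spec = pb.PopulationSpec(n_neurons=10, ad_incidence=0.0)
        sess = pb.simulate_population(spec, pb.StimulusProtocol(), seed=5)
        truth = sess.metadata["ground_truth"]
        assert all(v["ad_duration"] == 0.0 for v in truth.values())

    def test_silent_fraction_one_gives_all_zero_baselines(self):
        spec = pb.PopulationSpec(n_neurons=8, silent_fraction=1.0)
        sess = pb.simulate_population(spec, pb.StimulusProtocol(), seed=5)
        truth = sess.metadata["ground_truth"]
        assert all(v["baseline_rate"] == 0.0 for v in truth.values())

    def test_ad_incidence_recovered_binomially(self):
        """Ground-truth AD-positive fraction matches the population
        incidence parameter within binomial error."""
        p = 0.512
        n, reps = 43, 120
        rng = np.random.default_rng(0)
        k = 0
        for _ in range(reps):
            spec = pb.PopulationSpec(n_neurons=n, ad_incidence=p)
            r = np.random.default_rng(int(rng.integers(2**31)))
            k += sum(pb.sample_profile(spec, r).ad_duration > 0 for _ in range(n))
        frac = k / (n * reps)
        se = np.sqrt(p * (1 - p) / (n * reps))
        assert abs(frac - p) < 4 * se

    def test_event_spacing_respects_minimum(self):
        sess = pb.simulate_population(
            pb.PopulationSpec(n_neurons=1), pb.StimulusProtocol(), seed=2
        )
        evs = sorted(sess.events, key=lambda e: e.onset)
        gaps = [b.onset - a.offset for a, b in zip(evs, evs[1:])]
        assert all(g >= 8.0 for g in gaps)

    def test_marginal_off_cell_fraction(self):
        spec = pb.preset_spec("cci_like", 43)
        rng = np.random.default_rng(1)
        draws = [pb.sample_profile(spec, rng) for _ in range(4000)]
        off = np.mean([p.response_class == "suppressed" for p in draws])
        assert off == pytest.approx(11 / 43, abs=0.03)
        ad = np.mean([p.ad_duration > 0 for p in draws])
        assert ad == pytest.approx(0.512, abs=0.03)


class TestForceTrace:
    def test_noiseless_trapezoid_closed_form_integral(self):
        trace = pb.simulate_force_trace(peak=10, duration=3.0, rise_time=0.5,
                                        sample_rate=1000.0, noise_sd=0.0)
        assert pb.force_integral(trace) == pytest.approx(25.0, rel=1e-3)

    def test_zero_peak_all_zero(self):
        trace = pb.simulate_force_trace(peak=0.0, duration=3.0, rise_time=0.5)
        assert np.all(trace[:, 1] == 0)

    def test_noisy_trace_reproducible_and_non_negative(self):
        a = pb.simulate_force_trace(10, 3.0, 0.5, noise_sd=1.0, seed=9)
        b = pb.simulate_force_trace(10, 3.0, 0.5, noise_sd=1.0, seed=9)
        assert np.array_equal(a, b)
        assert np.all(a[:, 1] >= 0)

    def test_negative_peak_rejected(self):
        with pytest.raises(pb.ValidationError):
            pb.simulate_force_trace(peak=-1, duration=3.0, rise_time=0.5)


class TestUpDownSequence:
    LADDER = pb.FACE_LADDER

    def test_step_function_threshold_brackets(self):
        """Near-infinite slope: the staircase alternates around threshold."""
        prof = pb.PsychometricProfile(threshold_50=3.0, slope=1000.0)
        seq = pb.simulate_updown_sequence(prof, self.LADDER, seed=0)
        forces = np.array([f for f, _ in seq])
        resp = np.array([r for _, r in seq])
        # every response is deterministic: respond iff force > threshold
        assert np.array_equal(resp, forces > 3.0)

    def test_threshold_below_ladder_pins_to_lowest(self):
        prof = pb.PsychometricProfile(threshold_50=0.001, slope=1000.0)
        seq = pb.simulate_updown_sequence(prof, self.LADDER, seed=0)
        assert all(r for _, r in seq)
        assert seq[-1][0] == self.LADDER[0]

    def test_start_index_out_of_range(self):
        prof = pb.PsychometricProfile(threshold_50=3.0)
        with pytest.raises(pb.ValidationError):
            pb.simulate_updown_sequence(prof, self.LADDER, start_index=99, seed=0)

    def test_sequence_lengths_in_expected_range(self):
        prof = pb.PsychometricProfile(threshold_50=3.0, slope=10.0)
        lengths = [
            len(pb.simulate_updown_sequence(prof, self.LADDER, seed=s))
            for s in range(100)
        ]
        assert all(2 <= n <= 12 for n in lengths)
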