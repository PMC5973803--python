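"""Response classification, after-discharge, suppression, and rebound."""

import numpy as np
import pytest
from scipy import stats as sps

import pbspike as pb

EV, DUR = pb.build_events(pb.StimulusProtocol(), seed=0)


def _psth(train, config):
    return pb.build_psth(train, EV, (5.0, 13.0), config)


class TestResponse:
    def test_flat_homogeneous_not_responsive(self, config):
        tr = pb.simulate_spike_train(pb.NeuronProfile(baseline_rate=4.0), EV, DUR, seed=1)
        responsive, sign = pb.detect_response(_psth(tr, config), config)
        assert (responsive, sign) == (False, "none")

    def test_all_zero_train_not_responsive(self, config):
        tr = pb.SpikeTrain("u", [], duration=DUR)
        assert pb.detect_response(_psth(tr, config), config) == (False, "none")

    def test_strong_excitation_detected_almost_always(self, config):
        """Evoked rate ~10 baseline-sd above baseline: detected in >=99%
        of 500 seeds."""
        prof = pb.NeuronProfile(baseline_rate=5.0, evoked_gain=70.0)
        hits = sum(
            pb.detect_response(
                _psth(pb.simulate_spike_train(prof, EV, DUR, seed=s), config), config
            )[0]
            for s in range(500)
        )
        assert hits >= 495


class TestAfterDischarge:
    def test_no_post_offset_elevation(self, config):
        tr = pb.simulate_spike_train(pb.NeuronProfile(baseline_rate=4.0), EV, DUR, seed=2)
        present, dur = pb.detect_after_discharge(_psth(tr, config), config)
        assert (present, dur) == (False, 0.0)

    def test_window_too_short_errors(self, config):
        tr = pb.SpikeTrain("u", [], duration=DUR)
        psth = pb.build_psth(tr, EV, (5.0, 6.0), config)
        with pytest.raises(pb.ValidationError, match="window"):
            pb.detect_after_discharge(psth, config)

    def test_rectangular_ad_duration_recovery(self, config):
        """Ground-truth 1.2 s rectangular AD at high SNR: recovered within
        one bin in >= 95% of 200 seeds."""
        prof = pb.NeuronProfile(
            baseline_rate=5.0, evoked_gain=70.0, ad_duration=1.2, ad_rate=75.0
        )
        ok = 0
        for s in range(200):
            tr = pb.simulate_spike_train(prof, EV, DUR, seed=s)
            _, dur = pb.detect_after_discharge(_psth(tr, config), config)
            ok += abs(dur - 1.2) <= 0.1 + 1e-9
        assert ok >= 190

    def test_sub_threshold_run_scores_zero(self, config):
        """A 0.3 s elevation (< 500 ms) must not count as an AD."""
        prof = pb.NeuronProfile(
            baseline_rate=5.0, evoked_gain=70.0, ad_duration=0.3, ad_rate=75.0
        )
        detected = 0
        for s in range(50):
            tr = pb.simulate_spike_train(prof, EV, DUR, seed=s)
            present, dur = pb.detect_after_discharge(_psth(tr, config), config)
            detected += present
            assert dur in (0.0,) or dur >= 0.5
        assert detected <= 2  # only chance runs extending past 0.5 s

    def test_recovery_bias_within_one_bin(self, config):
        """Mean bias of the estimated AD duration within +/- 1 bin across
        the duration grid at high SNR."""
        for true_dur in (0.5, 1.0, 2.0, 3.0):
            prof = pb.NeuronProfile(
                baseline_rate=5.0, evoked_gain=70.0, ad_duration=true_dur, ad_rate=75.0
            )
            est = []
            for s in range(60):
                tr = pb.simulate_spike_train(prof, EV, DUR, seed=s)
                est.append(pb.detect_after_discharge(_psth(tr, config), config)[1])
            assert abs(np.mean(est) - true_dur) <= 0.1


class TestSuppression:
    def test_identical_rates_not_suppressed(self, config):
        # same spike pattern relative to every onset: zero paired difference
        spikes = []
        for e in EV:
            spikes += list(e.onset + np.array([-4.5, -2.5, -0.5, 0.5, 1.5, 2.5]) )
        tr = pb.SpikeTrain("u", np.sort(spikes), duration=DUR)
        suppressed, p = pb.detect_suppression(tr, EV, config)
        assert not suppressed

    def test_paired_t_matches_closed_form(self, config):
        """Pre {10,11,9,10,10} Hz vs stim {2,3,2,2,1} Hz: t = 25.3, df = 4."""
        pre = np.array([10, 11, 9, 10, 10], dtype=float)
        stim = np.array([2, 3, 2, 2, 1], dtype=float)
        spikes = []
        for e, npre, nstim in zip(EV, (pre * 5).astype(int), (stim * 3).astype(int)):
            spikes += list(np.linspace(e.onset - 5, e.onset, npre, endpoint=False))
            spikes += list(np.linspace(e.onset, e.offset, nstim, endpoint=False))
        tr = pb.SpikeTrain("u", np.sort(spikes), duration=DUR)
        suppressed, p = pb.detect_suppression(tr, EV, config)
        d = pre - stim
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df=4)
        assert suppressed
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_elevated_stim_rate_never_labelled_suppressed(self, config):
        prof = pb.NeuronProfile(baseline_rate=3.0, evoked_gain=40.0)
        tr = pb.simulate_spike_train(prof, EV, DUR, seed=5)
        suppressed, p = pb.detect_suppression(tr, EV, config)
        assert not suppressed

    def test_too_few_trials_error(self, config):
        tr = pb.SpikeTrain("u", [], duration=DUR)
        with pytest.raises(pb.ValidationError, match="3 trials"):
            pb.detect_suppression(tr, EV[:2], config)

    def test_degenerate_variance_reports_p_zero(self, config):
        # constant nonzero difference across trials
        spikes = []
        for e in EV:
            spikes += list(np.linspace(e.onset - 5, e.onset, 25, endpoint=False))
        tr = pb.SpikeTrain("u", np.sort(spikes), duration=DUR)
        suppressed, p = pb.detect_suppression(tr, EV, config)
        assert suppressed and p == 0.0


class TestRebound:
    def test_suppressed_without_rebound(self, config):
        prof = pb.NeuronProfile(
            baseline_rate=8.0, response_class="suppressed", suppression_fraction=0.0
        )
        tr = pb.simulate_spike_train(prof, EV, DUR, seed=3)
        res = pb.classify_unit(tr, EV, config)
        assert res.response_sign == "suppressed"
        assert res.ad_duration == 0.0
        # no engineered rebound: chance runs are rare
        assert res.rebound_duration <= 0.2

    def test_rebound_duration_recovery(self, config):
        """3 s rebound burst at high SNR recovered within one bin in >=95%
        of 200 seeds (3 s matches the sham-group median duration)."""
        prof = pb.NeuronProfile(
            baseline_rate=8.0,
            response_class="suppressed",
            suppression_fraction=0.0,
            rebound_duration=3.0,
            rebound_rate=80.0,
        )
        ok = 0
        for s in range(200):
            tr = pb.simulate_spike_train(prof, EV, DUR, seed=s)
            res = pb.classify_unit(tr, EV, config)
            ok += (
                res.response_sign == "suppressed"
                and abs(res.rebound_duration - 3.0) <= 0.1 + 1e-9
            )
        assert ok >= 190

    def test_sub_bin_rebound_undetectable(self, config):
        prof = pb.NeuronProfile(
            baseline_rate=8.0,
            response_class="suppressed",
            suppression_fraction=0.0,
            rebound_duration=0.04,
            rebound_rate=20.0,
        )
        hits = 0
        for s in range(30):
            tr = pb.simulate_spike_train(prof, EV, DUR, seed=s)
            res = pb.classify_unit(tr, EV, config)
            hits += res.rebound_duration > 0.2
        assert hits <= 1


class TestClassification:
    def test_suppressed_units_never_score_ad(self, config):
        """Simulated OFF-cells with rebound must contribute ad_duration 0
        and be labelled suppressed, not excited."""
        prof = pb.NeuronProfile(
            baseline_rate=8.0,
            response_class="suppressed",
            suppression_fraction=0.05,
            rebound_duration=2.0,
            rebound_rate=60.0,
        )
        for s in range(30):
            tr = pb.simulate_spike_train(prof, EV, DUR, seed=s)
            res = pb.classify_unit(tr, EV, config)
            assert res.ad_duration == 0.0
            if res.response_sign == "suppressed":
                assert not res.ad_present

    def test_determinism(self, config):
        prof = pb.NeuronProfile(baseline_rate=4.0, evoked_gain=50.0, ad_duration=1.0,
                                ad_rate=60.0)
        tr = pb.simulate_spike_train(prof, EV, DUR, seed=9)
        a = pb.classify_unit(tr, EV, config)
        b = pb.classify_unit(tr, EV, config)
        assert a == b

    def test_session_table_covers_all_units(self, small_session, config):
        table = pb.detect_session(small_session, config)
        assert set(table["unit_id"]) == {u.unit_id for u in small_session.units}
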