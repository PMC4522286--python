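"""Generator/analyzer closure, presets, seeding and cohort construction."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from ffm import protocol as P, synthetic as S, tracking as T, taps as K
from ffm.errors import InvalidParameterError


class TestTrackingSimulation:
    def test_noiseless_trace_matches_target(self, tracking_protocol, noiseless_params):
        rec, _ = S.simulate_tracking(tracking_protocol, noiseless_params)
        trials = T.analyze_tracking(rec, tracking_protocol)
        assert max(t.rmse_ramp for t in trials) == pytest.approx(0.0, abs=1e-12)
        assert max(t.rmse_hold for t in trials) == pytest.approx(0.0, abs=1e-12)
        assert all(t.mean_hold_force == pytest.approx(t.target_force) for t in trials)
        assert all(t.cv_hold == pytest.approx(0.0, abs=1e-12) for t in trials)

    @pytest.mark.parametrize("tau", [0.05, 0.2, 1.0])
    def test_exponential_release_closed_form(self, tracking_protocol, noiseless_params, tau):
        params = replace(noiseless_params, release_tau=tau)
        rec, _ = S.simulate_tracking(tracking_protocol, params)
        trials = T.analyze_tracking(rec, tracking_protocol)
        durs = np.array([t.release_duration for t in trials])
        assert np.all(np.abs(durs - tau * np.log(3)) <= 0.010)

    def test_baseline_offset_recovered(self, tracking_protocol, noiseless_params):
        params = replace(noiseless_params, baseline_offset=0.28, release_tau=0.05)
        rec, _ = S.simulate_tracking(tracking_protocol, params)
        trials = T.analyze_tracking(rec, tracking_protocol)
        base = np.nanmean([t.baseline_force for t in trials])
        assert base == pytest.approx(0.28, abs=0.02)

    def test_lag_shifts_force_onset(self, tracking_protocol, noiseless_params):
        params = replace(noiseless_params, tracking_lag=0.15)
        rec, _ = S.simulate_tracking(tracking_protocol, params)
        trace = rec.channel("index")
        # 2 N trials only: their ramp slope exceeds the default 1 N/s criterion
        for trial in tracking_protocol.trials[12:15]:
            onset = T.detect_force_onset(
                rec.times, trace, trial.ramp_start, trial.hold_start
            )
            assert onset - trial.ramp_start == pytest.approx(0.15, abs=0.03)

    def test_non_lead_channels_scaled_by_enslaving(self, tracking_protocol, noiseless_params):
        E = np.eye(4)
        E[0, 1] = 0.3
        params = replace(noiseless_params, enslaving=E)
        rec, _ = S.simulate_tracking(tracking_protocol, params, finger="index")
        assert np.allclose(rec.channel("middle"), 0.3 * rec.channel("index"), atol=1e-9)


class TestTappingSimulation:
    def test_every_cue_produces_one_tap(self, single_tap_protocol, noiseless_params):
        rec, truth = S.simulate_tapping(single_tap_protocol, noiseless_params)
        # 15 cued + 15 self-paced taps per each of 12 conditions
        assert len(truth.taps) == 12 * 30
        events = K.detect_taps(rec)
        assert len(events) == len(truth.taps)

    def test_full_omission_empty_trace(self, single_tap_protocol, noiseless_params):
        params = replace(noiseless_params, omission_prob=1.0)
        rec, truth = S.simulate_tapping(single_tap_protocol, params)
        assert truth.taps == []
        assert np.max(np.abs(rec.samples)) < 1e-12

    def test_rate_ceiling_thins_fast_cues(self, noiseless_params):
        proto = P.build_single_tap_protocol([3.0], ["index"], 15)
        params = replace(noiseless_params, max_rate=1.5)
        _, truth = S.simulate_tapping(proto, params)
        times = np.array([e.time for e in truth.taps])
        assert np.all(np.diff(times) >= 1 / 1.5 - 1e-9)

    def test_enslaved_pulses_above_threshold_in_ground_truth(self, noiseless_params):
        proto = P.build_single_tap_protocol([1.0], ["ring"], 10)
        E = np.eye(4)
        E[2, 1] = 0.4  # ring -> middle, coupled peak 0.8 N
        params = replace(noiseless_params, enslaving=E)
        _, truth = S.simulate_tapping(proto, params)
        lead = [e for e in truth.taps if e.source == "cued"]
        coupled = [e for e in truth.taps if e.source == "enslaved"]
        assert len(coupled) == len(lead)
        assert all(e.finger == "middle" for e in coupled)
        assert all(e.amplitude == pytest.approx(0.8) for e in coupled)

    def test_seed_reproducibility(self, multi_tap_protocol):
        params = S.preset("paretic_like")
        rec_a, truth_a = S.simulate_tapping(multi_tap_protocol, replace(params, seed=11))
        rec_b, truth_b = S.simulate_tapping(multi_tap_protocol, replace(params, seed=11))
        rec_c, _ = S.simulate_tapping(multi_tap_protocol, replace(params, seed=12))
        assert np.array_equal(rec_a.samples, rec_b.samples)
        assert truth_a.taps == truth_b.taps
        assert not np.array_equal(rec_a.samples, rec_c.samples)


class TestPresets:
    def test_diagonal_is_one(self):
        for g in ("control_like", "paretic_like"):
            assert np.allclose(np.diag(preset_enslaving(g)), 1.0)

    def test_paretic_enslaving_decays_with_distance(self):
        E = preset_enslaving("paretic_like")
        for i, fi in enumerate(P.FINGERS):
            by_dist = {}
            for j, fj in enumerate(P.FINGERS):
                if i != j:
                    by_dist.setdefault(P.finger_distance(fi, fj), []).append(E[i, j])
            dists = sorted(by_dist)
            means = [np.mean(by_dist[d]) for d in dists]
            assert all(a >= b for a, b in zip(means, means[1:]))

    def test_rate_ceilings_bracket_3hz(self):
        assert S.preset("control_like").max_rate > 3.0
        assert S.preset("paretic_like").max_rate < 3.0

    def test_unknown_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            S.preset("typical")


def preset_enslaving(group):
    return S.preset(group).enslaving


class TestSimParams:
    def test_json_round_trip(self):
        p = S.preset("paretic_like")
        q = S.SimParams.from_json(p.to_json())
        assert np.allclose(q.enslaving, p.enslaving)
        assert q.release_tau == p.release_tau

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"omission_prob": 1.5},
            {"tap_width": 0.0},
            {"enslaving": np.zeros((4, 4))},
            {"tracking_noise_sd": -0.1},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            S.SimParams(**kwargs)


class TestCohort:
    def test_reproducible_under_seed(self):
        a = S.make_cohort(2, 2, seed=3, tasks=("tracking",))
        b = S.make_cohort(2, 2, seed=3, tasks=("tracking",))
        for sa, sb in zip(a, b):
            assert sa.severity == sb.severity
            assert np.array_equal(
                sa.recordings["tracking"][0].samples, sb.recordings["tracking"][0].samples
            )

    def test_empty_groups(self):
        assert S.make_cohort(0, 0, seed=1, tasks=()) == []
        only_patients = S.make_cohort(0, 3, seed=1, tasks=())
        assert all(s.group == "patient" for s in only_patients)

    def test_arat_declines_with_severity(self):
        cohort = S.make_cohort(12, 12, seed=5, tasks=())
        sev = [s.severity for s in cohort]
        arat = [s.clinical.arat_total for s in cohort]
        rho, _ = stats.spearmanr(sev, arat)
        assert rho < -0.5
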