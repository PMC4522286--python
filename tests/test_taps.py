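"""Tap detection and the sequence/single/multi scoring operations."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ffm import protocol as P, synthetic as S, taps as K
from ffm.io import ForceRecording
from ffm.protocol import FINGERS


def pulse_recording(events, duration, width=0.2, rate=100.0):
    samples = S.render_tap_events(
        [S.TruthTap(f, t, a) for f, t, a in events], duration, rate, width
    )
    return ForceRecording(samples, rate)


class TestDetection:
    def test_single_pulse(self):
        rec = pulse_recording([("index", 1.0, 2.0)], 3.0)
        (ev,) = K.detect_taps(rec)
        assert ev.finger == "index"
        assert ev.amplitude == pytest.approx(2.0, abs=0.01)
        assert ev.peak_time == pytest.approx(1.0, abs=0.01)
        assert ev.onset_time <= ev.peak_time

    def test_pulse_train_spacing(self):
        rec = pulse_recording([("middle", 1.0 + k, 2.0) for k in range(15)], 17.0)
        events = K.detect_taps(rec)
        assert len(events) == 15
        spacing = np.diff([e.peak_time for e in events])
        assert np.all(np.abs(spacing - 1.0) <= 0.01)

    def test_subthreshold_pulse_ignored(self):
        rec = pulse_recording([("ring", 1.0, 0.4)], 3.0)
        assert K.detect_taps(rec) == []

    def test_nearby_bursts_merge_within_refractory(self):
        rec = pulse_recording([("index", 1.0, 2.0), ("index", 1.05, 1.0)], 3.0)
        events = K.detect_taps(rec, refractory=0.2)
        assert len(events) == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_precision_recall_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        t, truth = 0.5, []
        while t < 20.0:
            truth.append((FINGERS[rng.integers(4)], t, rng.uniform(1.0, 3.0)))
            t += rng.uniform(0.3, 0.8)
        rec = pulse_recording(truth, 21.0, width=0.15)
        events = K.detect_taps(rec)
        assert len(events) == len(truth)
        for (f, tt, _), ev in zip(sorted(truth, key=lambda x: x[1]), events):
            assert ev.finger == f
            assert abs(ev.peak_time - tt) <= 0.02


# -- sequence scoring --------------------------------------------------------

SEQ_A = P.PAPER_SEQUENCES["A"]  # index little middle ring index


def brute_force_lcs(a, b):
    best = 0
    for mask in range(1 << len(a)):
        sub = [a[i] for i in range(len(a)) if mask >> i & 1]
        it = iter(b)
        if all(x in it for x in sub):
            best = max(best, len(sub))
    return best


def brute_force_substring(a, b):
    best = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            sub = tuple(a[i:j])
            if any(tuple(b[k : k + len(sub)]) == sub for k in range(len(b))):
                best = max(best, len(sub))
    return best


class TestSequenceScoring:
    def test_exact_sequence_is_correct(self):
        res = K.score_sequence_trial(SEQ_A.fingers, SEQ_A)
        assert res.is_correct
        assert res.longest_correct_run == 5
        assert res.n_missing == res.n_extra == 0

    def test_truncated_sequence(self):
        res = K.score_sequence_trial(SEQ_A.fingers[:3], SEQ_A)
        assert not res.is_correct
        assert res.n_missing == 2
        assert res.n_extra == 0
        assert res.longest_correct_run == 3

    def test_single_repeat_insertion(self):
        user = ("index", "little", "little", "middle", "ring", "index")
        res = K.score_sequence_trial(user, SEQ_A)
        assert not res.is_correct
        assert res.n_correct_taps == 5
        assert res.n_missing == 0
        assert res.n_extra == 1
        assert res.error_taps == {"little": 1}

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from(FINGERS), max_size=7))
    def test_alignment_matches_exhaustive_oracle(self, user):
        res = K.score_sequence_trial(user, SEQ_A)
        assert res.n_correct_taps == brute_force_lcs(user, SEQ_A.fingers)
        assert res.longest_correct_run == brute_force_substring(user, SEQ_A.fingers)

    def test_summary_success_and_halves(self):
        trials = [
            K.score_sequence_trial(
                SEQ_A.fingers if i < 3 else SEQ_A.fingers[:4], SEQ_A, i, "learning"
            )
            for i in range(10)
        ]
        summary = K.summarize_sequence(trials)
        assert summary.success_rate["learning"] == pytest.approx(0.3)
        assert summary.first_half_correct_taps == pytest.approx((5 * 3 + 4 * 2) / 5)
        assert summary.second_half_correct_taps == pytest.approx(4.0)


# -- single finger tapping ---------------------------------------------------

class TestSingleTapScoring:
    def test_clean_condition(self, noiseless_params):
        proto = P.build_single_tap_protocol([2.0], ["index"], 15)
        rec, _ = S.simulate_tapping(proto, noiseless_params)
        results = K.analyze_single_tap(rec, proto)
        for r in results:
            assert r.rate == pytest.approx(2.0, abs=0.01)
            assert r.n_overflow == 0
            assert r.n_unwanted == 0

    def test_overflow_matches_ground_truth(self, noiseless_params):
        from dataclasses import replace

        proto = P.build_single_tap_protocol([1.0], ["ring"], 10)
        E = np.eye(4)
        E[2, 1] = 0.4
        rec, truth = S.simulate_tapping(proto, replace(noiseless_params, enslaving=E))
        results = K.analyze_single_tap(rec, proto)
        n_truth = sum(1 for e in truth.taps if e.source == "enslaved")
        assert sum(r.n_overflow for r in results) == n_truth
        assert sum(r.n_unwanted for r in results) == 0

    def test_isolated_non_lead_tap_is_unwanted(self):
        events = [("index", 1.0 + k, 2.0) for k in range(10)] + [("middle", 5.5, 2.0)]
        rec = pulse_recording(events, 12.0)
        cond = P.Condition(("index",), 1.0, "cued", 0.0, 10.0)
        res = K.score_single_tap(K.detect_taps(rec), cond)
        assert res.n_unwanted == 1
        assert res.n_overflow == 0


class TestRateSlope:
    @pytest.mark.parametrize(
        "rates,expected",
        [((1.0, 2.0, 3.0), 1.0), ((1.0, 1.5, 2.0), 0.5), ((1.0, 2.0, 2.31), 0.655)],
    )
    def test_known_fits(self, rates, expected):
        rs = K.rate_slope([1, 2, 3], rates)
        assert rs.slope == pytest.approx(expected, abs=1e-9)

    def test_undefined_with_single_frequency(self):
        assert np.isnan(K.rate_slope([2, 2], [1.9, 2.0]).slope)

    def test_invariant_to_time_shift(self, noiseless_params):
        proto = P.build_single_tap_protocol()
        rec, _ = S.simulate_tapping(proto, noiseless_params)
        events = K.detect_taps(rec)
        shifted = [
            K.TapEvent(e.finger, e.onset_time + 0.05, e.peak_time + 0.05, e.amplitude)
            for e in events
        ]
        a = K.rate_slopes(K.analyze_single_tap(rec, proto, events=events))
        b = K.rate_slopes(K.analyze_single_tap(rec, proto, events=shifted))
        for f in a:
            assert a[f].slope == pytest.approx(b[f].slope, abs=0.05)


# -- multi-finger tapping ----------------------------------------------------

def multi_trial(target, response, t=0.0, window=4.0):
    cue = P.CueEvent(t, target, "visual_tap_cue")
    events = [K.TapEvent(f, t + 0.3, t + 0.4, 2.0) for f in response]
    return K.score_multi_trial(events, cue, window)


class TestMultiScoring:
    def test_correct_single_finger(self):
        res = multi_trial(("ring",), ("ring",))
        assert res.is_correct
        assert res.omissions == () and res.extras == ()

    def test_extra_finger(self):
        res = multi_trial(("ring",), ("middle", "ring"))
        assert not res.is_correct
        assert res.extras == ("middle",)
        assert res.omissions == ()

    def test_omitted_finger(self):
        res = multi_trial(("index", "little"), ("index",))
        assert not res.is_correct
        assert res.omissions == ("little",)

    @settings(max_examples=100, deadline=None)
    @given(
        target=st.sampled_from(
            [(f,) for f in FINGERS] + list(combinations(FINGERS, 2))
        ),
        response=st.sets(st.sampled_from(FINGERS)),
    )
    def test_set_conservation(self, target, response):
        res = multi_trial(tuple(target), tuple(response))
        assert set(res.omissions) | (set(res.response_set) & set(res.target_set)) == set(
            res.target_set
        )
        assert set(res.extras) & set(res.target_set) == set()

    def test_all_correct_summary(self):
        trials = [multi_trial((f,), (f,), t=4.0 * i) for i, f in enumerate(FINGERS)]
        summary = K.summarize_multi(trials)
        assert summary.success_rate == 1.0
        assert summary.omission_rate == 0.0
        assert summary.ueft_total == 0
        off_target = summary.error_matrix.to_numpy()[
            ~summary.target_mask.to_numpy() & ~np.isnan(summary.error_matrix.to_numpy())
        ]
        assert np.all(off_target == 0)

    def test_systematic_neighbor_error_rate(self):
        trials = [multi_trial(("ring",), ("ring", "middle"), t=4.0 * i) for i in range(8)]
        summary = K.summarize_multi(trials)
        assert summary.error_matrix.loc["4", "middle"] == pytest.approx(100.0)

    def test_four_finger_trials_excluded(self):
        trials = [multi_trial((f,), (f,), t=4.0 * i) for i, f in enumerate(FINGERS)]
        trials.append(multi_trial(FINGERS, FINGERS, t=20.0))
        summary = K.summarize_multi(trials)
        assert summary.n_trials == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_summary_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        proto = P.build_multi_tap_protocol(seed=seed)
        trials = []
        records = []
        for i, cue in enumerate(proto.cues):
            response = tuple(
                f
                for f in FINGERS
                if (f in cue.fingers and rng.random() > 0.2)
                or (f not in cue.fingers and rng.random() < 0.15)
            )
            trials.append(multi_trial(cue.fingers, response, t=cue.time, window=4.0))
            records.append((tuple(sorted(cue.fingers, key=FINGERS.index)), response))
        summary = K.summarize_multi(trials)

        # independent tally over the constructed responses
        scored = [(t, r) for t, r in records if len(t) in (1, 2)]
        n_correct = sum(1 for t, r in scored if set(r) == set(t))
        assert summary.success_rate == pytest.approx(n_correct / len(scored))
        n_target = sum(len(t) for t, _ in scored)
        n_omit = sum(len(set(t) - set(r)) for t, r in scored)
        assert summary.omission_rate == pytest.approx(n_omit / n_target)
        n_ueft = sum(len(set(r) - set(t)) for t, r in scored)
        assert summary.ueft_total == n_ueft
        for t_combo in {t for t, _ in scored}:
            combo_trials = [(t, r) for t, r in scored if t == t_combo]
            label = "-".join(str(P.FINGER_TO_DIGIT[f]) for f in t_combo)
            for f in FINGERS:
                if f in t_combo:
                    continue
                expect = 100.0 * sum(1 for _, r in combo_trials if f in r) / len(combo_trials)
                assert summary.error_matrix.loc[label, f] == pytest.approx(expect)
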