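"""Tapping-trial scoring: hand-checked examples, invariances, and
equivalence with an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emafit.fittest import (
    FitTestTrial,
    KeystrokeEvent,
    TrialRejected,
    UndefinedScore,
    akinesia_time,
    dysmetria_score,
    incoordination_score,
    kinesia_score,
    qwerty_adjacency,
    score_trial,
    validate_trial,
)
from emafit.simulate import MotorParams, tapping_stream

TARGETS = ("s", ";")


def make_trial(events, hand="right", targets=TARGETS):
    return FitTestTrial(hand=hand, target_keys=targets, events=tuple(events))


def alternating_trial(dwells, travels, targets=TARGETS, start=10.0):
    """Build a clean alternating trial from explicit dwell/travel lists."""
    assert len(travels) == len(dwells) - 1
    events = []
    t = start
    for i, dwell in enumerate(dwells):
        events.append(KeystrokeEvent(targets[i % 2], t, t + dwell))
        if i < len(travels):
            t = t + dwell + travels[i]
    return make_trial(events)


class TestValidation:
    def test_well_formed_trial_accepted(self):
        trial = alternating_trial([100] * 40, [500] * 39)
        assert validate_trial(trial) == (True, None)

    def test_event_outside_window_rejected(self):
        trial = make_trial([KeystrokeEvent("s", 30_500.0, 31_000.0)])
        assert validate_trial(trial) == (False, "outside window")

    def test_empty_trial_rejected(self):
        assert validate_trial(make_trial([])) == (False, "no keystrokes")

    def test_overlapping_holds_rejected(self):
        events = [KeystrokeEvent("s", 0.0, 300.0), KeystrokeEvent(";", 200.0, 400.0)]
        assert validate_trial(make_trial(events))[1] == "overlapping key-holds"

    def test_rejected_trial_produces_no_result(self):
        with pytest.raises(TrialRejected):
            score_trial(make_trial([]))


class TestWorkedExamples:
    def test_kinesia_counts_all_keystrokes(self):
        trial = alternating_trial([100] * 42, [500] * 41)
        assert kinesia_score(trial) == 42

    def test_single_keystroke(self):
        trial = make_trial([KeystrokeEvent("s", 100.0, 240.0)])
        assert kinesia_score(trial) == 1
        assert akinesia_time(trial) == 140.0

    def test_akinesia_mean_of_dwells(self):
        assert akinesia_time(alternating_trial([100, 200], [500])) == 150.0

    def test_incoordination_constant_travel_is_zero(self):
        assert incoordination_score(alternating_trial([100] * 5, [400] * 4)) == 0.0

    def test_incoordination_two_travels(self):
        # sample variance of {100, 300} = ((100-200)^2 + (300-200)^2) / 1
        assert incoordination_score(alternating_trial([100] * 3, [100, 300])) == 20000.0

    def test_incoordination_needs_three_keystrokes(self):
        with pytest.raises(UndefinedScore):
            incoordination_score(alternating_trial([100, 100], [400]))

    def test_dysmetria_all_on_target(self):
        assert dysmetria_score(alternating_trial([100] * 10, [400] * 9)) == 0.0

    def test_dysmetria_one_adjacent_miss_in_ten(self):
        events = list(alternating_trial([100] * 10, [400] * 9).events)
        bad = events[4]
        events[4] = KeystrokeEvent("a", bad.down_ms, bad.up_ms)  # adjacent to "s"
        assert dysmetria_score(make_trial(events)) == pytest.approx(0.1)

    def test_dysmetria_all_distant_is_two(self):
        events = [
            KeystrokeEvent("q", t, t + 50.0) for t in np.arange(0.0, 5000.0, 500.0)
        ]
        assert dysmetria_score(make_trial(events, targets=("g", "m"))) == 2.0

    def test_two_hands_two_results(self):
        left = alternating_trial([100] * 5, [400] * 4)
        right = FitTestTrial(hand="left", target_keys=TARGETS, events=left.events)
        results = [score_trial(left), score_trial(right)]
        assert {r.hand for r in results} == {"right", "left"}


class TestInvariances:
    @settings(max_examples=30, derandomize=True)
    @given(shift=st.floats(min_value=0, max_value=1000))
    def test_time_shift_changes_no_score(self, shift):
        base = alternating_trial([110, 130, 95, 120], [480, 520, 460], start=0.0)
        shifted = make_trial(
            [KeystrokeEvent(e.key, e.down_ms + shift, e.up_ms + shift) for e in base.events]
        )
        a, b = score_trial(base), score_trial(shifted)
        assert a.kinesia_score == b.kinesia_score
        assert a.akinesia_time_ms == pytest.approx(b.akinesia_time_ms, rel=1e-12)
        assert a.incoordination_score_ms2 == pytest.approx(b.incoordination_score_ms2, rel=1e-6)
        assert a.dysmetria_score == b.dysmetria_score

    def test_kinesia_invariant_to_dwell_durations(self):
        a = alternating_trial([100] * 6, [400] * 5)
        b = alternating_trial([10] * 6, [490] * 5)
        assert kinesia_score(a) == kinesia_score(b) == 6

    def test_akinesia_invariant_to_gaps(self):
        a = alternating_trial([100, 200, 150], [400, 400])
        b = alternating_trial([100, 200, 150], [900, 100])
        assert akinesia_time(a) == akinesia_time(b)

    def test_incoordination_invariant_to_constant_travel_shift(self):
        a = alternating_trial([100] * 4, [400, 500, 450])
        b = alternating_trial([100] * 4, [600, 700, 650])
        assert incoordination_score(a) == pytest.approx(incoordination_score(b))

    def test_adjacency_map_is_symmetric(self):
        adj = qwerty_adjacency()
        for key, neighbours in adj.items():
            for n in neighbours:
                assert key in adj[n]


def brute_force_scores(trial: FitTestTrial) -> dict:
    """Independent single-pass recomputation from raw events, with its own
    formulas (variance via sum of squared deviations)."""
    targets = set(trial.target_keys)
    ks = len(trial.events)
    dwells = [e.up_ms - e.down_ms for e in trial.events if e.key in targets]
    at = sum(dwells) / len(dwells)
    kept = [e for e in trial.events if e.key in targets]
    travels = [kept[i + 1].down_ms - kept[i].up_ms for i in range(len(kept) - 1)]
    mean_t = sum(travels) / len(travels)
    is_ = sum((t - mean_t) ** 2 for t in travels) / (len(travels) - 1)
    adj = qwerty_adjacency()
    near = set().union(*(adj[t] for t in targets)) - targets
    ds = sum(
        0 if e.key in targets else (1 if e.key in near else 2) for e in trial.events
    ) / ks
    return {"KS": ks, "AT": at, "IS": is_, "DS": ds}


class TestOracleEquivalence:
    def test_scorer_matches_brute_force_on_random_trials(self):
        """>= 100 simulated trials across settings agree with the oracle."""
        rng = np.random.default_rng(20240304)
        count = 0
        for dwell_mean in (90.0, 120.0, 160.0):
            for travel_sd in (15.0, 30.0, 60.0):
                motor = MotorParams(
                    dwell_mean_ms=dwell_mean, travel_sd_ms=travel_sd, error_rate=0.04
                )
                for _ in range(12):
                    trial = make_trial(tapping_stream(motor, rng=rng))
                    res = score_trial(trial)
                    oracle = brute_force_scores(trial)
                    assert res.kinesia_score == oracle["KS"]
                    assert res.akinesia_time_ms == pytest.approx(oracle["AT"], rel=1e-12)
                    assert res.incoordination_score_ms2 == pytest.approx(oracle["IS"], rel=1e-9)
                    assert res.dysmetria_score == pytest.approx(oracle["DS"], rel=1e-12)
                    count += 1
        assert count >= 100


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "dwell_mean, dwell_sd, travel_mean, travel_sd",
        [(120.0, 10.0, 480.0, 30.0), (180.0, 20.0, 620.0, 45.0)],
    )
    def test_dwell_and_travel_variance_recovered(
        self, dwell_mean, dwell_sd, travel_mean, travel_sd
    ):
        """Mean scorer estimates over 200 error-free trials lie within 3
        standard errors of the generator parameters."""
        motor = MotorParams(
            dwell_mean_ms=dwell_mean,
            dwell_sd_ms=dwell_sd,
            travel_mean_ms=travel_mean,
            travel_sd_ms=travel_sd,
            error_rate=0.0,
        )
        rng = np.random.default_rng(int(dwell_mean))
        ats, iss = [], []
        for _ in range(200):
            trial = make_trial(tapping_stream(motor, rng=rng))
            res = score_trial(trial)
            ats.append(res.akinesia_time_ms)
            iss.append(res.incoordination_score_ms2)
        at_err = abs(np.mean(ats) - dwell_mean)
        assert at_err < 3 * np.std(ats, ddof=1) / np.sqrt(len(ats))
        is_err = abs(np.mean(iss) - travel_sd**2)
        assert is_err < 3 * np.std(iss, ddof=1) / np.sqrt(len(iss))

    def test_kinesia_tracks_tap_rate(self):
        """600 ms mean inter-tap interval yields about 50 strikes per trial."""
        motor = MotorParams(error_rate=0.0)  # dwell 120 + travel 480 = 600 ms
        rng = np.random.default_rng(5)
        ks = [kinesia_score(make_trial(tapping_stream(motor, rng=rng))) for _ in range(50)]
        assert abs(np.mean(ks) - 50) < 3 * np.sqrt(50)  # Poisson-count tolerance
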