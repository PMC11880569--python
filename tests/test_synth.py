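"""Synthetic cohort generator: scenario packing, amplitude schedules,
cohort structure, determinism."""

import numpy as np
import pytest

from habitu.synth import (
    MIN_EVENT_GAP_S,
    ParticipantProfile,
    generate_cohort,
    generate_participant_signals,
    generate_scenario,
)
from conftest import noise_free_profile


class TestScenario:
    def test_packing_respects_gap_and_span(self):
        specs = generate_scenario(4, 3, 480.0, seed=7, withdrawal_occurrences=2)
        times = sorted(t for s in specs for t in s.occurrence_times)
        assert len(times) == 14
        assert min(np.diff(times)) >= MIN_EVENT_GAP_S
        assert times[0] >= 5.0 and times[-1] <= 480.0 - 5.0
        assert [s.is_withdrawal for s in specs].count(True) == 1

    def test_two_occurrences_single_type(self):
        (spec,) = generate_scenario(1, 2, 480.0, seed=7)
        assert len(spec.occurrence_times) == 2
        assert not spec.is_withdrawal
        assert np.diff(spec.occurrence_times)[0] >= MIN_EVENT_GAP_S

    def test_seed_determinism(self):
        a = generate_scenario(4, 3, 480.0, seed=7)
        b = generate_scenario(4, 3, 480.0, seed=7)
        assert [(s.name, s.occurrence_times) for s in a] == [
            (s.name, s.occurrence_times) for s in b
        ]

    @pytest.mark.parametrize("bad", [dict(n_event_types=0), dict(occurrences_per_type=0)])
    def test_empty_preconditions(self, bad):
        kwargs = dict(n_event_types=2, occurrences_per_type=2) | bad
        with pytest.raises(ValueError):
            generate_scenario(**kwargs, session_duration=480.0, seed=1)

    def test_unpackable_session_raises(self):
        with pytest.raises(ValueError, match="pack"):
            generate_scenario(10, 10, 60.0, seed=1)


class TestSignals:
    def test_zero_gain_gives_equal_amplitudes(self):
        events = generate_scenario(1, 4, 300.0, seed=2)
        sess = generate_participant_signals(events, noise_free_profile(0.0), 300.0,
                                            include_raw=False)
        sched = sess.schedules[events[0].name]
        assert np.allclose(sched["phasic"], sched["phasic"][0])
        assert np.allclose(sched["hr"], sched["hr"][0])

    def test_positive_gain_decays_windowed_max(self, noise_free_session):
        """Monotone habituation: first-window phasic max exceeds the last's."""
        sess = noise_free_session
        for spec in sess.events:
            t0, t_last = spec.occurrence_times[0], spec.occurrence_times[-1]
            w = lambda t: sess.ideal.phasic[int(t * 32) : int(t * 32) + 160].max()
            assert w(t0) > w(t_last)

    def test_injected_amplitude_recovered_exactly(self, noise_free_session):
        """Windowed max on the noise-free phasic channel equals the analytic
        A0*exp(-g*k) schedule to machine precision."""
        sess = noise_free_session
        for spec in sess.events:
            sched = sess.schedules[spec.name]["phasic"]
            for k, te in enumerate(spec.occurrence_times):
                i = int(round(te * 32))
                assert sess.ideal.phasic[i : i + 160].max() == pytest.approx(
                    sched[k], abs=1e-12
                )

    def test_session_determinism(self):
        events = generate_scenario(2, 2, 200.0, seed=9)
        a = generate_participant_signals(events, noise_free_profile(0.3, seed=4), 200.0)
        b = generate_participant_signals(events, noise_free_profile(0.3, seed=4), 200.0)
        np.testing.assert_array_equal(a.recording.ecg.samples, b.recording.ecg.samples)
        np.testing.assert_array_equal(a.recording.gsr.samples, b.recording.gsr.samples)
        np.testing.assert_array_equal(a.recording.pupil.samples, b.recording.pupil.samples)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            ParticipantProfile("x", pclm_score=90, habituation_gain={})
        with pytest.raises(ValueError):
            ParticipantProfile("x", pclm_score=40, habituation_gain={}, baseline_hr=250)
        with pytest.raises(ValueError):
            ParticipantProfile("x", pclm_score=40, habituation_gain={},
                               noise_sd={"ecg": -1.0})


class TestCohort:
    def test_default_split_10_11(self):
        cohort = generate_cohort(21, 1.0, seed=1, include_raw=False, session_duration=200.0)
        assert int(cohort.labels.sum()) == 10
        assert (cohort.pclm_scores[cohort.labels] > 36).all()
        assert (cohort.pclm_scores[~cohort.labels] <= 36).all()

    def test_null_cohort_gains_overlap_between_classes(self):
        cohort = generate_cohort(21, 0.0, seed=3, include_raw=False, session_duration=200.0)
        gains = np.array([s.profile.habituation_gain["phasic"] for s in cohort.sessions])
        pos, neg = gains[cohort.labels], gains[~cohort.labels]
        # no sign enforcement at effect 0: both classes straddle zero
        assert pos.min() < 0 < pos.max() or neg.min() < 0 < neg.max()
        assert max(pos.min(), neg.min()) < min(pos.max(), neg.max())

    def test_cohort_determinism(self):
        a = generate_cohort(6, 1.0, seed=5, include_raw=False, session_duration=150.0)
        b = generate_cohort(6, 1.0, seed=5, include_raw=False, session_duration=150.0)
        np.testing.assert_array_equal(a.pclm_scores, b.pclm_scores)
        for sa, sb in zip(a.sessions, b.sessions):
            np.testing.assert_array_equal(sa.ideal.phasic, sb.ideal.phasic)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_cohort(3, 1.0, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(8, -0.5, seed=1)

    def test_pclm_positively_coupled_to_gain(self):
        cohort = generate_cohort(21, 2.0, seed=7, include_raw=False, session_duration=200.0)
        gains = np.array([s.profile.habituation_gain["phasic"] for s in cohort.sessions])
        assert np.corrcoef(gains, cohort.pclm_scores)[0, 1] > 0.5
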