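import pytest

from habitu import pipeline
from habitu.synth import (
    ParticipantProfile,
    generate_cohort,
    generate_participant_signals,
    generate_scenario,
)

NOISE_FREE = {"ecg": 0.0, "gsr": 0.0, "pupil": 0.0}


def noise_free_profile(gain: float, pclm: int = 45, seed: int = 1) -> ParticipantProfile:
    return ParticipantProfile(
        participant_id=f"nf{seed}",
        pclm_score=pclm,
        habituation_gain={"phasic": gain, "hr": gain, "ebp": gain},
        blink_rate=0.0,
        noise_sd=dict(NOISE_FREE),
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def noise_free_session():
    """2 event types x 3 occurrences, 240 s, no noise, ideal signals only."""
    events = generate_scenario(2, 3, 240.0, seed=3)
    return generate_participant_signals(events, noise_free_profile(0.4), 240.0, include_raw=False)


@pytest.fixture(scope="session")
def raw_session():
    """Full raw-channel session with default noise, 300 s."""
    profile = ParticipantProfile(
        participant_id="raw0",
        pclm_score=40,
        habituation_gain={"phasic": 0.4, "hr": 0.3, "ebp": 0.4},
        rng_seed=11,
    )
    events = generate_scenario(3, 3, 300.0, seed=5, withdrawal_occurrences=1)
    return generate_participant_signals(events, profile, 300.0)


@pytest.fixture(scope="session")
def ideal_cohort_matrix():
    """Well-separated 8-participant cohort on the ground-truth signal path."""
    cohort = generate_cohort(8, 3.0, seed=17, include_raw=False, session_duration=300.0)
    return pipeline.cohort_matrix(cohort, use_ideal=True), cohort
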