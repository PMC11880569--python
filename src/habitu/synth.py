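"""Synthetic psychophysiology cohort generator.

Emulates a ~21-participant virtual-reality stress session: an event log of
typed trigger stimuli (explosions, flashbangs, ...), raw ECG and skin
conductance at 2048 Hz, pupil diameter at 300 Hz with blink dropout, and a
PCL-M self-report score per participant.  Event-locked responses follow an
exponential habituation law: the k-th occurrence of a given event type
elicits amplitude ``A0 * exp(-g * k)`` per channel, so a positive
habituation gain ``g`` means decaying responses (habituation) and a
negative one growing responses (sensitization).

Two levels of output are produced for every session:

* ``recording`` — raw sensor channels, fed to the preprocessing stage;
* ``ideal``     — the noise-free ground-truth 32 Hz analysis series the
  raw channels were built from, usable directly as an oracle (and as a
  fast path that skips raw-signal synthesis entirely).

Design notes for exactness: scenario event times are snapped to the 1/32 s
analysis grid, consecutive events are at least 6 s apart, and the response
kernels have compact support shorter than that gap — so a 5-s window after
any event sees exactly one response and the windowed maximum equals the
injected amplitude to machine precision.  Deterministic per-event blink
gaps span whole 32 Hz frames, making the eye-blink proxy an exact integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import hr_bump_kernel, scr_kernel
from .signal_prep import Channel, ProcessedSignals, RawRecording, TARGET_RATE_HZ

#: default stimulus vocabulary; ``zone_withdrawal`` carries no response
DEFAULT_VOCABULARY = ("explosion", "flashbang", "tank_fire", "dog_bark")
WITHDRAWAL_NAME = "zone_withdrawal"

#: minimum gap between consecutive events, seconds (> kernel support)
MIN_EVENT_GAP_S = 6.0

#: session duration distribution, minutes (truncated normal)
SESSION_MINUTES_MEAN = 7.86
SESSION_MINUTES_SD = 1.83
SESSION_MINUTES_RANGE = (5.0, 15.0)

ECG_RATE = 2048.0
GSR_RATE = 2048.0
PUPIL_RATE = 300.0

#: default response amplitudes at occurrence 0: phasic EDA in uS, heart
#: rate in beats/min, blink gap in whole 32 Hz frames (8 frames = 0.25 s)
DEFAULT_AMPLITUDES = {"phasic": 0.6, "hr": 12.0, "ebp_frames": 8.0}


@dataclass
class EventSpec:
    """One event type and its occurrence times (seconds from start)."""

    name: str
    occurrence_times: list[float]
    is_withdrawal: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.occurrence_times, dtype=float)
        if len(t) and not (np.diff(t) > 0).all():
            raise ValueError(f"occurrence times for {self.name!r} not strictly increasing")
        if len(t) and t[0] < 0:
            raise ValueError("occurrence times must be nonnegative")
        self.occurrence_times = list(t)


@dataclass
class ParticipantProfile:
    participant_id: str
    pclm_score: int
    habituation_gain: dict[str, float]  # per channel: phasic / hr / ebp
    baseline_hr: float = 65.0  # beats/min
    baseline_scl: float = 4.0  # tonic skin conductance level, uS
    blink_rate: float = 12.0  # background blinks per minute
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"ecg": 0.03, "gsr": 0.02, "pupil": 0.05}
    )
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 17 <= self.pclm_score <= 85:
            raise ValueError(f"PCL-M score {self.pclm_score} outside [17, 85]")
        if not 30 <= self.baseline_hr <= 180:
            raise ValueError(f"baseline HR {self.baseline_hr} outside [30, 180] bpm")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be nonnegative")
        if self.blink_rate < 0:
            raise ValueError("blink rate must be nonnegative")
        for ch in ("phasic", "hr", "ebp"):
            self.habituation_gain.setdefault(ch, 0.0)


@dataclass
class SyntheticSession:
    events: list[EventSpec]
    recording: RawRecording | None
    profile: ParticipantProfile
    session_duration: float
    ideal: ProcessedSignals
    #: per event type: channel -> amplitude of occurrence k (ebp_frames is
    #: the integer number of missing 32 Hz frames in the blink gap)
    schedules: dict[str, dict[str, np.ndarray]]


@dataclass
class Cohort:
    sessions: list[SyntheticSession]
    pclm_scores: np.ndarray  # int, aligned with sessions
    labels: np.ndarray  # bool, PCL-M > 36

    def __len__(self) -> int:
        return len(self.sessions)


# ---------------------------------------------------------------------------
# Scenario


def generate_scenario(
    n_event_types: int,
    occurrences_per_type: int,
    session_duration: float,
    seed: int,
    *,
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    withdrawal_occurrences: int = 0,
) -> list[EventSpec]:
    """Randomly pack typed event occurrences into a session.

    All events (any type) are separated by at least :data:`MIN_EVENT_GAP_S`
    and fall in ``[5, session_duration - 5)`` so every 5-s response window
    fits inside the recording.  Times are snapped to the 1/32 s analysis
    grid.  Deterministic for a fixed seed.
    """
    if n_event_types < 1:
        raise ValueError("need at least one non-withdrawal event type")
    if occurrences_per_type < 1:
        raise ValueError("need at least one occurrence per type")
    names = [
        vocabulary[i] if i < len(vocabulary) else f"event_{i}" for i in range(n_event_types)
    ]
    m = n_event_types * occurrences_per_type + withdrawal_occurrences
    slack = (session_duration - 10.0) - (m - 1) * MIN_EVENT_GAP_S
    if slack < 0:
        raise ValueError(
            f"cannot pack {m} events with {MIN_EVENT_GAP_S} s gaps into "
            f"{session_duration} s"
        )
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.uniform(0.0, slack, m))
    cuts = np.round(cuts * TARGET_RATE_HZ) / TARGET_RATE_HZ  # snap, keeps order
    times = 5.0 + np.arange(m) * MIN_EVENT_GAP_S + cuts

    type_of = np.repeat(np.arange(n_event_types), occurrences_per_type)
    type_of = np.concatenate([type_of, np.full(withdrawal_occurrences, -1)])
    rng.shuffle(type_of)

    specs = []
    for i, name in enumerate(names):
        specs.append(EventSpec(name, list(times[type_of == i])))
    if withdrawal_occurrences:
        specs.append(
            EventSpec(WITHDRAWAL_NAME, list(times[type_of == -1]), is_withdrawal=True)
        )
    return specs


# ---------------------------------------------------------------------------
# Signals


def _amplitude_schedules(
    events: list[EventSpec], profile: ParticipantProfile
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for spec in events:
        if spec.is_withdrawal:
            continue
        k = np.arange(len(spec.occurrence_times))
        sched = {}
        for ch in ("phasic", "hr"):
            g = profile.habituation_gain[ch]
            sched[ch] = profile.amplitudes[ch] * np.exp(-g * k)
        g = profile.habituation_gain["ebp"]
        sched["ebp_frames"] = np.round(
            profile.amplitudes["ebp_frames"] * np.exp(-g * k)
        ).astype(int)
        out[spec.name] = sched
    return out


def _add_kernel(series: np.ndarray, kernel: np.ndarray, idx: int, amp: float) -> None:
    stop = min(idx + len(kernel), len(series))
    if stop > idx >= 0:
        series[idx:stop] += amp * kernel[: stop - idx]


def _frame_index(n: int, rate: float) -> np.ndarray:
    # must match the expression used by signal_prep.downsample's majority rule
    return (np.arange(n) / rate * TARGET_RATE_HZ).astype(int)


def generate_participant_signals(
    events: list[EventSpec],
    profile: ParticipantProfile,
    session_duration: float,
    *,
    include_raw: bool = True,
) -> SyntheticSession:
    """Render a participant's session from the event list and profile.

    With ``include_raw=False`` only the ground-truth 32 Hz series are
    produced (fast path for statistical simulations); otherwise raw ECG,
    skin conductance and pupil channels are synthesised on top of them.
    """
    for spec in events:
        if spec.occurrence_times and max(spec.occurrence_times) >= session_duration:
            raise ValueError(f"event {spec.name!r} beyond session end")
    rng = np.random.default_rng(profile.rng_seed)
    sched = _amplitude_schedules(events, profile)
    n32 = int(np.floor(session_duration * TARGET_RATE_HZ))

    scr32 = scr_kernel(TARGET_RATE_HZ)
    bump32 = hr_bump_kernel(TARGET_RATE_HZ)
    t32 = np.arange(n32) / TARGET_RATE_HZ

    hr = np.full(n32, profile.baseline_hr)
    phasic = np.zeros(n32)
    tonic = profile.baseline_scl + 0.15 * np.sin(2 * np.pi * t32 / 180.0) - 0.0004 * t32
    stim_occ: list[tuple[float, float]] = []  # (time, phasic amplitude)
    for spec in events:
        if spec.is_withdrawal:
            continue
        for k, te in enumerate(spec.occurrence_times):
            idx = int(round(te * TARGET_RATE_HZ))
            _add_kernel(phasic, scr32, idx, sched[spec.name]["phasic"][k])
            _add_kernel(hr, bump32, idx, sched[spec.name]["hr"][k])
            stim_occ.append((te, sched[spec.name]["phasic"][k]))

    # pupil: baseline diameter + event-locked dilation; blink gaps as NaN
    pupil = 4.0 + 0.4 * (phasic / max(profile.amplitudes["phasic"], 1e-9))
    blink32 = np.zeros(n32, dtype=bool)
    for spec in events:
        if spec.is_withdrawal:
            continue
        for k, te in enumerate(spec.occurrence_times):
            f0 = int(round((te + 1.0) * TARGET_RATE_HZ))
            m = int(sched[spec.name]["ebp_frames"][k])
            blink32[f0 : f0 + m] = True
    # background blinks (spontaneous, anywhere in the session)
    n_bg = rng.poisson(profile.blink_rate * session_duration / 60.0)
    bg_starts = np.sort(rng.uniform(0.0, session_duration, n_bg))
    bg_durs = rng.lognormal(np.log(0.18), 0.35, n_bg)  # mean run ~0.2 s
    for s, d in zip(bg_starts, bg_durs):
        i0 = int(s * TARGET_RATE_HZ)
        blink32[i0 : i0 + max(1, int(round(d * TARGET_RATE_HZ)))] = True
    pupil_ideal = pupil.copy()
    pupil_ideal[blink32] = np.nan

    ideal = ProcessedSignals(hr=hr, phasic=phasic, pupil=pupil_ideal, tonic=tonic)

    recording = None
    if include_raw:
        recording = _render_raw(
            profile, session_duration, hr, stim_occ, t32, tonic, pupil, blink32, rng
        )
    return SyntheticSession(
        events=events,
        recording=recording,
        profile=profile,
        session_duration=session_duration,
        ideal=ideal,
        schedules=sched,
    )


def _render_raw(
    profile: ParticipantProfile,
    duration: float,
    hr32: np.ndarray,
    stim_occ: list[tuple[float, float]],
    t32: np.ndarray,
    tonic32: np.ndarray,
    pupil32: np.ndarray,
    blink32: np.ndarray,
    rng: np.random.Generator,
) -> RawRecording:
    # --- ECG: beat times from integrated instantaneous rate, stereotyped beat
    # (phase integrated at 32 Hz; the rate varies on second timescales)
    n_ecg = int(duration * ECG_RATE)
    phase = np.cumsum(hr32 / 60.0) / TARGET_RATE_HZ
    n_beats = int(phase[-1])
    beat_t = np.interp(np.arange(1, n_beats + 1), phase, t32)
    sd_ecg = profile.noise_sd["ecg"]
    ecg = rng.normal(0.0, sd_ecg, n_ecg) if sd_ecg > 0 else np.zeros(n_ecg)
    qrs_half = int(0.04 * ECG_RATE)
    tq = np.arange(-qrs_half, qrs_half) / ECG_RATE
    qrs = np.exp(-0.5 * (tq / 0.012) ** 2)  # R wave, amplitude 1 mV
    tw = hr_bump_kernel(ECG_RATE, support=0.16) * 0.2  # T wave
    beat = np.zeros(qrs_half * 2 + int(0.18 * ECG_RATE) + len(tw))
    beat[: len(qrs)] += qrs
    beat[qrs_half * 2 + int(0.18 * ECG_RATE) :] += tw
    starts = (beat_t * ECG_RATE).astype(int) - qrs_half
    starts = starts[(starts >= 0) & (starts + len(beat) <= n_ecg)]
    idx = starts[:, None] + np.arange(len(beat))[None, :]
    np.add.at(ecg, idx.ravel(), np.broadcast_to(beat, idx.shape).ravel())

    # --- skin conductance: tonic drift + SCR kernels + noise
    n_gsr = int(duration * GSR_RATE)
    t_gsr = np.arange(n_gsr) / GSR_RATE
    gsr = np.interp(t_gsr, t32, tonic32) + rng.normal(0.0, profile.noise_sd["gsr"], n_gsr)
    scr_fine = scr_kernel(GSR_RATE)
    for te, amp in stim_occ:
        _add_kernel(gsr, scr_fine, int(round(te * GSR_RATE)), amp)

    # --- pupil at 300 Hz; blink gaps reproduce the 32 Hz frame mask exactly
    n_pup = int(duration * PUPIL_RATE)
    t_pup = np.arange(n_pup) / PUPIL_RATE
    pupil = np.interp(t_pup, t32, pupil32) + rng.normal(
        0.0, profile.noise_sd["pupil"], n_pup
    )
    frame = _frame_index(n_pup, PUPIL_RATE)
    frame = np.minimum(frame, len(blink32) - 1)
    pupil[blink32[frame]] = np.nan
    return RawRecording(
        ecg=Channel(ecg, ECG_RATE),
        gsr=Channel(gsr, GSR_RATE),
        pupil=Channel(pupil, PUPIL_RATE),
    )


# ---------------------------------------------------------------------------
# Cohort


def generate_cohort(
    n: int,
    effect: float,
    seed: int,
    *,
    n_event_types: int = 4,
    occurrences_per_type: int = 3,
    withdrawal_occurrences: int = 2,
    session_duration: float | None = None,
    include_raw: bool = True,
    gain_sd: float = 0.15,
) -> Cohort:
    """Simulate a cohort with class-dependent habituation structure.

    ``effect`` is the separation of the class-mean habituation gains in
    units of the within-class SD (`gain_sd`): PTSD-positive participants
    draw gains around ``+effect*gain_sd/2`` (habituation), negatives around
    ``-effect*gain_sd/2`` (sensitization).  With ``effect > 0`` the signs
    are enforced (positives > 0, negatives <= 0); with ``effect == 0`` both
    classes draw from the identical zero-mean distribution.  PCL-M scores
    are positively coupled to the gain and clamped to the class side of the
    36-point threshold, so the class split is exact (10:11 at n = 21).
    """
    if n < 4:
        raise ValueError("leave-one-out evaluation needs at least 4 participants")
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * 10 / 21))
    is_pos = np.zeros(n, dtype=bool)
    is_pos[:n_pos] = True
    rng.shuffle(is_pos)

    sessions, pclm_scores = [], []
    for i in range(n):
        mu = (effect * gain_sd / 2.0) * (1 if is_pos[i] else -1)
        g = rng.normal(mu, gain_sd)
        if effect > 0:
            g = max(g, 0.02) if is_pos[i] else min(g, 0.0)
        pclm = int(np.clip(round(36.5 + 20.0 * g + rng.normal(0.0, 3.0)), 17, 85))
        pclm = max(pclm, 37) if is_pos[i] else min(pclm, 36)

        dur = session_duration
        if dur is None:
            minutes = float(
                np.clip(
                    rng.normal(SESSION_MINUTES_MEAN, SESSION_MINUTES_SD),
                    *SESSION_MINUTES_RANGE,
                )
            )
            dur = round(minutes * 60.0)
        profile = ParticipantProfile(
            participant_id=f"p{i:03d}",
            pclm_score=pclm,
            habituation_gain={"phasic": g, "hr": 0.8 * g, "ebp": g},
            baseline_hr=rng.uniform(55.0, 80.0),
            baseline_scl=rng.uniform(2.0, 8.0),
            blink_rate=rng.uniform(8.0, 20.0),
            rng_seed=int(rng.integers(2**31)),
        )
        events = generate_scenario(
            n_event_types,
            occurrences_per_type,
            dur,
            seed=int(rng.integers(2**31)),
            withdrawal_occurrences=withdrawal_occurrences,
        )
        sessions.append(
            generate_participant_signals(events, profile, dur, include_raw=include_raw)
        )
        pclm_scores.append(pclm)

    pclm_arr = np.asarray(pclm_scores)
    return Cohort(sessions=sessions, pclm_scores=pclm_arr, labels=pclm_arr > 36)
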