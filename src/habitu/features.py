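"""Habituation feature extraction.

For each event type with at least two valid occurrences, seven
first-minus-last features are computed from 5-second post-event windows:
max/min/mean of heart rate and of phasic skin conductance, plus the
eye-blink proxy (EBP) — the count of missing pupil samples in the window.
A positive feature value means the response shrank between the first and
last occurrence (habituation); a negative one means sensitization.

An occurrence is *valid* when its window lies entirely inside the
recording and at least 80% of its pupil samples are present; first/last
are taken over valid occurrences only, and event types with fewer than two
valid occurrences emit no features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .signal_prep import CleanEventList, ProcessedSignals

log = logging.getLogger(__name__)

WINDOW_S = 5.0
MIN_PUPIL_COVERAGE = 0.8

#: canonical marker order for feature-matrix columns
MARKERS = ("max_phasic", "min_phasic", "mean_phasic", "max_hr", "min_hr", "mean_hr", "ebp")
_STATS = {"max": np.nanmax, "min": np.nanmin, "mean": np.nanmean}


class FeatureKey(NamedTuple):
    """An (event type, physiological marker) pair, e.g. explosion/max_hr."""

    event_type: str
    marker: str

    def __str__(self) -> str:
        return f"{self.event_type}/{self.marker}"

    @classmethod
    def parse(cls, s: str) -> "FeatureKey":
        event_type, marker = s.rsplit("/", 1)
        if marker not in MARKERS:
            raise ValueError(f"unknown marker {marker!r}")
        return cls(event_type, marker)

    @property
    def sort_index(self) -> tuple[str, int]:
        return (self.event_type, MARKERS.index(self.marker))


class WindowError(ValueError):
    """A 5-s window cannot be evaluated (overrun or insufficient coverage)."""


@dataclass
class FeatureVector:
    participant_id: str
    values: dict[FeatureKey, float] = field(default_factory=dict)
    window_s: float = WINDOW_S

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values for {bad}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CohortMatrix:
    """Participant x feature matrix (NaN = feature unavailable) + labels."""

    X: pd.DataFrame  # columns are FeatureKey strings in canonical order
    pclm_scores: pd.Series
    labels: pd.Series  # bool

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.labels.index) or not self.X.index.equals(
            self.pclm_scores.index
        ):
            raise ValueError("labels/pclm not aligned with feature rows")

    @property
    def n(self) -> int:
        return len(self.X)


def _window_slice(n_samples: int, rate: float, t: float, window_s: float) -> slice:
    i0 = int(round(t * rate))
    i1 = i0 + int(round(window_s * rate))
    if i0 < 0 or i1 > n_samples:
        raise WindowError(f"window [{t}, {t + window_s}) s overruns the recording")
    return slice(i0, i1)


def window_stat(
    series: np.ndarray,
    t: float,
    stat: str,
    rate: float = 32.0,
    window_s: float = WINDOW_S,
    min_coverage: float = MIN_PUPIL_COVERAGE,
) -> float:
    """Statistic (max/min/mean) over the half-open window [t, t+5) s.

    Missing (NaN) samples are excluded; raises :class:`WindowError` if the
    window overruns the recording or fewer than ``min_coverage`` of its
    samples are present.
    """
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {sorted(_STATS)}")
    w = series[_window_slice(len(series), rate, t, window_s)]
    present = np.isfinite(w)
    if present.mean() < min_coverage:
        raise WindowError(f"window at t={t} s has {present.mean():.0%} coverage")
    return float(_STATS[stat](w))


def ebp(pupil: np.ndarray, t: float, rate: float = 32.0, window_s: float = WINDOW_S) -> int:
    """Eye-blink proxy: number of missing pupil samples in [t, t+5) s."""
    w = pupil[_window_slice(len(pupil), rate, t, window_s)]
    return int(np.isnan(w).sum())


def _valid_occurrence(signals: ProcessedSignals, t: float, window_s: float) -> bool:
    try:
        sl = _window_slice(signals.n_samples, signals.rate, t, window_s)
    except WindowError:
        return False
    return np.isfinite(signals.pupil[sl]).mean() >= MIN_PUPIL_COVERAGE


def habituation_features(
    signals: ProcessedSignals,
    events: CleanEventList,
    participant_id: str = "",
    window_s: float = WINDOW_S,
) -> FeatureVector:
    """First-minus-last window features for every qualifying event type.

    Returns an empty vector (logged) when no event type has two valid
    occurrences — such participants are excluded at assembly time.
    """
    values: dict[FeatureKey, float] = {}
    for event_type, times in events.by_type().items():
        valid = [t for t in times if _valid_occurrence(signals, t, window_s)]
        if len(valid) < len(times):
            log.info(
                "%s/%s: %d occurrence(s) invalid (window overrun or pupil dropout)",
                participant_id, event_type, len(times) - len(valid),
            )
        if len(valid) < 2:
            continue
        t0, t_last = valid[0], valid[-1]
        for channel, series in (("phasic", signals.phasic), ("hr", signals.hr)):
            for stat in ("max", "min", "mean"):
                key = FeatureKey(event_type, f"{stat}_{channel}")
                values[key] = window_stat(
                    series, t0, stat, signals.rate, window_s
                ) - window_stat(series, t_last, stat, signals.rate, window_s)
        values[FeatureKey(event_type, "ebp")] = float(
            ebp(signals.pupil, t0, signals.rate, window_s)
            - ebp(signals.pupil, t_last, signals.rate, window_s)
        )
    if not values:
        log.warning("participant %s: no event type with >= 2 valid occurrences", participant_id)
    return FeatureVector(participant_id=participant_id, values=values, window_s=window_s)


def assemble_cohort(
    vectors: Iterable[FeatureVector],
    pclm_scores: Mapping[str, int],
    label_threshold: int = 36,
) -> CohortMatrix:
    """Stack per-participant feature vectors into the cohort matrix.

    Columns are the union of feature keys in canonical order (event type,
    then marker); a cell is NaN when that participant lacked the key —
    imputation happens inside each cross-validation fold, never here.
    Participants with empty vectors are dropped with a logged reason.
    """
    rows = {}
    for vec in vectors:
        if len(vec) == 0:
            log.warning("dropping participant %s: empty feature vector", vec.participant_id)
            continue
        rows[vec.participant_id] = {str(k): v for k, v in vec.values.items()}
    if len(rows) < 4:
        raise ValueError(f"only {len(rows)} usable participants; need at least 4")
    X = pd.DataFrame.from_dict(rows, orient="index")
    cols = sorted(X.columns, key=lambda c: FeatureKey.parse(c).sort_index)
    X = X[cols]
    pclm = pd.Series({pid: int(pclm_scores[pid]) for pid in X.index}, name="pclm")
    labels = (pclm > label_threshold).rename("label")
    return CohortMatrix(X=X, pclm_scores=pclm, labels=labels)
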