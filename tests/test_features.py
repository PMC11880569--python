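"""Habituation feature math: window statistics, eye-blink proxy,
first-minus-last differences, cohort assembly."""

import numpy as np
import pytest

from habitu.features import (
    FeatureKey,
    FeatureVector,
    WindowError,
    assemble_cohort,
    ebp,
    habituation_features,
    window_stat,
)
from habitu.signal_prep import CleanEventList, ProcessedSignals


def make_signals(n=320 * 2, phasic=None, hr=None, pupil=None) -> ProcessedSignals:
    return ProcessedSignals(
        hr=np.full(n, 60.0) if hr is None else hr,
        phasic=np.zeros(n) if phasic is None else phasic,
        pupil=np.full(n, 4.0) if pupil is None else pupil,
    )


class TestWindowStat:
    @pytest.mark.parametrize("stat", ["max", "min", "mean"])
    def test_constant(self, stat):
        assert window_stat(np.full(320, 3.0), 0.0, stat) == 3.0

    def test_mean_of_index_ramp(self):
        series = np.arange(640, dtype=float)
        assert window_stat(series, 0.0, "mean") == 79.5

    def test_window_overrun_raises(self):
        with pytest.raises(WindowError):
            window_stat(np.zeros(320), 6.0, "max")

    def test_low_coverage_raises(self):
        series = np.full(320, 1.0)
        series[:40] = np.nan  # 25% of the first window missing
        with pytest.raises(WindowError):
            window_stat(series, 0.0, "mean")
        series[:30] = 1.0  # back above 80% coverage
        assert window_stat(series, 0.0, "mean") == 1.0


class TestEbp:
    def test_counts(self):
        pupil = np.full(640, 4.0)
        assert ebp(pupil, 0.0) == 0
        pupil[:160] = np.nan
        assert ebp(pupil, 0.0) == 160
        pupil2 = np.full(640, 4.0)
        pupil2[10:18] = np.nan  # 8-sample blink
        pupil2[100:105] = np.nan  # 5-sample blink
        assert ebp(pupil2, 0.0) == 13


class TestHabituationFeatures:
    def test_identical_windows_give_zero(self):
        n = 320 * 3
        phasic, pupil = np.zeros(n), np.full(n, 4.0)
        bump = np.r_[np.linspace(0, 0.8, 32), np.linspace(0.8, 0, 32)]
        for t in (5.0, 20.0):
            i = int(t * 32)
            phasic[i : i + 64] += bump
            pupil[i + 32 : i + 40] = np.nan
        signals = make_signals(n, phasic=phasic, pupil=pupil)
        events = CleanEventList([("boom", 5.0), ("boom", 20.0)])
        fv = habituation_features(signals, events)
        assert len(fv) == 7
        assert all(v == 0.0 for v in fv.values.values())

    def test_phasic_max_difference(self):
        n = 320 * 3
        phasic = np.zeros(n)
        phasic[int(5.5 * 32)] = 0.8
        phasic[int(20.5 * 32)] = 0.3
        signals = make_signals(n, phasic=phasic)
        fv = habituation_features(signals, CleanEventList([("boom", 5.0), ("boom", 20.0)]))
        assert fv.values[FeatureKey("boom", "max_phasic")] == pytest.approx(0.5)

    def test_single_occurrence_type_absent(self):
        signals = make_signals(320 * 3)
        fv = habituation_features(
            signals, CleanEventList([("boom", 5.0), ("boom", 20.0), ("lone", 12.0)])
        )
        assert {k.event_type for k in fv.values} == {"boom"}

    def test_empty_when_no_type_qualifies(self):
        fv = habituation_features(make_signals(320), CleanEventList([("lone", 1.0)]))
        assert len(fv) == 0

    def test_intermediate_occurrences_ignored(self):
        n = 320 * 4
        phasic = np.zeros(n)
        for t, amp in [(5.0, 0.9), (15.0, 55.0), (30.0, 0.4)]:
            phasic[int((t + 1) * 32)] = amp
        fv = habituation_features(
            make_signals(n, phasic=phasic),
            CleanEventList([("boom", 5.0), ("boom", 15.0), ("boom", 30.0)]),
        )
        assert fv.values[FeatureKey("boom", "max_phasic")] == pytest.approx(0.5)

    def test_invalid_occurrence_recomputes_endpoints(self):
        """An occurrence with heavy pupil dropout is skipped; last valid wins."""
        n = 320 * 5
        phasic = np.zeros(n)
        for t, amp in [(5.0, 0.9), (20.0, 0.6), (40.0, 0.2)]:
            phasic[int((t + 1) * 32)] = amp
        pupil = np.full(n, 4.0)
        pupil[int(40 * 32) : int(45 * 32)] = np.nan  # third occurrence invalid
        fv = habituation_features(
            make_signals(n, phasic=phasic, pupil=pupil),
            CleanEventList([("boom", 5.0), ("boom", 20.0), ("boom", 40.0)]),
        )
        assert fv.values[FeatureKey("boom", "max_phasic")] == pytest.approx(0.3)

    def test_locality(self):
        """Edits outside the first/last 5-s windows leave features unchanged."""
        n = 320 * 4
        rng = np.random.default_rng(2)
        phasic = rng.random(n)
        events = CleanEventList([("boom", 10.0), ("boom", 30.0)])
        base = habituation_features(make_signals(n, phasic=phasic.copy()), events)
        phasic[int(18 * 32) : int(25 * 32)] += 100.0  # between the windows
        phasic[: int(8 * 32)] -= 50.0  # before the first
        edited = habituation_features(make_signals(n, phasic=phasic), events)
        for k in base.values:
            assert edited.values[k] == base.values[k]

    def test_nonfinite_feature_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector("p", {FeatureKey("a", "max_hr"): np.nan})


class TestAssembleCohort:
    def _vec(self, pid, keys_vals):
        return FeatureVector(pid, {FeatureKey(*k): v for k, v in keys_vals.items()})

    def test_dense_matrix_and_canonical_order(self):
        vecs = [
            self._vec("a", {("boom", "max_hr"): 1.0, ("boom", "max_phasic"): 2.0}),
            self._vec("b", {("boom", "max_hr"): 3.0, ("boom", "max_phasic"): 4.0}),
            self._vec("c", {("boom", "max_hr"): 5.0, ("boom", "max_phasic"): 6.0}),
            self._vec("d", {("boom", "max_hr"): 7.0, ("boom", "max_phasic"): 8.0}),
        ]
        cm = assemble_cohort(vecs, {"a": 40, "b": 30, "c": 50, "d": 20})
        assert not cm.X.isna().any().any()
        assert list(cm.X.columns) == ["boom/max_phasic", "boom/max_hr"]
        assert cm.labels.tolist() == [True, False, True, False]

    def test_missing_cell_is_nan_not_zero(self):
        vecs = [
            self._vec("a", {("boom", "max_hr"): 1.0, ("bark", "max_hr"): 2.0}),
            self._vec("b", {("boom", "max_hr"): 3.0}),
            self._vec("c", {("boom", "max_hr"): 5.0, ("bark", "max_hr"): 1.0}),
            self._vec("d", {("boom", "max_hr"): 7.0, ("bark", "max_hr"): 0.5}),
        ]
        cm = assemble_cohort(vecs, {"a": 40, "b": 30, "c": 50, "d": 20})
        assert np.isnan(cm.X.loc["b", "bark/max_hr"])

    def test_empty_vectors_dropped_and_minimum_enforced(self):
        vecs = [self._vec(p, {("boom", "ebp"): 1.0}) for p in "abc"]
        vecs.append(FeatureVector("empty", {}))
        with pytest.raises(ValueError, match="at least 4"):
            assemble_cohort(vecs, {"a": 40, "b": 30, "c": 50, "empty": 20})
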