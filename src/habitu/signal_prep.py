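"""Raw-recording preprocessing: ECG -> heart rate, EDA -> tonic/phasic,
anti-aliased downsampling to the common 32 Hz analysis rate, and event-list
cleaning.

The three analysis series (heart rate in beats/min, phasic skin conductance
in microsiemens, pupil diameter in mm with NaN marking blinks/dropout) all
end up sampled at ``TARGET_RATE_HZ`` and trimmed to a common length.

Electrodermal decomposition is performed *after* downsampling: the convex
program scales with sample count, and the downstream habituation features
are 5-second window statistics that are insensitive to the ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import numpy as np
import scipy.fft
import scipy.optimize
import scipy.signal
import scipy.sparse

from .kernels import bateman_kernel

log = logging.getLogger(__name__)

TARGET_RATE_HZ = 32.0

# Physiologically plausible inter-beat-interval bounds, seconds.  Intervals
# outside these bounds are treated as detection artefacts and corrected.
IBI_MIN_S = 0.33
IBI_MAX_S = 2.0


class SignalError(ValueError):
    """A physiological channel cannot be processed."""


@dataclass
class Channel:
    """A uniformly sampled signal; NaN samples mark missing data."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


@dataclass
class RawRecording:
    """Multichannel raw session: ECG + skin conductance at 2048 Hz,
    pupil diameter at 300 Hz (NaN = blink / tracking dropout)."""

    ecg: Channel
    gsr: Channel
    pupil: Channel

    def __post_init__(self) -> None:
        durs = [self.ecg.duration, self.gsr.duration, self.pupil.duration]
        rates = [self.ecg.rate, self.gsr.rate, self.pupil.rate]
        tol = max(1.0 / r for r in rates)
        if max(durs) - min(durs) > tol:
            raise ValueError(
                f"channels cover different time spans: {durs} (tolerance {tol:.4f} s)"
            )

    @property
    def duration(self) -> float:
        return min(self.ecg.duration, self.gsr.duration, self.pupil.duration)


@dataclass
class ProcessedSignals:
    """The three 32 Hz analysis series, equal length."""

    hr: np.ndarray
    phasic: np.ndarray
    pupil: np.ndarray
    rate: float = TARGET_RATE_HZ
    tonic: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = {len(self.hr), len(self.phasic), len(self.pupil)}
        if len(n) != 1:
            raise ValueError(f"series lengths differ: {sorted(n)}")

    @property
    def n_samples(self) -> int:
        return len(self.hr)

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class CleanEventList:
    """Time-sorted stimulus occurrences with withdrawal events removed."""

    occurrences: list[tuple[str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.occurrences)

    def by_type(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for name, t in self.occurrences:
            out.setdefault(name, []).append(t)
        return out


# ---------------------------------------------------------------------------
# ECG -> heart rate


def detect_r_peaks(ecg: Channel, height_frac: float = 0.5) -> np.ndarray:
    """R-peak sample indices via thresholded local-maximum detection.

    The height threshold is a fraction of the 99.9th amplitude percentile,
    which rejects T waves and baseline noise; the minimum peak distance is
    kept short (50 ms) so that detection artefacts are *found* here and
    corrected downstream by the inter-beat-interval rules rather than
    silently suppressed.
    """
    x = ecg.samples
    ref = np.percentile(x, 99.9)
    peaks, _ = scipy.signal.find_peaks(
        x, height=height_frac * ref, distance=max(1, int(0.05 * ecg.rate))
    )
    return peaks


def ecg_to_hr(ecg: Channel) -> Channel:
    """Instantaneous heart rate (beats/min) at the ECG's native rate.

    R-peaks are detected, implausible inter-beat intervals (outside
    [0.33, 2.0] s) are corrected — spuriously short intervals by dropping
    the offending peak, overlong ones by interpolating the rate across the
    gap — and 60/IBI is linearly interpolated onto the full time grid
    (held constant before the first and after the last beat).
    """
    if ecg.duration < 10.0:
        raise SignalError("need at least 10 s of ECG")
    peaks = detect_r_peaks(ecg)
    if len(peaks) < 5:
        raise SignalError(f"only {len(peaks)} R-peaks detected; ECG unusable")

    beat_t = peaks / ecg.rate
    # drop peaks creating implausibly short intervals (double detections)
    keep = [0]
    for i in range(1, len(beat_t)):
        if beat_t[i] - beat_t[keep[-1]] >= IBI_MIN_S:
            keep.append(i)
    beat_t = beat_t[keep]
    if len(beat_t) < 5:
        raise SignalError("fewer than 5 plausible beats after correction")

    ibi = np.diff(beat_t)
    hr_beats = 60.0 / ibi
    t_mid = beat_t[1:]
    valid = ibi <= IBI_MAX_S
    if not valid.any():
        raise SignalError("no plausible inter-beat interval")
    if not valid.all():  # missed beats: interpolate rate across the gap
        hr_beats = np.interp(t_mid, t_mid[valid], hr_beats[valid])

    t = ecg.times()
    return Channel(np.interp(t, t_mid, hr_beats), ecg.rate)


# ---------------------------------------------------------------------------
# Electrodermal decomposition


@dataclass
class EDADecomposition:
    tonic: np.ndarray
    phasic: np.ndarray
    driver: np.ndarray  # nonnegative sparse sudomotor driver
    residual: np.ndarray


def decompose_eda(
    gsr: Channel,
    *,
    alpha: float = 0.1,
    smooth_lambda: float = 10.0,
    knot_spacing_s: float = 10.0,
    driver_rate: float = 8.0,
    max_iter: int = 300,
) -> EDADecomposition:
    """Split skin conductance into smooth tonic and sparse-driven phasic.

    Solves the convex program

        min_{q >= 0, c}  0.5*||y - K q - B c||^2 + alpha*sum(q)
                         + 0.5*smooth_lambda*||D2 c||^2

    where ``K`` convolves the nonnegative driver ``q`` with a Bateman
    biexponential SCR kernel, ``B`` interpolates tonic knot values ``c``
    placed every `knot_spacing_s` seconds, and ``D2`` is the second
    difference (curvature) operator on the knots.  The L1 term makes the
    driver sparse; it is linear because of the nonnegativity bound, so the
    whole problem is a smooth bound-constrained QP solved with L-BFGS-B.
    The driver lives on a coarser grid (`driver_rate`, default 8 Hz =
    0.125 s resolution, well below the 0.5 s peak-time accuracy the
    downstream features need) and is zero-stuffed to the signal rate
    before convolution.

    Returns tonic, phasic (= K q), driver and residual series at the input
    rate.  Raises :class:`SignalError` on non-finite input or failure to
    converge.
    """
    y = gsr.samples
    if not np.isfinite(y).all():
        raise SignalError("non-finite skin-conductance input")
    n = len(y)
    fs = gsr.rate
    if n < 10 * fs:
        raise SignalError("need at least 10 s of skin conductance")

    kern = bateman_kernel(fs)
    nk = len(kern)
    nfft = scipy.fft.next_fast_len(n + nk - 1)
    kern_f = scipy.fft.rfft(kern, nfft)
    # driver on a coarse grid, zero-stuffed to the signal rate
    stride = max(1, int(round(fs / driver_rate)))
    nq = -(-n // stride)  # ceil

    # linear-interpolation tonic basis on a coarse knot grid
    knot_t = np.arange(0.0, n / fs + knot_spacing_s, knot_spacing_s)
    nknot = len(knot_t)
    t = np.arange(n) / fs
    pos = np.clip(t / knot_spacing_s, 0, nknot - 1 - 1e-9)
    i0 = pos.astype(int)
    w1 = pos - i0
    B = scipy.sparse.csr_matrix(
        (
            np.concatenate([1.0 - w1, w1]),
            (np.concatenate([np.arange(n)] * 2), np.concatenate([i0, i0 + 1])),
        ),
        shape=(n, nknot),
    )
    D2 = scipy.sparse.diags(
        [np.ones(nknot - 2), -2 * np.ones(nknot - 2), np.ones(nknot - 2)],
        offsets=[0, 1, 2],
        shape=(nknot - 2, nknot),
    ).tocsr()

    def conv(q: np.ndarray) -> np.ndarray:
        # K U q: zero-stuffed driver convolved with the SCR kernel
        qf = np.zeros(n)
        qf[::stride] = q
        return scipy.fft.irfft(scipy.fft.rfft(qf, nfft) * kern_f, nfft)[:n]

    def conv_t(r: np.ndarray) -> np.ndarray:
        # U^T K^T r: cross-correlation with the kernel, on the coarse grid
        full = scipy.fft.irfft(scipy.fft.rfft(r, nfft) * kern_f.conj(), nfft)[:n]
        return full[::stride]

    def objective(z: np.ndarray) -> tuple[float, np.ndarray]:
        q, c = z[:nq], z[nq:]
        r = conv(q) + B @ c - y
        d2c = D2 @ c
        f = 0.5 * r @ r + alpha * q.sum() + 0.5 * smooth_lambda * d2c @ d2c
        gq = conv_t(r) + alpha
        gc = B.T @ r + smooth_lambda * (D2.T @ d2c)
        return f, np.concatenate([gq, gc])

    z0 = np.concatenate([np.zeros(nq), np.interp(knot_t, t, y)])
    bounds = [(0.0, None)] * nq + [(None, None)] * nknot
    res = scipy.optimize.minimize(
        objective,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-11, "maxcor": 8},
    )
    if not res.success and "ITERATIONS" not in str(res.message).upper():
        raise SignalError(f"EDA decomposition failed to converge: {res.message}")

    q, c = res.x[:nq], res.x[nq:]
    phasic = conv(q)
    tonic = np.asarray(B @ c)
    driver = np.zeros(n)
    driver[::stride] = q
    return EDADecomposition(tonic=tonic, phasic=phasic, driver=driver, residual=y - tonic - phasic)


# ---------------------------------------------------------------------------
# Downsampling


def _resample_factors(rate: float, target: float) -> tuple[int, int]:
    frac = Fraction(target / rate).limit_denominator(10_000)
    return frac.numerator, frac.denominator


def downsample(x: np.ndarray | Channel, rate: float | None = None, target: float = TARGET_RATE_HZ) -> np.ndarray:
    """Anti-aliased polyphase decimation to `target` Hz.

    NaN (missing) samples are linearly bridged before filtering, and an
    output sample is marked missing iff a strict majority of its source
    window is missing.  Output length is ``floor(duration * target)``.
    """
    if isinstance(x, Channel):
        rate = x.rate
        x = x.samples
    if rate is None:
        raise TypeError("rate required when passing a bare array")
    if rate < target:
        raise ValueError(f"input rate {rate} Hz below target {target} Hz")
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_out = int(np.floor(n / rate * target))

    missing = np.isnan(x)
    xf = x
    if missing.any():
        if missing.all():
            return np.full(n_out, np.nan)
        idx = np.arange(n)
        xf = x.copy()
        xf[missing] = np.interp(idx[missing], idx[~missing], x[~missing])

    up, down = _resample_factors(rate, target)
    y = scipy.signal.resample_poly(xf, up, down, padtype="line")
    y = y[:n_out]
    if len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")

    if missing.any():
        win = np.minimum((np.arange(n) / rate * target).astype(int), n_out - 1)
        frac_missing = np.bincount(win, weights=missing, minlength=n_out) / np.bincount(
            win, minlength=n_out
        )
        y[frac_missing > 0.5] = np.nan
    return y


# ---------------------------------------------------------------------------
# Event cleaning


def clean_events(
    events: Iterable, duration: float | None = None
) -> CleanEventList:
    """Drop zone-withdrawal occurrences and sort the rest by time.

    Accepts either ``EventSpec``-like objects (``name``, ``is_withdrawal``,
    ``occurrence_times``) or bare ``(event_type, time_s)`` pairs (optionally
    with a trailing is_withdrawal flag).  Occurrences outside the recording
    span are dropped with a log message; occurrences whose 5-s window would
    overrun the recording are kept here and policed by the feature stage.
    """
    occ: list[tuple[str, float]] = []
    for ev in events:
        if hasattr(ev, "occurrence_times"):
            if ev.is_withdrawal:
                continue
            occ.extend((ev.name, float(t)) for t in ev.occurrence_times)
        else:
            ev = tuple(ev)
            if len(ev) > 2 and bool(ev[2]):
                continue
            occ.append((str(ev[0]), float(ev[1])))
    if duration is not None:
        kept = [(n, t) for n, t in occ if 0.0 <= t < duration]
        if len(kept) < len(occ):
            log.warning("dropped %d event(s) outside recording span", len(occ) - len(kept))
        occ = kept
    occ.sort(key=lambda p: (p[1], p[0]))
    return CleanEventList(occ)


# ---------------------------------------------------------------------------
# Full per-participant preprocessing


def process_recording(recording: RawRecording, **eda_kwargs) -> ProcessedSignals:
    """Raw channels -> aligned 32 Hz heart rate, phasic EDA and pupil series."""
    hr = downsample(ecg_to_hr(recording.ecg))
    gsr32 = downsample(recording.gsr)
    eda = decompose_eda(Channel(gsr32, TARGET_RATE_HZ), **eda_kwargs)
    pupil = downsample(recording.pupil)
    n = min(len(hr), len(eda.phasic), len(pupil))
    return ProcessedSignals(
        hr=hr[:n], phasic=eda.phasic[:n], pupil=pupil[:n], tonic=eda.tonic[:n]
    )
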