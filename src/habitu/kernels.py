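"""Event-locked response kernel shapes.

Two families live here:

* compact-support kernels used by the synthetic generator (an SCR-like
  skin-conductance transient and a raised-cosine heart-rate bump).  Their
  support is strictly shorter than the generator's minimum inter-event gap,
  so responses to consecutive events never overlap and window statistics
  recover injected amplitudes exactly.
* the Bateman (two-exponential) kernel used by the electrodermal
  decomposition.  It is deliberately a *different* shape from the
  generator's SCR kernel, so the decomposition is exercised under realistic
  model mismatch.

All kernels are sampled on a regular grid and peak-normalised on that grid,
which makes the sampled maximum exactly 1.0 at a grid point.
"""

from __future__ import annotations

import numpy as np

#: support of the synthetic SCR kernel, seconds.  Must not exceed the
#: generator's minimum inter-event gap (6 s).
SCR_SUPPORT_S = 6.0

#: support of the synthetic heart-rate bump, seconds.
HR_BUMP_SUPPORT_S = 4.0


def scr_kernel(rate: float, tau: float = 1.5, support: float = SCR_SUPPORT_S) -> np.ndarray:
    """Sampled skin-conductance-response kernel, peak-normalised.

    Shape is ``t * exp(-t/tau) * sin(pi * t / support)``: a gamma-like rise
    (peak ~1.4 s, within the 1-5 s physiological SCR latency) tapered
    smoothly to zero at ``support`` seconds so the kernel has compact
    support.  Nonnegative on [0, support).
    """
    t = np.arange(int(round(support * rate))) / rate
    k = t * np.exp(-t / tau) * np.sin(np.pi * t / support)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate SCR kernel (rate too low?)")
    return k / peak


def hr_bump_kernel(rate: float, support: float = HR_BUMP_SUPPORT_S) -> np.ndarray:
    """Raised-cosine heart-rate transient: 0.5*(1 - cos(2*pi*t/support)).

    Peaks at support/2 with value exactly 1 (a grid point whenever
    ``rate * support / 2`` is an integer), zero at both ends.
    """
    t = np.arange(int(round(support * rate))) / rate
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / support))


def bateman_kernel(
    rate: float, tau_fast: float = 0.7, tau_slow: float = 3.0, support: float = 15.0
) -> np.ndarray:
    """Bateman biexponential SCR model, ``exp(-t/tau_slow) - exp(-t/tau_fast)``.

    The canonical kernel for sparse-driver electrodermal deconvolution.
    Truncated at `support` seconds and peak-normalised.
    """
    if tau_slow <= tau_fast:
        raise ValueError("tau_slow must exceed tau_fast")
    t = np.arange(int(round(support * rate))) / rate
    k = np.exp(-t / tau_slow) - np.exp(-t / tau_fast)
    return k / k.max()
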