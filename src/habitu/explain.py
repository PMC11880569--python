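"""Model-agnostic Shapley attributions, global importance rankings, and the
individual habituation response.

Attributions are computed on the classifier's PTSD probability output with
the fold's *training* rows as the background distribution (the only
leakage-free choice under leave-one-out).  A coalition's value is the mean
model output over background rows with the coalition's features replaced
by the explained participant's values ("interventional" Shapley).  With at
most `EXACT_LIMIT` features the full coalition lattice is enumerated —
exact Shapley values; above that, a seeded permutation-sampling estimator
is used.  Both satisfy the additivity identity

    base_value + sum_i phi_i = model_output(x)

exactly (per permutation the marginal contributions telescope), which is
asserted after every estimation.

The individual habituation response aggregates a participant's *raw*
(unscaled) habituation feature values, weighted by the absolute
attribution of each selected feature:  response = sum_i x_i * |w_i|.
Positive values mean the participant's physiology predominantly habituated
to repeated stimuli; negative values mean sensitization.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.stats

from .model import FoldResult

EXACT_LIMIT = 12
ADDITIVITY_RTOL = 1e-6


class AttributionError(RuntimeError):
    """Shapley estimation failed its additivity check."""


@dataclass
class AttributionVector:
    participant_id: str
    phi: dict[str, float]  # feature key -> Shapley value (w_i)
    base_value: float  # mean model output over the background
    model_output: float


@dataclass
class GlobalImportance:
    """Cumulative |phi| per feature key and per physiological marker group."""

    per_key: dict[str, float]  # descending
    per_marker: dict[str, float]  # descending


@dataclass
class HabituationResponse:
    participant_id: str
    value: float  # sum_i x_i * |w_i|
    pclm_score: int


@dataclass
class ResponseRegression:
    slope: float
    intercept: float
    correlation: float


# ---------------------------------------------------------------------------
# Shapley estimation


def _coalition_values(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    masks: np.ndarray,
) -> np.ndarray:
    """Mean model output over the background for each boolean mask row."""
    n_bg, m = background.shape
    hybrids = np.where(masks[:, None, :], x[None, None, :], background[None, :, :])
    out = f(hybrids.reshape(-1, m))
    return out.reshape(len(masks), n_bg).mean(axis=1)


def shapley_exact(
    f: Callable[[np.ndarray], np.ndarray], x: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values by full coalition enumeration."""
    m = len(x)
    masks = np.zeros((2**m, m), dtype=bool)
    for code in range(2**m):
        for j in range(m):
            masks[code, j] = bool(code >> j & 1)
    v = _coalition_values(f, x, background, masks)

    weights = np.array(
        [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
    )
    phi = np.zeros(m)
    sizes = masks.sum(axis=1)
    for code in range(2**m):
        s = sizes[code]
        for j in range(m):
            if not code >> j & 1:
                phi[j] += weights[s] * (v[code | (1 << j)] - v[code])
    return phi, float(v[0])


def shapley_sampled(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 128,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley estimator (antithetic pairs).

    For each sampled permutation the features are added one by one and the
    marginal changes in coalition value are credited to the added feature;
    contributions telescope to ``f(x) - base`` exactly, so additivity holds
    for the averaged estimate as well.
    """
    rng = rng or np.random.default_rng()
    m = len(x)
    perms = []
    for _ in range(max(1, n_permutations // 2)):
        p = rng.permutation(m)
        perms.extend([p, p[::-1]])

    masks = np.zeros((len(perms) * (m + 1), m), dtype=bool)
    row = 0
    for p in perms:
        cur = np.zeros(m, dtype=bool)
        masks[row] = cur
        for j in p:
            cur = cur.copy()
            cur[j] = True
            row += 1
            masks[row] = cur
        row += 1
    v = _coalition_values(f, x, background, masks)

    phi = np.zeros(m)
    base_acc = 0.0
    row = 0
    for p in perms:
        base_acc += v[row]
        for step, j in enumerate(p):
            phi[j] += v[row + step + 1] - v[row + step]
        row += m + 1
    phi /= len(perms)
    return phi, base_acc / len(perms)


def attribute(
    fold: FoldResult,
    *,
    n_permutations: int = 128,
    rng: np.random.Generator | None = None,
    exact_limit: int = EXACT_LIMIT,
) -> AttributionVector:
    """Shapley attributions for one leave-one-out fold's held-out row."""
    model = fold.model
    keys = fold.selected_keys
    x = fold.x_test_scaled.to_numpy(dtype=float)
    background = fold.X_train_scaled.to_numpy(dtype=float)
    if background.size == 0:
        raise ValueError("background (training rows) must be nonempty")

    def f(X: np.ndarray) -> np.ndarray:
        return model.predict_proba(X)[:, 1]

    if len(keys) <= exact_limit:
        phi, base = shapley_exact(f, x, background)
    else:
        phi, base = shapley_sampled(f, x, background, n_permutations, rng)

    out = float(f(x[None, :])[0])
    gap = abs(base + phi.sum() - out)
    if gap > ADDITIVITY_RTOL * max(1.0, abs(out)):
        raise AttributionError(
            f"additivity violated for {fold.held_out_id}: |base + sum(phi) - f(x)| = {gap:.3e}"
        )
    return AttributionVector(
        participant_id=fold.held_out_id,
        phi=dict(zip(keys, phi.tolist())),
        base_value=base,
        model_output=out,
    )


# ---------------------------------------------------------------------------
# Aggregation


def global_ranking(attributions: Iterable[AttributionVector]) -> GlobalImportance:
    """Cumulative absolute importance across participants, per feature key
    and grouped by physiological marker (max_hr, ebp, ...)."""
    attributions = list(attributions)
    if not attributions:
        raise ValueError("need at least one attribution")
    per_key: dict[str, float] = {}
    for att in attributions:
        for key, w in att.phi.items():
            per_key[key] = per_key.get(key, 0.0) + abs(w)
    per_marker: dict[str, float] = {}
    for key, total in per_key.items():
        marker = key.rsplit("/", 1)[-1]
        per_marker[marker] = per_marker.get(marker, 0.0) + total
    desc = lambda d: dict(sorted(d.items(), key=lambda kv: -kv[1]))
    return GlobalImportance(per_key=desc(per_key), per_marker=desc(per_marker))


def habituation_response(
    x_raw: Mapping[str, float],
    attribution: AttributionVector,
    pclm_score: int,
) -> HabituationResponse:
    """Individual habituation response: sum_i x_i * |w_i| over the fold's
    selected features, with x_i the raw (unscaled) habituation values."""
    if set(x_raw) != set(attribution.phi):
        missing = set(attribution.phi) ^ set(x_raw)
        raise KeyError(f"feature keys do not align; mismatched: {sorted(missing)}")
    value = sum(x_raw[k] * abs(w) for k, w in attribution.phi.items())
    return HabituationResponse(
        participant_id=attribution.participant_id, value=float(value), pclm_score=pclm_score
    )


def response_vs_pclm(responses: Sequence[HabituationResponse]) -> ResponseRegression:
    """OLS regression of PCL-M score on the habituation response.

    A positive slope means stronger habituators report higher PCL-M scores.
    """
    if len(responses) < 3:
        raise ValueError("need at least 3 participants for the regression")
    x = np.array([r.value for r in responses])
    y = np.array([r.pclm_score for r in responses], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in habituation responses")
    res = scipy.stats.linregress(x, y)
    return ResponseRegression(
        slope=float(res.slope), intercept=float(res.intercept), correlation=float(res.rvalue)
    )
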