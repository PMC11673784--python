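"""Optimal dichotomization of risk scores by maximally selected log-rank
statistics, and transfer of a trained threshold to validation cohorts.

The cut-point search evaluates the absolute standardized two-group
log-rank statistic at every candidate cut (midpoints between consecutive
distinct ordered scores whose split proportions fall inside a window) and
returns the argmax. Because the maximum over many correlated candidates
inflates the naive p-value, inference uses a permutation test by default
(scores permuted against the (time, event) pairs, re-maximizing each
permutation); the Lausen-Schumacher asymptotic approximation is available
as a cheaper alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logrank import logrank_z

__all__ = ["MaxstatResult", "maxstat_cutpoint", "dichotomize",
           "transfer_threshold"]


@dataclass
class MaxstatResult:
    """Outcome of a maximally selected log-rank cut-point search."""

    cutpoint: float
    statistic: float                 # max over candidates of |Z|
    candidates: pd.DataFrame         # candidate, n_low, n_high, statistic
    p_value: float
    p_method: str
    group_labels: np.ndarray         # "low"/"high" per patient
    min_prop: float
    max_prop: float


def _candidate_cuts(scores: np.ndarray, min_prop: float, max_prop: float
                    ) -> np.ndarray:
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("scores are all equal; no cut-point exists")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = scores.size
    prop_low = np.searchsorted(np.sort(scores), mids, side="right") / n
    ok = (prop_low >= min_prop) & (prop_low <= max_prop)
    if not ok.any():
        raise ValueError(
            f"no candidate cut-point satisfies the proportion window "
            f"[{min_prop}, {max_prop}]")
    return mids[ok]


def _max_abs_z(times: np.ndarray, events: np.ndarray, scores: np.ndarray,
               cuts: np.ndarray) -> np.ndarray:
    """|Z| for each candidate cut (group 1 = score above the cut)."""
    G = scores[None, :] > cuts[:, None]
    _, _, z = logrank_z(times, events, G)
    return np.abs(z)


def maxstat_cutpoint(scores, times, events, min_prop: float = 0.1,
                     max_prop: float = 0.9, p_method: str = "permutation",
                     n_perm: int = 1000, seed: int = 0) -> MaxstatResult:
    """Find the score cut maximizing the standardized log-rank statistic.

    Candidates are midpoints between consecutive distinct ordered scores
    whose low-group proportions lie in ``[min_prop, max_prop]``. Ties in
    the maximum resolve to the smallest candidate. ``p_method`` is
    ``"permutation"`` (exact in distribution; re-maximizes every
    permutation), ``"lausen"`` (asymptotic approximation for the maximally
    selected statistic) or ``"none"``.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if scores.size < 10:
        raise ValueError("need at least 10 patients")
    if events.sum() < 2:
        raise ValueError("need at least 2 events")
    cuts = _candidate_cuts(scores, min_prop, max_prop)
    absz = _max_abs_z(times, events, scores, cuts)
    top = absz.max()
    # exact ties resolve to the smallest candidate, robust to float noise
    best = int(np.flatnonzero(absz >= top * (1 - 1e-12))[0])
    statistic = float(absz[best])
    cutpoint = float(cuts[best])
    n_high = (scores[None, :] > cuts[:, None]).sum(axis=1)
    cand_table = pd.DataFrame({"candidate": cuts,
                               "n_low": scores.size - n_high,
                               "n_high": n_high,
                               "statistic": absz})
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        n = scores.size
        # batch all permutations x candidates through the log-rank kernel
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        G = scores[perms][:, None, :] > cuts[None, :, None]   # (B, C, n)
        _, _, z = logrank_z(times, events, G.reshape(-1, n))
        perm_max = np.abs(z).reshape(n_perm, cuts.size).max(axis=1)
        p_value = float((1 + np.sum(perm_max >= statistic)) / (1 + n_perm))
    elif p_method == "lausen":
        p_value = _p_lausen(statistic, min_prop, max_prop)
    elif p_method == "none":
        p_value = float("nan")
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    labels = dichotomize(scores, cutpoint)
    return MaxstatResult(cutpoint, statistic, cand_table, p_value, p_method,
                         labels, min_prop, max_prop)


def _p_lausen(b: float, min_prop: float, max_prop: float) -> float:
    """Lausen-Schumacher (1992) approximation for the maximally selected
    standardized statistic restricted to a proportion window."""
    if b <= 0:
        return 1.0
    db = stats.norm.pdf(b)
    span = np.log((max_prop * (1 - min_prop)) / (min_prop * (1 - max_prop)))
    p = 4 * db / b + db * (b - 1.0 / b) * span
    return float(min(1.0, max(p, 2 * stats.norm.sf(b))))


def dichotomize(scores, cutpoint: float) -> np.ndarray:
    """Label each patient ``high`` iff score > cutpoint, else ``low``.

    Empty groups are permitted (the situation arises when a trained
    threshold is transferred to a shifted cohort) but trigger a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(cutpoint):
        raise ValueError("cutpoint must be finite")
    labels = np.where(scores > cutpoint, "high", "low")
    for side in ("low", "high"):
        if not np.any(labels == side):
            warnings.warn(f"dichotomization produced an empty {side!r} group")
    return labels


def transfer_threshold(training: MaxstatResult | float, validation_scores
                       ) -> np.ndarray:
    """Apply a training cut-point to validation scores without re-optimizing."""
    cut = training.cutpoint if isinstance(training, MaxstatResult) else float(training)
    return dichotomize(validation_scores, cut)


def stratification_frame(patient_ids, scores, labels) -> pd.DataFrame:
    return pd.DataFrame({"patient_id": patient_ids, "score": scores,
                         "group": labels})
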