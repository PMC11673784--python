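"""Two-group log-rank kernel, vectorized over many candidate group vectors.

The same standardized statistic is used by the log-rank test (its square is
the 1-df chi-square) and by maximally selected cut-point search, which
evaluates it for every candidate split and every permutation at once.
"""

from __future__ import annotations

import numpy as np


def logrank_z(times: np.ndarray, events: np.ndarray,
              groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized two-group log-rank statistic for a batch of group labels.

    Parameters
    ----------
    times, events:
        Length-n arrays of follow-up times and event indicators.
    groups:
        Boolean array of shape (B, n); each row indicates membership of
        "group 1" for one labelling of the same cohort.

    Returns
    -------
    (U, V, Z):
        Observed-minus-expected events in group 1, its hypergeometric
        variance, and the standardized statistic ``U / sqrt(V)`` (0 where
        V = 0), each of shape (B,).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    G = np.atleast_2d(np.asarray(groups)).astype(float)
    n = times.size
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    G = G[:, order]

    # n1[:, i] = members of group 1 still at risk at position i
    n1_tail = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]

    U = np.zeros(G.shape[0])
    V = np.zeros(G.shape[0])
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            n_t = n - i
            n1 = n1_tail[:, i]
            d1 = (G[:, i:j] * e[i:j]).sum(axis=1)
            frac = n1 / n_t
            U += d1 - d * frac
            if n_t > 1:
                V += d * frac * (1.0 - frac) * (n_t - d) / (n_t - 1)
        i = j
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(V > 0, U / np.sqrt(V), 0.0)
    return U, V, Z
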