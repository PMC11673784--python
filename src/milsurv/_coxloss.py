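"""Breslow Cox partial likelihood: value, gradient and Hessian in the risks.

Used both as the training loss of the MIL network (value + gradient with
respect to the per-patient risk scores) and, through the chain rule, by the
Newton-Raphson Breslow fitter in :mod:`milsurv.survival`.
"""

from __future__ import annotations

import numpy as np


def _validate(risks, times, events):
    r = np.asarray(risks, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events, dtype=int).ravel()
    if not (r.size == t.size == e.size):
        raise ValueError("risks, times and events must have equal length")
    if e.sum() == 0:
        raise ValueError("loss undefined without events")
    return r, t, e


def cox_partial_nll(risks, times, events, ties: str = "breslow") -> float:
    """Negative log Cox partial likelihood (sum over events).

    ``-sum_{i: event} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ]`` with
    Breslow handling of tied event times (tied events share one risk set).
    Uses a shifted log-sum-exp; adding a constant to every risk leaves the
    value unchanged.
    """
    if ties != "breslow":
        raise ValueError("only Breslow tie handling is implemented in the loss")
    nll, _ = cox_nll_grad(risks, times, events)
    return float(nll)


def cox_nll_grad(risks, times, events) -> tuple[float, np.ndarray]:
    """Breslow negative log partial likelihood and its gradient in the risks."""
    r, t, e = _validate(risks, times, events)
    n = r.size
    order = np.argsort(t, kind="stable")
    rs, ts, es = r[order], t[order], e[order]
    m = rs.max()
    w = np.exp(rs - m)
    # S_i = sum_{j >= start of i's tie block} w_j  (risk set of time ts[i])
    tail = np.cumsum(w[::-1])[::-1]
    # first index of each tie block
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if ts[i] == ts[i - 1] else i
    S = tail[first]                               # in e^{r-m} units
    ev = es == 1
    nll = -(np.sum(rs[ev]) - np.sum(np.log(S[ev]) + m) * 1.0)
    # gradient: dnll/dr_j = -e_j + w_j * sum_{event times <= t_j} d_t / S_t
    inv_contrib = np.where(ev, 1.0 / S, 0.0)
    prefix = np.cumsum(inv_contrib)
    # for j, events with t_i <= t_j include j's whole tie block
    last = np.zeros(n, dtype=int)
    last[-1] = n - 1
    for i in range(n - 2, -1, -1):
        last[i] = last[i + 1] if ts[i] == ts[i + 1] else i
    grad_sorted = -es + w * prefix[last]
    grad = np.empty(n)
    grad[order] = grad_sorted
    return float(nll), grad


def cox_nll_grad_hess(risks, times, events) -> tuple[float, np.ndarray, np.ndarray]:
    """As :func:`cox_nll_grad`, plus the n x n Hessian in the risks.

    ``H = sum_t d_t (diag(pi_t) - pi_t pi_t^T)`` with ``pi_t`` the softmax
    of the risks over the risk set at event time ``t``. O(n^2 per event
    time); intended for cohort-scale fits, not the training loop.
    """
    nll, grad = cox_nll_grad(risks, times, events)
    r, t, e = _validate(risks, times, events)
    n = r.size
    m = r.max()
    w = np.exp(r - m)
    H = np.zeros((n, n))
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        d = int(np.sum(e[t == ut]))
        pi = np.where(at_risk, w, 0.0)
        pi = pi / pi.sum()
        H += d * (np.diag(pi) - np.outer(pi, pi))
    return nll, grad, H
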