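"""Survival estimation and testing for the image-based prognostic score.

Covers the downstream statistics of the pipeline: Kaplan-Meier estimation
with Greenwood confidence bands, the log-rank test, Cox proportional-
hazards fits (Efron ties through lifelines; Breslow through an internal
Newton-Raphson on the package's partial-likelihood kernel), likelihood-
ratio comparison of nested models, Harrell's concordance index, the
combined clinical + image-score model, and subgroup analyses.

Records are plain DataFrames with ``patient_id``, ``time_months`` (> 0),
``event`` (0/1: for progression-free survival the event is first relapse
or death from any cause; for overall survival, death) and covariate
columns. Categorical covariates are coded against the first sorted level
as reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from ._coxloss import cox_nll_grad, cox_nll_grad_hess
from ._logrank import logrank_z

__all__ = [
    "KaplanMeierResult", "kaplan_meier", "LogrankResult", "logrank_test",
    "CoxFit", "cox_fit", "LRTResult", "likelihood_ratio_test",
    "concordance_index", "CombinedModelReport", "combined_model",
    "subgroup_analysis", "validate_records",
]


def validate_records(records: pd.DataFrame, duration_col: str = "time_months",
                     event_col: str = "event") -> None:
    if duration_col not in records or event_col not in records:
        raise ValueError(f"records need {duration_col!r} and {event_col!r} columns")
    if (records[duration_col] <= 0).any():
        raise ValueError("survival times must be positive")
    if not records[event_col].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierResult:
    """Product-limit estimate with Greenwood log-transform 95% bands."""

    table: pd.DataFrame          # time, n_risk, n_events, n_censored, estimate, ci_low, ci_high
    median: float                # nan when never reached
    median_defined: bool

    def survival_at(self, t: float) -> float:
        tab = self.table
        past = tab[tab["time"] <= t]
        return 1.0 if past.empty else float(past["estimate"].iloc[-1])


def kaplan_meier(times, events, z: float = 1.959963984540054) -> KaplanMeierResult:
    """Kaplan-Meier estimator.

    Confidence bands use the Greenwood variance on the log-survival scale:
    ``S * exp(+-z * se)`` with ``se^2 = sum d / (n (n - d))``. The median is
    the earliest observed time with estimate <= 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one record")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    utimes = np.unique(t)
    n = t.size
    rows = []
    S = 1.0
    greenwood = 0.0
    for ut in utimes:
        at_risk = int(np.sum(t >= ut))
        d = int(np.sum(e[t == ut]))
        c = int(np.sum((t == ut) & (e == 0)))
        if d > 0:
            S *= 1.0 - d / at_risk
            if at_risk > d:
                greenwood += d / (at_risk * (at_risk - d))
            else:
                greenwood = np.inf
        if S > 0 and np.isfinite(greenwood):
            se = np.sqrt(greenwood)
            lo, hi = S * np.exp(-z * se), min(1.0, S * np.exp(z * se))
        else:
            lo = hi = 0.0 if S == 0 else np.nan
        rows.append((ut, at_risk, d, c, S, lo, hi))
    tab = pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "n_censored",
                                      "estimate", "ci_low", "ci_high"])
    reached = tab[tab["estimate"] <= 0.5]
    if reached.empty:
        return KaplanMeierResult(tab, float("nan"), False)
    return KaplanMeierResult(tab, float(reached["time"].iloc[0]), True)


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(times, events, groups) -> LogrankResult:
    """Log-rank comparison of two or more survival curves.

    Observed-minus-expected events with hypergeometric variance, summed
    over event times. For two groups the chi-square equals the square of
    the standardized statistic used for cut-point selection (shared
    kernel).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if e.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    if levels.size == 2:
        _, _, z = logrank_z(t, e, (g == levels[1])[None, :])
        chi2 = float(z[0] ** 2)
        return LogrankResult(chi2, 1, float(stats.chi2.sf(chi2, 1)))
    G = np.stack([(g == lv).astype(float) for lv in levels])     # (g, n)
    k = levels.size
    O_E = np.zeros(k)
    V = np.zeros((k, k))
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n_t = int(at_risk.sum())
        d_t = int(e[t == ut].sum())
        n_i = G[:, at_risk].sum(axis=1)
        d_i = G[:, t == ut] @ e[t == ut]
        O_E += d_i - d_t * n_i / n_t
        if n_t > 1:
            mult = d_t * (n_t - d_t) / (n_t - 1)
            V += mult * (np.diag(n_i / n_t) - np.outer(n_i, n_i) / n_t ** 2)
    chi2 = float(O_E[:-1] @ np.linalg.solve(V[:-1, :-1], O_E[:-1]))
    return LogrankResult(chi2, k - 1, float(stats.chi2.sf(chi2, k - 1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted proportional-hazards model (one row of output per term)."""

    terms: list                       # design-matrix column names
    coefficients: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    log_likelihood_null: float
    n: int
    n_events: int
    ties: str
    converged: bool = True
    separation: bool = False
    source_terms: list = field(default_factory=list)
    term_levels: dict = field(default_factory=dict)   # source term -> (reference, levels)
    z: float = 1.959963984540054

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    @property
    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.terms)

    @property
    def p_values(self) -> pd.Series:
        zstat = self.coefficients / self.standard_errors
        return pd.Series(2 * stats.norm.sf(np.abs(zstat)), index=self.terms)

    def summary(self) -> pd.DataFrame:
        se = self.standard_errors
        return pd.DataFrame({
            "term": self.terms,
            "coef": self.coefficients.values,
            "HR": np.exp(self.coefficients.values),
            "ci_low": np.exp(self.coefficients.values - self.z * se.values),
            "ci_high": np.exp(self.coefficients.values + self.z * se.values),
            "p": self.p_values.values,
        })


def _build_design(records: pd.DataFrame, terms, categorical=None
                  ) -> tuple[pd.DataFrame, list, dict]:
    """Expand terms into a design matrix; categorical terms get
    reference-level dummy coding (reference = first sorted level)."""
    categorical = set(categorical or [])
    cols = {}
    levels_info = {}
    for term in terms:
        if term not in records:
            raise ValueError(f"term {term!r} not in records")
        col = records[term]
        is_cat = (term in categorical or col.dtype == object
                  or isinstance(col.dtype, pd.CategoricalDtype))
        if is_cat:
            lv = sorted(col.astype(str).unique())
            levels_info[term] = (lv[0], lv)
            for level in lv[1:]:
                cols[f"{term}={level}"] = (col.astype(str) == level).astype(float)
        else:
            levels_info[term] = (None, None)
            cols[term] = col.astype(float)
    X = pd.DataFrame(cols, index=records.index)
    zero_var = [c for c in X if X[c].nunique() <= 1]
    if zero_var:
        raise ValueError(f"constant (zero-information) design column(s): {zero_var}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name a collinear subset via pivoted QR
        _, _, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(
            X.to_numpy(), pivoting=True)
        dropped = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank-deficient; collinear term(s): {dropped}")
    return X, list(X.columns), levels_info


def _newton_breslow(X: np.ndarray, t: np.ndarray, e: np.ndarray,
                    tol: float = 1e-9, max_iter: int = 100):
    beta = np.zeros(X.shape[1])
    nll = np.inf
    converged = False
    for _ in range(max_iter):
        val, g_r, H_r = cox_nll_grad_hess(X @ beta, t, e)
        g = X.T @ g_r
        H = X.T @ H_r @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving on non-improvement
        alpha = 1.0
        for _ in range(30):
            new_beta = beta - alpha * step
            new_val, _ = cox_nll_grad(X @ new_beta, t, e)
            if new_val <= val + 1e-12:
                break
            alpha /= 2.0
        delta = np.max(np.abs(new_beta - beta))
        beta, nll = new_beta, new_val
        if delta < tol:
            converged = True
            break
    _, _, H_r = cox_nll_grad_hess(X @ beta, t, e)
    H = X.T @ H_r @ X
    cov = np.linalg.pinv(H)
    null_nll, _ = cox_nll_grad(np.zeros_like(t), t, e)
    return beta, cov, -nll, -null_nll, converged


def cox_fit(records: pd.DataFrame, terms, duration_col: str = "time_months",
            event_col: str = "event", ties: str = "efron",
            categorical=None) -> CoxFit:
    """Fit a Cox proportional-hazards model on the given covariate terms.

    ``ties="efron"`` delegates to lifelines' Newton-Raphson; ``"breslow"``
    uses the package's own Newton solver on the Breslow partial likelihood
    (the same kernel as the MIL training loss). Monotone likelihood
    (separation) is reported on the fit rather than raised.
    """
    validate_records(records, duration_col, event_col)
    if records[event_col].sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    X, design_terms, levels_info = _build_design(records, list(terms), categorical)
    t = records[duration_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy(dtype=int)
    separation = False
    converged = True
    if ties == "efron":
        from lifelines.exceptions import ConvergenceError

        df = X.copy()
        df["__T"] = t
        df["__E"] = e
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cph.fit(df, duration_col="__T", event_col="__E")
            msgs = " ".join(str(w.message) for w in caught)
            if "convergence" in msgs.lower() or "complete separation" in msgs.lower():
                separation = True
            beta = cph.params_.to_numpy()
            cov = cph.variance_matrix_.to_numpy()
            ll = float(cph.log_likelihood_)
            lrt = cph.log_likelihood_ratio_test()
            ll_null = ll - float(lrt.test_statistic) / 2.0
        except ConvergenceError:
            # monotone likelihood: the Efron Newton diverged. Fall back to
            # the damped Breslow solver (identical likelihood when event
            # times are untied) and flag the separation.
            beta, cov, ll, ll_null, converged = _newton_breslow(
                X.to_numpy(), t, e)
            separation = True
    elif ties == "breslow":
        beta, cov, ll, ll_null, converged = _newton_breslow(X.to_numpy(), t, e)
    else:
        raise ValueError(f"unknown ties method {ties!r}")
    if np.max(np.abs(beta)) > 15:
        separation = True
    return CoxFit(design_terms,
                  pd.Series(beta, index=design_terms),
                  pd.DataFrame(cov, index=design_terms, columns=design_terms),
                  ll, ll_null, int(t.size), int(e.sum()), ties,
                  converged, separation, list(terms), levels_info)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(nested: CoxFit, full: CoxFit) -> LRTResult:
    """Compare nested Cox models: ``2 (ll_full - ll_nested) ~ chi2(df)``."""
    if not set(nested.terms).issubset(full.terms):
        raise ValueError("models are not nested (term sets)")
    if nested.n != full.n or nested.n_events != full.n_events:
        raise ValueError("models were fit on different record sets")
    if nested.ties != full.ties:
        raise ValueError("models use different tie-handling methods")
    df = len(full.terms) - len(nested.terms)
    stat = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(stat, df, p)


def _null_fit(records: pd.DataFrame, like: CoxFit,
              duration_col: str, event_col: str) -> CoxFit:
    """A zero-covariate 'fit' carrying only the null log-likelihood."""
    return CoxFit([], pd.Series(dtype=float), pd.DataFrame(),
                  like.log_likelihood_null, like.log_likelihood_null,
                  like.n, like.n_events, like.ties)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(risks, times, events) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly.

    A pair (i, j) is comparable when ``t_i < t_j`` and subject i had the
    event; it is concordant when the earlier-event subject has the higher
    risk. Risk ties count 1/2.
    """
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = earlier.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = (r[:, None] > r[None, :]) * earlier
    ties = (r[:, None] == r[None, :]) * earlier
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


# ---------------------------------------------------------------------------
# combined clinical + image model, subgroups
# ---------------------------------------------------------------------------

@dataclass
class CombinedModelReport:
    univariate: pd.DataFrame           # per clinical covariate: LRT p etc.
    screened: list
    clinical_fit: CoxFit | None
    combined_fit: CoxFit
    lrt: LRTResult                     # combined vs clinical-only
    table: pd.DataFrame                # Table-style rows for the combined fit


def _table_rows(fit: CoxFit, records: pd.DataFrame) -> pd.DataFrame:
    """Per-term report rows, including reference-level dashes for
    categorical covariates (mirrors standard clinical Cox tables)."""
    summ = fit.summary().set_index("term")
    rows = []
    for term in fit.source_terms:
        ref, levels = fit.term_levels.get(term, (None, None))
        n_term = int(records[term].notna().sum())
        if levels is None:
            s = summ.loc[term]
            rows.append((term, "", n_term, s["HR"], s["ci_low"], s["ci_high"], s["p"]))
        else:
            rows.append((term, ref, n_term, np.nan, np.nan, np.nan, np.nan))
            for level in levels[1:]:
                key = f"{term}={level}"
                s = summ.loc[key]
                rows.append((term, level, n_term,
                             s["HR"], s["ci_low"], s["ci_high"], s["p"]))
    return pd.DataFrame(rows, columns=["variable", "level", "N", "HR",
                                       "ci_low", "ci_high", "p"])


def combined_model(records: pd.DataFrame, clinical_terms,
                   ibp_term: str = "ibp_group", screen_alpha: float = 0.05,
                   duration_col: str = "time_months", event_col: str = "event",
                   ties: str = "efron", categorical=None) -> CombinedModelReport:
    """Clinical-only vs clinical + image-score Cox models.

    Each clinical covariate is screened by its univariate likelihood-ratio
    p-value; covariates below ``screen_alpha`` enter the multivariate
    clinical model. The combined model adds the dichotomized image-based
    prognostic group, and the two are compared by likelihood ratio.
    """
    uni_rows = []
    screened = []
    for term in clinical_terms:
        fit = cox_fit(records, [term], duration_col, event_col, ties, categorical)
        stat = max(0.0, 2.0 * (fit.log_likelihood - fit.log_likelihood_null))
        p = float(stats.chi2.sf(stat, len(fit.terms)))
        uni_rows.append({"variable": term, "lrt_statistic": stat,
                         "df": len(fit.terms), "p": p})
        if p < screen_alpha:
            screened.append(term)
    univariate = pd.DataFrame(uni_rows)

    combined_fit = cox_fit(records, screened + [ibp_term],
                           duration_col, event_col, ties, categorical)
    if screened:
        clinical_fit = cox_fit(records, screened, duration_col, event_col,
                               ties, categorical)
    else:
        clinical_fit = _null_fit(records, combined_fit, duration_col, event_col)
    lrt = likelihood_ratio_test(clinical_fit, combined_fit)
    table = _table_rows(combined_fit, records)
    return CombinedModelReport(univariate, screened,
                               clinical_fit if screened else None,
                               combined_fit, lrt, table)


def subgroup_analysis(records: pd.DataFrame, stratum: str,
                      group_col: str = "ibp_group",
                      duration_col: str = "time_months",
                      event_col: str = "event") -> pd.DataFrame:
    """Per-stratum log-rank and univariate Cox HR of the image-score group.

    Strata without events are skipped with a warning. Returns one row per
    retained stratum.
    """
    validate_records(records, duration_col, event_col)
    levels = sorted(records[stratum].astype(str).unique())
    rows = []
    for level in levels:
        sub = records[records[stratum].astype(str) == level]
        if sub[event_col].sum() == 0:
            warnings.warn(f"stratum {stratum}={level} has no events; skipped")
            continue
        lr = logrank_test(sub[duration_col], sub[event_col], sub[group_col])
        fit = cox_fit(sub, [group_col], duration_col, event_col,
                      categorical=[group_col])
        s = fit.summary().iloc[0]
        rows.append({"stratum": level, "n": len(sub),
                     "n_events": int(sub[event_col].sum()),
                     "HR": s["HR"], "ci_low": s["ci_low"], "ci_high": s["ci_high"],
                     "cox_p": s["p"], "logrank_p": lr.p_value})
    return pd.DataFrame(rows)
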