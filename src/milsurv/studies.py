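"""Simulation studies exercising the pipeline against known ground truth.

Each function runs one self-contained experiment on synthetic cohorts —
parameter recovery, null calibration, end-to-end threshold transfer — and
returns the measured quantities. They are the package's own validation
battery: the same protocols back the test suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic
from .features import bags_from_cohort, cluster_phenotypes
from .model import ModelConfig, train, train_ensemble
from .pipeline import RunConfig, run_pipeline
from .stratify import maxstat_cutpoint
from .survival import concordance_index, cox_fit, likelihood_ratio_test

DEFAULT_EFFECT = 2.0
DEFAULT_CENSOR = 0.3


def _standard_cohort(seed: int, n: int = 200, K: int = 10, d: int = 16,
                     effect: float = DEFAULT_EFFECT,
                     censor_rate: float = DEFAULT_CENSOR):
    beta = synthetic.phenotype_effect_pattern(K, effect)
    return synthetic.generate_cohort(n, K_true=K, d=d, beta_phenotype=beta,
                                     censor_rate=censor_rate, seed=seed)


def heldout_concordance(seed: int, n: int = 200, K: int = 10, d: int = 16,
                        effect: float = DEFAULT_EFFECT,
                        permute_labels: bool = False,
                        n_members: int = 3) -> float:
    """Train on 75% of one synthetic cohort, score Harrell's C on the rest.

    The phenotype clustering is fit on the training portion only; the
    model is the package's standard estimator (ensemble over inits).
    With ``permute_labels`` the survival labels are shuffled before
    training — the held-out concordance must then collapse to chance.
    """
    co = _standard_cohort(seed, n=n, K=K, d=d, effect=effect)
    rng = np.random.default_rng(seed + 1000)
    idx = rng.permutation(n)
    tr, te = idx[:int(0.75 * n)], idx[int(0.75 * n):]
    times, events = co.times.copy(), co.events.copy()
    if permute_labels:
        perm = rng.permutation(n)
        times, events = times[perm], events[perm]
    X = np.concatenate([co.features[co.patients[i]] for i in tr])
    _, clustering = cluster_phenotypes(X, k=K, seed=0)
    bags = bags_from_cohort(co, clustering)
    cfg = ModelConfig(k=K, d=d, epochs=30, seed=0)
    if n_members > 1:
        model = train_ensemble([bags[i] for i in tr], times[tr], events[tr],
                               cfg, n_members=n_members)
    else:
        model = train([bags[i] for i in tr], times[tr], events[tr], cfg)
    risks = model.predict_many([bags[i] for i in te])
    return concordance_index(risks, times[te], events[te])


def clinical_hr_coverage(n_reps: int = 50, n: int = 400,
                         true_hr: float = 2.0, seed: int = 0) -> float:
    """Fraction of replicates whose univariate Cox 95% CI covers the
    planted hazard ratio for a binary covariate."""
    covered = 0
    for rep in range(n_reps):
        co = synthetic.generate_cohort(
            n, K_true=3, d=4, bag_size_range=(2, 4),
            clinical_effects={"node": np.log(true_hr)},
            censor_rate=0.2, seed=seed + rep)
        rec = co.survival_frame().drop(columns=["patient_id"])
        fit = cox_fit(rec, ["node"])
        s = fit.summary().iloc[0]
        if s["ci_low"] <= true_hr <= s["ci_high"]:
            covered += 1
    return covered / n_reps


def censoring_calibration(n: int = 500, target: float = DEFAULT_CENSOR,
                          seed: int = 0) -> float:
    """Empirical censored fraction of one cohort at the target rate."""
    co = synthetic.generate_cohort(n, K_true=5, d=8, bag_size_range=(5, 10),
                                   censor_rate=target, seed=seed)
    return float(1.0 - co.events.mean())


def maxstat_null_pvalues(n_reps: int = 200, n: int = 60, n_perm: int = 199,
                         seed: int = 0) -> np.ndarray:
    """Permutation p-values when scores are independent of survival."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_reps)
    for rep in range(n_reps):
        scores = rng.normal(size=n)
        times = rng.exponential(10.0, size=n)
        events = (rng.uniform(size=n) > 0.3).astype(int)
        if events.sum() < 2:
            events[:2] = 1
        res = maxstat_cutpoint(scores, times, events, n_perm=n_perm,
                               seed=int(rng.integers(2 ** 31)))
        ps[rep] = res.p_value
    return ps


def lrt_null_pvalues(n_reps: int = 200, n: int = 120,
                     seed: int = 0) -> np.ndarray:
    """Likelihood-ratio p-values for adding a pure-noise covariate."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_reps)
    for rep in range(n_reps):
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x), size=n) + 1e-3
        e = (rng.uniform(size=n) > 0.2).astype(int)
        rec = pd.DataFrame({"time_months": t, "event": e,
                            "x": x, "noise": noise})
        nested = cox_fit(rec, ["x"])
        full = cox_fit(rec, ["x", "noise"])
        ps[rep] = likelihood_ratio_test(nested, full).p_value
    return ps


def uniformity_ks_pvalue(pvalues: np.ndarray) -> float:
    """Kolmogorov-Smirnov p-value against Uniform(0, 1)."""
    return float(stats.kstest(pvalues, "uniform").pvalue)


def endtoend_run_config(seed: int) -> RunConfig:
    """Moderate-size full-pipeline configuration for replicate runs."""
    return RunConfig(
        seed=seed,
        synthetic={"n_train": 120, "n_validation": 120, "K_true": 10,
                   "d": 16, "bag_size_range": (60, 150),
                   "effect": DEFAULT_EFFECT,
                   "clinical_effects": {"node": 0.693},
                   "censor_rate": DEFAULT_CENSOR, "baseline": (1.3, 20.0)},
        cluster={"k": 10},
        model={"embed_dims": (64, 32), "attention_dim": 32,
               "learning_rate": 1e-2, "folds": 3,
               "epoch_grid": (10, 20, 30), "test_fraction": 0.2,
               "n_members": 2},
        stratify={"min_prop": 0.1, "max_prop": 0.9, "n_perm": 199},
    )


def endtoend_validation_pvalues(n_runs: int = 10, seed: int = 0,
                                workdir=None) -> list[float]:
    """Run the full pipeline ``n_runs`` times; collect the log-rank p of
    the transferred-threshold dichotomization on the validation cohort."""
    import tempfile
    from pathlib import Path

    ps = []
    for rep in range(n_runs):
        cfg = endtoend_run_config(seed + rep)
        if workdir is None:
            with tempfile.TemporaryDirectory() as tmp:
                result = run_pipeline(cfg, Path(tmp) / f"run{rep}")
        else:
            result = run_pipeline(cfg, Path(workdir) / f"run{rep}")
        ps.append(result.summary["validation_logrank_p"])
    return ps
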