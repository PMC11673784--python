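"""Synthetic stained tiles and feature-bag survival cohorts with known truth.

Two generators:

* :func:`generate_tiles` renders small two-stain tiles by the Beer-Lambert
  law ``I = I0 * 10**(-S c)`` with per-pixel concentrations drawn uniformly,
  plus a controllable fraction of pure-white background pixels. They exist
  to exercise tiling, background filtering and Macenko estimation against a
  known generating stain matrix.

* :func:`generate_cohort` draws patient-level bags of tile features from
  ``K_true`` well-separated Gaussian phenotypes. Each patient's slide is
  dominated by a small number of phenotypes (a random support of 1-3 of the
  K phenotypes with near-even proportions within the support) — mirroring
  slides dominated by a few morphologies. The hazard of progression is
  proportional to ``exp(beta_phenotype . proportions + sum of clinical
  effects)`` with a Weibull baseline; censoring is independent exponential
  with its rate solved numerically to hit a target censored fraction.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .preprocess import TileImage


@dataclass
class StainSimConfig:
    """Parameters of the toy tile renderer."""

    stain_matrix: np.ndarray                      # 3x2, unit columns
    # near-zero minima let single-stain (e.g. pure-hematoxylin nucleus)
    # pixels occur, which anchors the angular extremes of the OD cloud
    concentration_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (0.02, 1.5), (0.02, 1.5))
    white_fraction: float = 0.0
    tile_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        for j in range(2):
            if abs(norms[j] - 1.0) > 1e-6:
                raise ValueError(
                    f"stain_matrix column {j} is not unit-norm (|v|={norms[j]:.4f})")
        cosang = abs(float(self.stain_matrix[:, 0] @ self.stain_matrix[:, 1]))
        if cosang > 0.999:
            raise ValueError("stain_matrix columns are collinear (column 1 ~ column 0)")
        if not 0.0 <= self.white_fraction <= 1.0:
            raise ValueError("white_fraction must lie in [0, 1]")


def generate_tiles(config: StainSimConfig, n: int,
                   slide_id: str = "sim") -> list[TileImage]:
    """Render ``n`` tiles under ``config``.

    Background pixels are pure white (255,255,255); tissue pixels follow
    ``I = I0 * 10**(-S c)`` with concentrations drawn uniformly from the
    configured ranges. The number of white pixels equals
    ``round(white_fraction * tile_size**2)`` exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    ts = config.tile_size
    npix = ts * ts
    n_white = int(round(config.white_fraction * npix))
    (c0_lo, c0_hi), (c1_lo, c1_hi) = config.concentration_ranges
    tiles = []
    for i in range(n):
        conc = np.stack([rng.uniform(c0_lo, c0_hi, size=npix),
                         rng.uniform(c1_lo, c1_hi, size=npix)], axis=1)
        od = conc @ config.stain_matrix.T
        pixels = np.clip(np.round(255.0 * np.power(10.0, -od)), 0, 255)
        white_idx = rng.permutation(npix)[:n_white]
        pixels[white_idx] = 255.0
        tiles.append(TileImage(pixels.reshape(ts, ts, 3).astype(np.uint8),
                               slide_id, (i * ts, 0)))
    return tiles


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A cohort of patient bags with known generating parameters."""

    patients: list[str]
    features: dict[str, np.ndarray]            # patient -> (m_i, d)
    phenotype_labels: dict[str, np.ndarray]    # patient -> (m_i,), values in 1..K
    proportions: np.ndarray                    # (n, K) realized tile proportions
    counts: np.ndarray                         # (n, K) integer tile counts
    times: np.ndarray                          # months, > 0
    events: np.ndarray                         # {0,1}
    clinical: pd.DataFrame                     # binary covariate columns
    truth: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def log_hazard(self) -> np.ndarray:
        """The generating linear predictor eta for each patient."""
        return np.asarray(self.truth["eta"])

    def survival_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patients,
                           "time_months": self.times,
                           "event": self.events})
        return pd.concat([df, self.clinical.reset_index(drop=True)], axis=1)

    def feature_frame(self) -> pd.DataFrame:
        """Long-format tile feature table (one row per tile)."""
        rows = []
        for pid in self.patients:
            X = self.features[pid]
            lab = self.phenotype_labels[pid]
            for j in range(X.shape[0]):
                rows.append((pid, f"{pid}_t{j}", int(lab[j]), *X[j]))
        d = next(iter(self.features.values())).shape[1]
        cols = ["patient_id", "tile_id", "true_phenotype"] + [f"f{i}" for i in range(d)]
        return pd.DataFrame(rows, columns=cols)


def phenotype_effect_pattern(K: int, scale: float = 2.0) -> np.ndarray:
    """Zero-mean, unit-variance coefficient pattern scaled by ``scale``.

    ``scale`` is the log-hazard effect size: the population of per-phenotype
    coefficients has standard deviation ``scale``, so a patient whose slide
    is dominated by the extreme phenotypes differs by roughly ``2*scale``
    in log hazard from one at the opposite extreme.
    """
    pat = np.linspace(-1.0, 1.0, K)
    pat = (pat - pat.mean()) / pat.std()
    return scale * pat


def _phenotype_means(K: int, d: int, separation: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Cluster means with pairwise distance ``separation`` (in sd units)."""
    if d >= K:
        means = np.zeros((K, d))
        means[np.arange(K), np.arange(K)] = separation / np.sqrt(2.0)
    else:
        raw = rng.standard_normal((K, d))
        q, _ = np.linalg.qr(raw.T)
        means = (separation / np.sqrt(2.0)) * q.T[:K]
    return means


def _largest_remainder_counts(p: np.ndarray, m: int) -> np.ndarray:
    """Round ``m * p`` to integers that sum exactly to ``m``."""
    raw = p * m
    counts = np.floor(raw).astype(int)
    short = m - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def generate_cohort(n_patients: int,
                    K_true: int = 10,
                    d: int = 16,
                    bag_size_range: tuple[int, int] = (100, 300),
                    beta_phenotype: np.ndarray | None = None,
                    clinical_effects: dict[str, float] | None = None,
                    baseline: tuple[float, float] = (1.3, 20.0),
                    censor_rate: float = 0.3,
                    seed: int = 0,
                    separation: float = 4.0,
                    support_range: tuple[int, int] = (1, 3),
                    within_concentration: float = 8.0,
                    censoring: str = "exponential",
                    admin_time: float | None = None,
                    prefix: str = "P") -> SyntheticCohort:
    """Draw a cohort of feature bags with a planted proportional-hazards truth.

    Parameters
    ----------
    beta_phenotype:
        Length-``K_true`` log-hazard coefficients applied to the bag's
        phenotype proportions. Default: zeros (null cohort).
    clinical_effects:
        Map of covariate name -> log hazard ratio; each covariate is an
        independent Bernoulli(1/2) indicator.
    baseline:
        Weibull ``(shape, scale)`` of the baseline event-time distribution,
        in months.
    censor_rate:
        Target expected censored fraction in [0, 1). With ``censoring=
        "exponential"`` the censoring rate is solved numerically against
        the realized event times; ``censoring="administrative"`` censors at
        the fixed ``admin_time`` instead.
    separation:
        Pairwise distance between phenotype feature means, in units of the
        within-phenotype standard deviation.
    support_range, within_concentration:
        Each slide's composition has ``support`` phenotypes (uniform in the
        range) with proportions Dirichlet(``within_concentration``) on that
        support — near-even dominant morphologies with jitter.
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    if bag_size_range[0] > bag_size_range[1] or bag_size_range[0] < 1:
        raise ValueError(f"invalid bag_size_range {bag_size_range}")
    beta = (np.zeros(K_true) if beta_phenotype is None
            else np.asarray(beta_phenotype, dtype=float))
    if beta.shape != (K_true,):
        raise ValueError(
            f"beta_phenotype has length {beta.size}, expected K_true={K_true}")
    clinical_effects = dict(clinical_effects or {})
    smin, smax = support_range
    if not (1 <= smin <= smax <= K_true):
        raise ValueError(f"invalid support_range {support_range}")

    rng = np.random.default_rng(seed)
    n = int(n_patients)
    patients = [f"{prefix}{i:04d}" for i in range(n)]
    means = _phenotype_means(K_true, d, separation, rng)

    proportions = np.zeros((n, K_true))
    counts = np.zeros((n, K_true), dtype=int)
    bag_sizes = rng.integers(bag_size_range[0], bag_size_range[1] + 1, size=n)
    features: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for i, pid in enumerate(patients):
        support_size = int(rng.integers(smin, smax + 1))
        support = rng.choice(K_true, size=support_size, replace=False)
        p = np.zeros(K_true)
        p[support] = rng.dirichlet(np.full(support_size, within_concentration))
        c = _largest_remainder_counts(p, int(bag_sizes[i]))
        counts[i] = c
        proportions[i] = c / c.sum()
        lab = np.repeat(np.arange(1, K_true + 1), c)
        X = means[lab - 1] + rng.standard_normal((lab.size, d))
        perm = rng.permutation(lab.size)
        features[pid] = X[perm]
        labels[pid] = lab[perm]

    clinical = pd.DataFrame(index=range(n))
    eta_clin = np.zeros(n)
    for name, loghr in clinical_effects.items():
        x = rng.integers(0, 2, size=n)
        clinical[name] = x
        eta_clin += loghr * x

    eta = proportions @ beta + eta_clin
    shape, scale = baseline
    u = rng.uniform(size=n)
    T = scale * np.power(-np.log(u) * np.exp(-eta), 1.0 / shape)

    censor_info: dict = {"method": censoring, "target_rate": censor_rate}
    if censor_rate == 0.0:
        times, events = T, np.ones(n, dtype=int)
    elif censoring == "exponential":
        def expected_censored(rate: float) -> float:
            return float(np.mean(1.0 - np.exp(-rate * T))) - censor_rate

        rate = brentq(expected_censored, 1e-10, 1e4)
        C = rng.exponential(1.0 / rate, size=n)
        times = np.minimum(T, C)
        events = (T <= C).astype(int)
        censor_info["rate"] = rate
    elif censoring == "administrative":
        if admin_time is None:
            admin_time = float(np.quantile(T, 1.0 - censor_rate))
        times = np.minimum(T, admin_time)
        events = (T <= admin_time).astype(int)
        censor_info["admin_time"] = admin_time
    else:
        raise ValueError(f"unknown censoring method {censoring!r}")
    times = np.maximum(times, 1e-6)

    truth = {"beta_phenotype": beta, "clinical_effects": clinical_effects,
             "baseline": {"shape": shape, "scale": scale},
             "phenotype_means": means, "separation": separation,
             "eta": eta, "event_times_uncensored": T,
             "censoring": censor_info, "seed": int(seed),
             "support_range": support_range,
             "within_concentration": within_concentration}
    return SyntheticCohort(patients, features, labels, proportions, counts,
                           times, events, clinical, truth)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write survival CSV, feature TSV and truth JSON under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"survival": directory / "survival.csv",
             "features": directory / "features.tsv",
             "truth": directory / "truth.json"}
    cohort.survival_frame().to_csv(paths["survival"], index=False)
    cohort.feature_frame().to_csv(paths["features"], sep="\t", index=False)
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in cohort.truth.items()}
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def load_cohort(directory: str | Path) -> SyntheticCohort:
    """Inverse of :func:`write_cohort`."""
    directory = Path(directory)
    surv = pd.read_csv(directory / "survival.csv")
    feats = pd.read_csv(directory / "features.tsv", sep="\t")
    truth = json.loads((directory / "truth.json").read_text())
    for key in ("beta_phenotype", "phenotype_means", "eta", "event_times_uncensored"):
        if key in truth:
            truth[key] = np.asarray(truth[key])
    fcols = [c for c in feats.columns if c.startswith("f")]
    patients = list(surv["patient_id"].astype(str))
    features = {}
    labels = {}
    K = truth["beta_phenotype"].size
    counts = np.zeros((len(patients), K), dtype=int)
    for i, pid in enumerate(patients):
        sub = feats[feats["patient_id"] == pid]
        features[pid] = sub[fcols].to_numpy(dtype=float)
        labels[pid] = sub["true_phenotype"].to_numpy(dtype=int)
        counts[i] = np.bincount(labels[pid] - 1, minlength=K)
    proportions = counts / counts.sum(axis=1, keepdims=True)
    clinical_cols = [c for c in surv.columns
                     if c not in ("patient_id", "time_months", "event")]
    return SyntheticCohort(patients, features, labels, proportions, counts,
                           surv["time_months"].to_numpy(dtype=float),
                           surv["event"].to_numpy(dtype=int),
                           surv[clinical_cols].copy(), truth)
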