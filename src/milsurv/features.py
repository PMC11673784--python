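"""Tile feature extraction and phenotype clustering.

Stage 1 of the survival-MIL pipeline: each preprocessed tile is mapped to a
feature vector and the training population's tiles are grouped into ``k``
phenotype clusters by k-means. Clusters act as morphology-specific
"phenotypes": a patient's bag of tiles is partitioned by cluster and each
non-empty slot becomes one instance set of the MIL model.

The extractor is an interface, not a fixed network. The built-in
descriptor (mean-pooled grayscale grid + per-channel intensity histograms)
is deterministic and dependency-free; a pretrained CNN (e.g. the
penultimate layer of an ImageNet VGG16) plugs in through
:func:`register_extractor` with the same contract: tiles in, one fixed-size
vector per tile out.

Clustering is fit once on the training population and the centroids (plus
the feature scaler) are frozen; validation tiles are assigned to the
nearest frozen centroid so the phenotype vocabulary is shared across
cohorts. Features are z-scored per dimension before k-means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .preprocess import TileImage

# ---------------------------------------------------------------------------
# extractors
# ---------------------------------------------------------------------------

_EXTRACTORS: dict[str, Callable[[TileImage], np.ndarray]] = {}


def register_extractor(name: str, fn: Callable[[TileImage], np.ndarray]) -> None:
    """Register a per-tile feature extractor under ``name``.

    ``fn`` receives a :class:`TileImage` and must return a 1-D float vector
    of constant length. This is the seam where a pretrained CNN adapter
    (e.g. VGG16 penultimate activations) is plugged in.
    """
    _EXTRACTORS[name] = fn


def builtin_descriptor(tile: TileImage, grid: int = 4, bins: int = 8) -> np.ndarray:
    """Deterministic hand-crafted descriptor: grayscale grid + color histograms.

    Concatenates a ``grid x grid`` block-mean of the grayscale image
    (scaled to [0, 1]) with ``bins``-bin per-channel intensity histograms
    (as fractions). An all-white tile puts every histogram's mass in the
    top bin.
    """
    px = tile.pixels.astype(float)
    h, w = px.shape[:2]
    gray = px.mean(axis=2)
    ys = np.linspace(0, h, grid + 1).astype(int)
    xs = np.linspace(0, w, grid + 1).astype(int)
    blocks = np.array([[gray[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].mean()
                        for j in range(grid)] for i in range(grid)])
    hists = [np.histogram(px[..., c], bins=bins, range=(0, 256))[0]
             for c in range(3)]
    hists = np.concatenate(hists).astype(float) / (h * w)
    return np.concatenate([blocks.ravel() / 255.0, hists])


register_extractor("builtin", builtin_descriptor)


@dataclass
class FeatureTable:
    """One feature vector per tile, with provenance columns.

    The underlying frame has columns ``patient_id, slide_id, tile_id, x, y,
    f0..f{d-1}``; ``extractor_name`` and ``d`` are metadata.
    """

    frame: pd.DataFrame
    extractor_name: str
    d: int

    def __post_init__(self) -> None:
        dup = self.frame.duplicated(subset=["slide_id", "tile_id"])
        if dup.any():
            raise ValueError("duplicate (slide_id, tile_id) rows in feature table")

    @property
    def feature_columns(self) -> list[str]:
        return [f"f{i}" for i in range(self.d)]

    def matrix(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.attrs = {}
        header = f"# extractor={self.extractor_name} d={self.d}\n"
        with open(path, "w") as fh:
            fh.write(header)
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        with open(path) as fh:
            meta = fh.readline().strip().lstrip("# ")
            frame = pd.read_csv(fh, sep="\t")
        kv = dict(item.split("=") for item in meta.split())
        return cls(frame, kv["extractor"], int(kv["d"]))


def extract_features(tiles: Iterable[TileImage], extractor: str = "builtin",
                     patient_of_slide: Callable[[str], str] | None = None
                     ) -> FeatureTable:
    """Apply a registered extractor to every tile.

    ``patient_of_slide`` maps slide ids to patient ids (identity by
    default); tiles of all slides of one patient end up in one bag
    downstream.
    """
    if extractor not in _EXTRACTORS:
        raise KeyError(f"no extractor registered under {extractor!r}; "
                       f"known: {sorted(_EXTRACTORS)}")
    fn = _EXTRACTORS[extractor]
    rows = []
    d = None
    for t in tiles:
        v = np.asarray(fn(t), dtype=float).ravel()
        if d is None:
            d = v.size
        elif v.size != d:
            raise ValueError(
                f"extractor returned length {v.size}, expected {d} "
                f"(tile {t.tile_id})")
        pid = patient_of_slide(t.slide_id) if patient_of_slide else t.slide_id
        rows.append((pid, t.slide_id, t.tile_id, t.origin[0], t.origin[1], *v))
    if d is None:
        raise ValueError("no tiles given")
    cols = ["patient_id", "slide_id", "tile_id", "x", "y"] + [f"f{i}" for i in range(d)]
    return FeatureTable(pd.DataFrame(rows, columns=cols), extractor, d)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeClustering:
    """Frozen k-means phenotype vocabulary: scaler + centroids."""

    k: int
    mean_: np.ndarray
    scale_: np.ndarray
    centroids: np.ndarray        # (k, d) in standardized space
    seed: int
    inertia: float = float("nan")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment (Euclidean, standardized space)."""
        Z = self.standardize(X)
        d2 = ((Z[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k, "mean": self.mean_.tolist(), "scale": self.scale_.tolist(),
            "centroids": self.centroids.tolist(), "seed": self.seed,
            "inertia": self.inertia}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeClustering":
        d = json.loads(Path(path).read_text())
        return cls(d["k"], np.array(d["mean"]), np.array(d["scale"]),
                   np.array(d["centroids"]), d["seed"], d["inertia"])


def cluster_phenotypes(features: FeatureTable | np.ndarray, k: int = 10,
                       seed: int = 0) -> tuple[np.ndarray, PhenotypeClustering]:
    """Fit k-means (k-means++ init, seeded) on the feature population.

    Features are z-scored per dimension first (constant dimensions get unit
    scale). Returns per-tile cluster assignments and the frozen clustering.
    """
    X = features.matrix() if isinstance(features, FeatureTable) else np.asarray(features, dtype=float)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct feature vectors for k={k}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                tol=1e-6, random_state=seed)
    labels = km.fit_predict(Z)
    clustering = PhenotypeClustering(k, mean, scale, km.cluster_centers_,
                                     seed, float(km.inertia_))
    return labels, clustering


# ---------------------------------------------------------------------------
# bags
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeBag:
    """One patient's tiles partitioned into k phenotype slots."""

    patient_id: str
    k: int
    slots: list[np.ndarray]                  # k arrays of shape (n_c, d)
    tile_ids: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slots) != self.k:
            raise ValueError("number of slots must equal k")

    @property
    def counts(self) -> np.ndarray:
        return np.array([s.shape[0] for s in self.slots])

    @property
    def n_tiles(self) -> int:
        return int(self.counts.sum())

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


def build_bags(features: FeatureTable | pd.DataFrame, assignments: np.ndarray,
               k: int, patients: Sequence[str] | None = None) -> list[PhenotypeBag]:
    """Partition each patient's tiles by global cluster id.

    ``assignments`` is aligned with the rows of ``features``. Empty slots
    are permitted (shape (0, d) arrays). If ``patients`` is given, a
    patient with zero tiles raises an error naming them; otherwise patients
    are taken from the table (sorted), preserving input-order invariance.
    """
    frame = features.frame if isinstance(features, FeatureTable) else features
    assignments = np.asarray(assignments)
    if assignments.shape[0] != len(frame):
        raise ValueError("assignments do not cover all tiles")
    if assignments.size and (assignments.min() < 0 or assignments.max() >= k):
        raise ValueError("cluster assignment outside 0..k-1")
    fcols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    X = frame[fcols].to_numpy(dtype=float)
    pids = frame["patient_id"].astype(str).to_numpy()
    tids = frame["tile_id"].astype(str).to_numpy()
    present = sorted(set(pids))
    if patients is not None:
        missing = [p for p in patients if p not in set(present)]
        if missing:
            raise ValueError(f"patient(s) with zero tiles: {missing}")
        ordered = [str(p) for p in patients]
    else:
        ordered = present
    bags = []
    for pid in ordered:
        sel = pids == pid
        order = np.argsort(tids[sel], kind="stable")
        Xp = X[sel][order]
        ap = assignments[sel][order]
        tp = tids[sel][order]
        slots = [Xp[ap == c] for c in range(k)]
        ids = [tp[ap == c] for c in range(k)]
        bags.append(PhenotypeBag(pid, k, slots, ids))
    return bags


def bags_from_cohort(cohort, clustering: PhenotypeClustering) -> list[PhenotypeBag]:
    """Assign a synthetic cohort's tile features to frozen phenotype clusters."""
    bags = []
    for pid in cohort.patients:
        X = cohort.features[pid]
        a = clustering.assign(X)
        slots = [X[a == c] for c in range(clustering.k)]
        ids = [np.array([f"{pid}_t{j}" for j in np.flatnonzero(a == c)])
               for c in range(clustering.k)]
        bags.append(PhenotypeBag(pid, clustering.k, slots, ids))
    return bags
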