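"""Hemodynamic pattern recognition.

Feature points (per-voxel speed and flow direction) are embedded in a
functional feature space — (normalized speed, cos direction, sin direction)
— and partitioned by adaptive K-means: K-means is fit for every candidate
cluster count, the count with the best mean silhouette wins, and a single
pattern is declared when even the best silhouette is weak.  The resulting
patterns drive everything downstream: per-pattern sub-sequences for
super-resolved reconstruction, and the heterogeneity metrics computed from
cluster centers and occupancies.

Direction enters through its cosine and sine so that flows at +179 and
-179 degrees are neighbors, not opposites; spatial coordinates are
deliberately excluded so that the patterns are purely functional.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .synthetic import CeusSequence
from .trail import FeaturePointSet

__all__ = [
    "FeatureSpace",
    "PatternModel",
    "build_feature_space",
    "adaptive_kmeans",
    "split_sequence",
]

SILHOUETTE_FLOOR = 0.25      # below this, no real cluster structure: K = 1
SILHOUETTE_SAMPLE = 2000     # subsample size for silhouette evaluation
N_RESTARTS = 10
MAX_FIT_POINTS = 100_000     # K-means fits on a seeded subsample above this


@dataclass
class FeatureSpace:
    """Normalized feature matrix plus the affine transform that made it."""

    matrix: np.ndarray                 # (n, 3): speed_norm, cos dir, sin dir
    speed_min: float
    speed_max: float
    weights: np.ndarray                # per-column rescaling applied

    def inverse_speed(self, s_norm: np.ndarray) -> np.ndarray:
        """Map normalized speeds back to mm/s."""
        w = self.weights[0] if self.weights[0] != 0 else 1.0
        if self.speed_max == self.speed_min:
            return np.full_like(np.asarray(s_norm, dtype=float), self.speed_min)
        return np.asarray(s_norm) / w * (self.speed_max - self.speed_min) \
            + self.speed_min


@dataclass
class PatternModel:
    """Fitted hemodynamic patterns: count K, centers C_n, labels, occupancy M_n.

    Labels are 1-based (pattern n in 1..K) to match the field's usual
    pattern numbering.
    """

    K: int
    centers: np.ndarray                # (K, n_features), normalized space
    labels: np.ndarray                 # (n,), values in 1..K
    occupancy: np.ndarray              # (K,) counts M_n
    normalization: dict = field(default_factory=dict)
    selection_scores: dict = field(default_factory=dict)   # K -> silhouette
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if int(self.occupancy.sum()) != len(self.labels):
            raise ValueError("occupancy must sum to the number of points")
        if len(self.labels) and (self.labels.min() < 1 or self.labels.max() > self.K):
            raise ValueError("labels must lie in 1..K")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")

    def to_json(self) -> str:
        return json.dumps({
            "K": int(self.K),
            "centers": self.centers.tolist(),
            "occupancy": self.occupancy.tolist(),
            "normalization": self.normalization,
            "selection_scores": {str(k): float(v)
                                 for k, v in self.selection_scores.items()},
            "seed": int(self.seed),
        }, indent=2)

    def save(self, path: str):
        with open(path, "w") as fh:
            fh.write(self.to_json())


def build_feature_space(points: FeaturePointSet,
                        weights=None) -> FeatureSpace:
    """Embed feature points as (min-max normalized speed, cos dir, sin dir).

    A constant speed column has no range to normalize; it is mapped to 0.5
    with a warning.  Optional ``weights`` rescale the three columns.
    """
    if len(points) == 0:
        raise ValueError("empty feature point set")
    speed = np.asarray(points.speed, dtype=float)
    smin, smax = float(speed.min()), float(speed.max())
    if smax > smin:
        s_norm = (speed - smin) / (smax - smin)
    else:
        warnings.warn("constant speed column: normalized to 0.5", stacklevel=2)
        s_norm = np.full_like(speed, 0.5)
    mat = np.column_stack([s_norm,
                           np.cos(points.direction),
                           np.sin(points.direction)])
    w = np.ones(3) if weights is None else np.asarray(weights, dtype=float)
    mat = mat * w
    return FeatureSpace(matrix=mat, speed_min=smin, speed_max=smax, weights=w)


def adaptive_kmeans(features, k_max: int = 10, seed: int = 0) -> PatternModel:
    """Seeded K-means over K = 2..k_max; pick K by the best mean silhouette.

    When the best silhouette falls below ``SILHOUETTE_FLOOR`` the data are
    declared a single pattern (K = 1, center = mean).  Silhouettes are
    evaluated on a seeded subsample for tractability on voxel-level point
    sets, and above ``MAX_FIT_POINTS`` the K-means itself fits on a seeded
    subsample and assigns the remaining points to the nearest center.
    K is capped at the number of distinct points.  Fully deterministic for
    fixed inputs and seed.
    """
    mat = features.matrix if isinstance(features, FeatureSpace) \
        else np.asarray(features, dtype=float)
    norm = {} if not isinstance(features, FeatureSpace) else {
        "speed_min": features.speed_min, "speed_max": features.speed_max,
        "weights": features.weights.tolist()}
    n = mat.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < k_max + 1:
        raise ValueError(f"need at least k_max + 1 = {k_max + 1} points, got {n}")
    if n > MAX_FIT_POINTS:
        sub_idx = np.random.default_rng(seed).choice(n, MAX_FIT_POINTS,
                                                     replace=False)
        fit_mat = mat[sub_idx]
    else:
        fit_mat = mat
    n_distinct = len(np.unique(fit_mat, axis=0))
    k_cap = min(k_max, n_distinct)

    scores: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in range(2, k_cap + 1):
        km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
        lab = km.fit_predict(fit_mat)
        if len(np.unique(lab)) < 2:
            scores[k] = -1.0
        else:
            scores[k] = float(silhouette_score(
                fit_mat, lab, sample_size=min(len(fit_mat), SILHOUETTE_SAMPLE),
                random_state=seed))
        fits[k] = km

    if scores and max(scores.values()) >= SILHOUETTE_FLOOR:
        best_k = max(scores, key=lambda k: (scores[k], -k))
        km = fits[best_k]
        labels = (km.labels_ if fit_mat is mat else km.predict(mat)) + 1
        centers = km.cluster_centers_
        occupancy = np.bincount(labels, minlength=best_k + 1)[1:]
    else:
        best_k = 1
        labels = np.ones(n, dtype=int)
        centers = mat.mean(axis=0, keepdims=True)
        occupancy = np.array([n])

    return PatternModel(K=best_k, centers=np.asarray(centers, dtype=float),
                        labels=np.asarray(labels, dtype=int),
                        occupancy=np.asarray(occupancy, dtype=int),
                        normalization=norm, selection_scores=scores,
                        seed=seed)


def split_sequence(seq: CeusSequence, points: FeaturePointSet,
                   model: PatternModel) -> list:
    """Divide the MB signal into K voxel-disjoint per-pattern sequences.

    Sequence n keeps the original intensities at the feature-point voxels
    labeled n and is zero elsewhere, so the per-pattern sequences sum
    exactly to the masked input.  Outputs span the full length of ``seq``
    (frame indexing is absolute, so point sets merged from several
    segments split correctly).  Empty patterns yield all-zero sequences,
    kept so list indices stay aligned with pattern numbers.
    """
    if len(points) != len(model.labels):
        raise ValueError("labels do not align with feature points")
    it = np.asarray(points.t_index, dtype=int)
    _, iz, ix = points.voxel_indices
    out = []
    for k in range(1, model.K + 1):
        sel = model.labels == k
        frames = np.zeros_like(seq.frames)
        frames[it[sel], iz[sel], ix[sel]] = seq.frames[it[sel], iz[sel], ix[sel]]
        out.append(seq.copy_with(frames))
    return out
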