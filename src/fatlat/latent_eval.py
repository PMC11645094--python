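"""Cluster-drift indices on per-set latent point clouds.

Each set of 10 repetitions of one exercise maps to a cluster of 10 points in
the 2-D latent space.  Fatigue-related drift is quantified by four indices:

* silhouette score of cluster *i* against the initial cluster 0,
* Davies-Bouldin index of the same pair (for two clusters the average of
  maximum similarities reduces to the single ratio ``(S_i + S_0) / d``),
* the area of the 95% confidence ellipse of cluster *i* alone, assuming a
  bivariate normal distribution,
* the Euclidean distance between the centroids of cluster *i* and cluster 0.

Degenerate geometry (coincident centroids, singular covariance) yields
flagged missing records rather than aborting; downstream regression drops
flagged rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.metrics import silhouette_score

INDEX_NAMES = ("silhouette", "davies_bouldin", "ellipse_area", "centroid_distance")


class CoincidentCentroidsError(ValueError):
    pass


@dataclass
class SetCluster:
    """Latent points of one set of one exercise for one participant."""

    participant_id: str
    exercise: str
    set_index: int
    points: np.ndarray  # (n_points, 2)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def covariance(self) -> np.ndarray:
        return np.cov(self.points, rowvar=False, bias=False)


def _as_points(c) -> np.ndarray:
    return c.points if isinstance(c, SetCluster) else np.asarray(c, dtype=float)


def silhouette_pair(cluster_i, cluster_0) -> float:
    """Mean silhouette over both clusters' points in the 2-cluster labelling.

    Near 0 for overlapping clusters, approaching 1 for clusters separated by
    much more than their spread.  Fully coincident point sets score 0.
    """
    a, b = _as_points(cluster_i), _as_points(cluster_0)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("silhouette requires >= 2 points per cluster")
    if a.shape == b.shape and np.allclose(a, b):
        return 0.0  # identical point sets: cohesion equals separation
    X = np.vstack([a, b])
    if np.allclose(X, X[0]):
        return 0.0  # all points identical
    labels = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    return float(silhouette_score(X, labels, metric="euclidean"))


def davies_bouldin_pair(cluster_i, cluster_0, eps: float = 1e-12) -> float:
    """Two-cluster Davies-Bouldin index ``(S_i + S_0) / d(c_i, c_0)``.

    ``S`` is the mean Euclidean distance of a cluster's points to its own
    centroid.  With exactly two clusters, each cluster's maximum similarity
    to any other is the same single ratio, so the index equals it directly.
    """
    a, b = _as_points(cluster_i), _as_points(cluster_0)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    d = float(np.linalg.norm(ca - cb))
    if d <= eps:
        raise CoincidentCentroidsError(
            f"centroid separation {d:.3g} below tolerance {eps:.3g}")
    s_a = float(np.linalg.norm(a - ca, axis=1).mean())
    s_b = float(np.linalg.norm(b - cb, axis=1).mean())
    return (s_a + s_b) / d


def davies_bouldin(clusters: list) -> float:
    """General Davies-Bouldin index (average of maximum pairwise similarity).

    Provided for >= 3 clusters; for exactly two it equals
    :func:`davies_bouldin_pair`.
    """
    pts = [_as_points(c) for c in clusters]
    if len(pts) < 2:
        raise ValueError("need >= 2 clusters")
    cents = [p.mean(axis=0) for p in pts]
    scatter = [float(np.linalg.norm(p - c, axis=1).mean()) for p, c in zip(pts, cents)]
    k = len(pts)
    worst = np.zeros(k)
    for i in range(k):
        sims = [(scatter[i] + scatter[j]) / np.linalg.norm(cents[i] - cents[j])
                for j in range(k) if j != i]
        worst[i] = max(sims)
    return float(worst.mean())


def ellipse_area(cluster, coverage: float = 0.95,
                 regularize: float = 0.0) -> float:
    """Area of the coverage-level confidence ellipse of a fitted normal.

    ``area = pi * q * sqrt(det(S))`` with ``q`` the chi-square(2 dof)
    quantile at the coverage level and ``S`` the sample covariance.  A
    singular covariance raises unless ``regularize`` adds ``eps * I``.
    """
    p = _as_points(cluster)
    if len(p) < 3:
        raise ValueError("ellipse_area requires >= 3 points")
    S = np.cov(p, rowvar=False, bias=False)
    det = float(np.linalg.det(S))
    if det <= 0:
        if regularize > 0:
            det = float(np.linalg.det(S + regularize * np.eye(2)))
        else:
            raise ValueError("singular covariance (collinear points)")
    q = chi2.ppf(coverage, df=2)
    return float(np.pi * q * np.sqrt(det))


def centroid_distance(cluster_i, cluster_0) -> float:
    """Euclidean distance between the two cluster centroids."""
    a, b = _as_points(cluster_i), _as_points(cluster_0)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("clusters must be non-empty")
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


def index_table(clusters: list[SetCluster], fold=None, variant=None) -> pd.DataFrame:
    """All four indices across the ordered sets of one participant/exercise.

    ``ellipse_area`` is computed for every set; the comparative indices
    (silhouette, Davies-Bouldin, centroid distance) compare each set i >= 1
    with set 0.  Degenerate cases are emitted as rows with ``missing=True``
    and a reason instead of a value.
    """
    clusters = sorted(clusters, key=lambda c: c.set_index)
    if not clusters or clusters[0].set_index != 0:
        raise ValueError("missing initial set (set_index 0)")
    base = clusters[0]
    rows = []

    def emit(c, name, fn):
        row = {"participant": c.participant_id, "exercise": c.exercise,
               "set": c.set_index, "fold": fold, "variant": variant,
               "index": name, "value": np.nan, "missing": True, "reason": ""}
        try:
            row["value"] = fn()
            row["missing"] = False
        except (CoincidentCentroidsError, ValueError) as e:
            row["reason"] = str(e)
        rows.append(row)

    for c in clusters:
        emit(c, "ellipse_area", lambda c=c: ellipse_area(c))
        if c.set_index == 0:
            continue
        emit(c, "silhouette", lambda c=c: silhouette_pair(c, base))
        emit(c, "davies_bouldin", lambda c=c: davies_bouldin_pair(c, base))
        emit(c, "centroid_distance", lambda c=c: centroid_distance(c, base))
    return pd.DataFrame(rows)


def clusters_from_latents(latents: pd.DataFrame) -> list[SetCluster]:
    """Group a tidy latents table into per-set clusters.

    Expects columns participant, exercise, set, rep, z1, z2.
    """
    out = []
    for (pid, ex, si), g in latents.groupby(["participant", "exercise", "set"]):
        out.append(SetCluster(participant_id=pid, exercise=ex, set_index=int(si),
                              points=g.sort_values("rep")[["z1", "z2"]].to_numpy()))
    return out


def index_table_from_latents(latents: pd.DataFrame) -> pd.DataFrame:
    """Tidy index table from a tidy latents table (one row per point).

    Expects columns participant, exercise, set, rep, z1, z2 and optionally
    fold and variant (propagated to the output).
    """
    frames = []
    keys = ["participant", "exercise"]
    extra = [k for k in ("fold", "variant") if k in latents.columns]
    for key, g in latents.groupby(extra + keys):
        key = dict(zip(extra + keys, key))
        frames.append(index_table(clusters_from_latents(g),
                                  fold=key.get("fold"), variant=key.get("variant")))
    return pd.concat(frames, ignore_index=True)
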