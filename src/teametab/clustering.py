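"""Trend clustering of discriminatory features across processing stages.

Features selected as stage-discriminatory are grouped by the shape of
their percentage-relative-abundance profile with k-means (Lloyd's
algorithm, k-means++ initialisation, best of 25 restarts by WCSS) on the
raw percentage vectors — percentages already share a 0-100 scale, so no
z-scoring is applied by default.  k-selection diagnostics report the mean
silhouette and WCSS over a k range; the silhouette argmax is recommended
but the final k remains an analyst's choice.

Cluster ids are canonicalised 1..k by descending cluster size so reports
are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import EmptyInputError


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series  # feature -> cluster id in 1..k
    centroids: pd.DataFrame  # cluster id x stage
    silhouette: float
    wcss: float
    seed: int
    n_init: int

    @property
    def members(self) -> dict[int, list[str]]:
        return {
            int(c): list(self.labels.index[self.labels == c])
            for c in sorted(self.labels.unique())
        }


def _as_frame(profiles) -> pd.DataFrame:
    frame = pd.DataFrame(profiles)
    if frame.empty:
        raise EmptyInputError("no profiles to cluster")
    if not np.isfinite(frame.to_numpy(dtype=float)).all():
        raise ValueError("profiles contain non-finite values")
    return frame


def _canonicalise(raw_labels: np.ndarray, index: pd.Index) -> pd.Series:
    """Renumber clusters 1..k by descending size (ties: first appearance)."""
    sizes = pd.Series(raw_labels).value_counts()
    first_pos = {c: int(np.argmax(raw_labels == c)) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first_pos[c]))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([mapping[c] for c in raw_labels], index=index, dtype=int)


def kmeans(
    profiles,
    k: int,
    seed: int,
    n_init: int = 25,
    max_iter: int = 300,
    tol: float = 1e-6,
    scale: bool = False,
) -> ClusterResult:
    """Cluster stage profiles into k trend groups (Euclidean k-means).

    ``scale=True`` z-scores each stage column first (sensitivity
    analysis); the default works on the raw percentage vectors.
    """
    frame = _as_frame(profiles)
    if not 1 <= k <= len(frame):
        raise ValueError(f"k={k} outside [1, {len(frame)}]")
    X = frame.to_numpy(dtype=float)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    labels = _canonicalise(km.labels_, frame.index)
    centroids = pd.DataFrame(
        [frame[labels == c].mean(axis=0) for c in range(1, k + 1)],
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=frame.columns,
    )
    sil = silhouette_mean(frame, labels) if 2 <= k < len(frame) else float("nan")
    return ClusterResult(
        k=k,
        labels=labels,
        centroids=centroids,
        silhouette=sil,
        wcss=wcss(frame, labels),
        seed=seed,
        n_init=n_init,
    )


def wcss(profiles, assignment: pd.Series) -> float:
    """Within-cluster sum of squared Euclidean distances to centroids."""
    frame = _as_frame(profiles)
    labels = pd.Series(assignment)
    total = 0.0
    for c in labels.unique():
        sub = frame[labels == c].to_numpy(dtype=float)
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def silhouette_mean(profiles, assignment: pd.Series) -> float:
    """Mean silhouette (b - a) / max(a, b) over points; in [-1, 1]."""
    frame = _as_frame(profiles)
    labels = pd.Series(assignment)
    k = labels.nunique()
    if k < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if k >= len(frame):
        raise ValueError("silhouette undefined for singleton-only clusterings")
    return float(
        silhouette_score(frame.to_numpy(dtype=float), labels.to_numpy())
    )


def select_k(
    profiles, k_range, seed: int, n_init: int = 25
) -> tuple[pd.DataFrame, int]:
    """Silhouette/WCSS diagnostics per k; recommend the silhouette argmax.

    The recommendation is advisory: WCSS elbows and interpretability of
    the resulting trends legitimately override it.
    """
    frame = _as_frame(profiles)
    ks = [int(k) for k in k_range]
    if not ks:
        raise EmptyInputError("empty k range")
    if min(ks) < 2 or max(ks) > len(frame) - 1:
        raise ValueError(f"k range must lie within [2, {len(frame) - 1}]")
    rows = []
    for k in ks:
        res = kmeans(frame, k, seed=seed, n_init=n_init)
        rows.append({"k": k, "silhouette": res.silhouette, "wcss": res.wcss})
    diagnostics = pd.DataFrame(rows)
    recommended = int(diagnostics.loc[diagnostics["silhouette"].idxmax(), "k"])
    return diagnostics, recommended
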