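"""K-means clustering of group-mean expression profiles within a category.

Each probeset (or gene representative) is reduced to a 4-vector of design
cell means on the log2 scale, ordered control, factor-2 treated, factor-1
treated, both treated.  Profiles are z-scored across the four values so the
clustering groups by *shape* rather than absolute expression — constant
profiles map to the all-zero vector.  K-means uses Euclidean distance with
k-means++ seeding, the best of ``n_restarts`` runs by inertia, and a final
Lloyd polish to a strict assignment fixed point.  Cluster indices are then
relabeled deterministically by descending cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import CELL_ORDER, ExpressionBundle

__all__ = ["PROFILE_COLUMNS", "DEFAULT_K", "ClusterModel", "build_profiles", "kmeans_cluster"]

PROFILE_COLUMNS = [
    "mean_control",
    "mean_factor2",
    "mean_factor1",
    "mean_both",
]

#: default cluster counts per response category
DEFAULT_K = {"A": 2, "B": 2, "C": 4, "D": 8}


@dataclass
class ClusterModel:
    category: str
    k: int
    centroids: np.ndarray
    assignments: pd.Series  # id -> cluster index (0-based, by descending size)
    inertia: float
    seed: int
    n_restarts: int
    restart_inertias: np.ndarray = field(default_factory=lambda: np.empty(0))


def build_profiles(
    bundle: ExpressionBundle,
    calls: pd.DataFrame,
    category: str,
    id_column: str = "probeset_id",
) -> pd.DataFrame:
    """Standardized 4-cell mean profiles of the calls in one category.

    Returns a DataFrame indexed by id with raw mean columns
    (:data:`PROFILE_COLUMNS`) and z-scored copies (``z_*``).  An empty
    category yields an empty frame.
    """
    members = calls.loc[calls["category"] == category, id_column].astype(str)
    rep_col = "representative_probeset" if "representative_probeset" in calls.columns else id_column
    probes = calls.loc[calls["category"] == category, rep_col].astype(str)
    if members.empty:
        return pd.DataFrame(columns=PROFILE_COLUMNS + [f"z_{c}" for c in PROFILE_COLUMNS])
    log2v = np.log2(bundle.values.loc[probes.to_numpy()].to_numpy(dtype=float) + 1.0)
    col_pos = {s: k for k, s in enumerate(bundle.sample_ids)}
    cells = bundle.cell_samples()
    means = np.column_stack(
        [
            log2v[:, [col_pos[s] for s in cells[cell]]].mean(axis=1)
            for cell in CELL_ORDER
        ]
    )
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / sd, 0.0)
    out = pd.DataFrame(means, columns=PROFILE_COLUMNS, index=members.to_numpy())
    for j, c in enumerate(PROFILE_COLUMNS):
        out[f"z_{c}"] = z[:, j]
    return out


def _lloyd_polish(x: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run Lloyd iterations until the assignment stops changing."""
    labels = None
    while True:
        dists = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = dists.argmin(axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            return labels, centroids
        labels = new_labels
        for j in range(centroids.shape[0]):
            mask = labels == j
            if mask.any():
                centroids[j] = x[mask].mean(axis=0)


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 17,
    n_restarts: int = 50,
    category: str = "",
) -> ClusterModel:
    """Cluster standardized profiles into k groups.

    Uses scikit-learn's k-means++ with ``n_restarts`` initializations, keeps
    the best run by inertia, polishes it to a Lloyd fixed point, and
    relabels clusters by descending size (ties broken by centroid values)
    so labels are reproducible across runs with the same seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    z_cols = [c for c in profiles.columns if c.startswith("z_")]
    if not z_cols:
        raise ValueError("profiles lack standardized z_* columns")
    x = profiles[z_cols].to_numpy(dtype=float)
    if len(x) < k:
        raise ValueError(
            f"cannot form {k} clusters from {len(x)} profiles"
            + (f" in category {category}" if category else "")
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=int(seed) % (2**32),
        tol=1e-12,
        max_iter=500,
    ).fit(x)
    labels, centroids = _lloyd_polish(x, km.cluster_centers_.copy())

    # deterministic relabeling: descending size, centroid lexicographic tiebreak
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda j: (-sizes[j], tuple(np.round(centroids[j], 12))))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[l] for l in labels])
    centroids = centroids[order]
    inertia = float(((x - centroids[labels]) ** 2).sum())
    return ClusterModel(
        category=category,
        k=k,
        centroids=centroids,
        assignments=pd.Series(labels, index=profiles.index, name="cluster"),
        inertia=inertia,
        seed=seed,
        n_restarts=n_restarts,
    )
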