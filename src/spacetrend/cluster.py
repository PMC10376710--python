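"""Two-level agglomerative clustering of classified series.

Within one subject and one trend class, series are first clustered into
groups (G) by the similarity of their autocorrelation profiles
(correlation-based dissimilarity, 1 - Pearson r), then each group is split
into subgroups (S) by the similarity of the normalized series themselves
(Euclidean).  Both levels use average-linkage hierarchical clustering, and
the number of clusters is chosen by maximizing the mean silhouette over
k = 2..min(n-1, cap), ties going to the smallest k; sets with fewer than
three members bypass silhouette selection and form a single cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from spacetrend.grid import TimeGrid
from spacetrend.spectral import LAG, autocorrelation_profile, spectral_grids

#: Largest cluster count ever considered by silhouette selection.
SILHOUETTE_CAP = 8

#: Dissimilarities below this are treated as "all members identical".
_IDENTICAL_TOL = 1e-10


def correlation_dissimilarity(vectors: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r.  Zero-variance vectors compare as identical
    (dissimilarity 0) when equal and maximally distant (2) otherwise."""
    vectors = np.asarray(vectors, dtype=float)
    n = len(vectors)
    centered = vectors - vectors.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    diss = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] < _IDENTICAL_TOL or norms[j] < _IDENTICAL_TOL:
                d = 0.0 if np.allclose(vectors[i], vectors[j]) else 2.0
            else:
                r = float(np.dot(centered[i], centered[j]) / (norms[i] * norms[j]))
                d = 1.0 - r
            diss[i, j] = diss[j, i] = max(d, 0.0)
    return diss


def choose_k_silhouette(
    dissimilarity: np.ndarray,
    k_range: range | None = None,
    cap: int = SILHOUETTE_CAP,
) -> tuple[int, np.ndarray]:
    """Pick the cluster count by mean silhouette and return (k, labels).

    Average-linkage labels are computed for each candidate k; ties prefer
    the smallest k.  n < 3 yields a single cluster, as does a set whose
    members are all mutually identical.
    """
    diss = np.asarray(dissimilarity, dtype=float)
    n = len(diss)
    if diss.shape != (n, n) or not np.allclose(diss, diss.T):
        raise ValueError("dissimilarity must be a symmetric square matrix")
    if n < 3 or diss.max() < _IDENTICAL_TOL:
        return 1, np.ones(n, dtype=int)
    link = linkage(squareform(diss, checks=False), method="average")
    if k_range is None:
        k_range = range(2, min(n - 1, cap) + 1)
    best_k, best_score, best_labels = 1, -np.inf, np.ones(n, dtype=int)
    for k in k_range:
        labels = fcluster(link, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(diss, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, labels
    return best_k, best_labels


def cluster_groups(profiles: np.ndarray) -> np.ndarray:
    """First-level group labels (1-based) from autocorrelation profiles."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if len(profiles) == 1:
        return np.array([1])
    _, labels = choose_k_silhouette(correlation_dissimilarity(profiles))
    return labels


def cluster_subgroups(members: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Second-level subgroup labels (1-based) from normalized series."""
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if len(members) == 1:
        return np.array([1])
    filled = np.nan_to_num(members, nan=0.0)
    if metric == "euclidean":
        diss = squareform(pdist(filled))
    elif metric == "correlation":
        diss = correlation_dissimilarity(filled)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    _, labels = choose_k_silhouette(diss)
    return labels


def class_label(kind: str, lag: int | None) -> str:
    """Printable class label: Lag1, Lag2, ..., SpikeMax, SpikeMin."""
    if kind == LAG:
        return f"Lag{int(lag)}"
    return {"spike_max": "SpikeMax", "spike_min": "SpikeMin"}.get(kind, "NoTrend")


def cluster_cohort(
    classification: pd.DataFrame,
    normalized: pd.DataFrame,
    grid: TimeGrid | None = None,
    significant_only: bool = True,
    subgroup_metric: str = "euclidean",
) -> pd.DataFrame:
    """Group/subgroup assignments for every classified series.

    Clustering is performed independently per subject and per class label
    (Lag1, Lag2, ..., SpikeMax, SpikeMin).  Returns a frame with columns
    subject_id, measurement_id, class_label, group, subgroup.
    """
    grid = grid or TimeGrid()
    grids = spectral_grids(grid)
    table = classification[classification["kind"] != "no_trend"]
    if significant_only:
        table = table[table["significant"]]
    rows = []
    for (sid, label), chunk in table.assign(
        label=[class_label(k, m) for k, m in zip(table["kind"], table["lag"])]
    ).groupby(["subject_id", "label"], sort=True):
        mids = chunk["measurement_id"].tolist()
        values = normalized.loc[[(sid, m) for m in mids]].to_numpy(dtype=float)
        profiles = np.array([
            autocorrelation_profile(v, grids).rho for v in values
        ])
        groups = cluster_groups(profiles)
        for g in np.unique(groups):
            sel = groups == g
            subs = cluster_subgroups(values[sel], metric=subgroup_metric)
            for mid, s in zip(np.array(mids)[sel], subs):
                rows.append((sid, mid, label, int(g), int(s)))
    out = pd.DataFrame(
        rows, columns=["subject_id", "measurement_id", "class_label", "group", "subgroup"]
    )
    return out.sort_values(["subject_id", "class_label", "group", "subgroup",
                            "measurement_id"]).reset_index(drop=True)
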