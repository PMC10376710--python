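"""Cross-subject similarity network and consensus communities.

For every measurement m, the Euclidean distance between the Lomb-Scargle
periodograms of two subjects' series quantifies how differently that
biomarker evolved in the two subjects.  A bootstrap set of null signals
(values resampled with replacement from the cohort pool) yields a null
distribution of periodogram distances whose configured quantile (default
0.99) becomes the similarity radius d_q.  Each per-measurement distance
matrix is binarized strictly below d_q and the binary matrices are summed
into a weighted adjacency A = sum_m R_m: the weight of an edge counts the
measurements for which the two subjects' temporal behavior is similar.
Pairs that do not share a measurement simply contribute nothing; subjects
sharing no measurement with anyone remain isolated nodes.

Community detection embeds the adjacency with a regularized generalized-SVD
(degree-normalized) spectral embedding in ``dim`` dimensions (default 2) and
clusters the embedding with k-means, k either fixed or selected by
silhouette.  The embed-and-cluster step is repeated ``n_runs`` times with
varied k-means initialization; run labels are aligned through a
co-association matrix and every node receives its highest-frequency
community membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from spacetrend.grid import TimeGrid
from spacetrend.spectral import (
    bootstrap_series,
    _batch_power,
    lomb_scargle_power,
    spectral_grids,
)

DEFAULT_RADIUS_LEVEL = 0.99
DEFAULT_N_SIGNALS = 50_000
#: Null-distance pairs sampled (with replacement) to estimate the radius.
DEFAULT_N_PAIRS = 1_000_000


def cohort_periodograms(
    normalized: pd.DataFrame, grid: TimeGrid | None = None
) -> pd.DataFrame:
    """Periodogram of every (subject, measurement) series on the shared grid.

    Returns a frame indexed like ``normalized`` with one column per
    frequency.  Series with fewer than 3 present bins are skipped.
    """
    grid = grid or TimeGrid()
    grids = spectral_grids(grid)
    rows, keys = [], []
    for key, series in normalized.iterrows():
        values = series.to_numpy(dtype=float)
        if np.sum(~np.isnan(values)) < 3:
            continue
        rows.append(lomb_scargle_power(values, grids.times, grids.freqs))
        keys.append(key)
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(keys, names=["subject_id", "measurement_id"])
        if keys else normalized.index[:0],
        columns=[f"f{k}" for k in range(1, len(grids.freqs) + 1)],
    )


def periodogram_distances(
    periodograms: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Per-measurement subject-by-subject Euclidean distance matrices.

    Entries are NaN when either subject lacks the measurement.  Returns the
    matrices and the full subject roster (sorted).
    """
    roster = sorted(periodograms.index.get_level_values("subject_id").unique())
    out: dict[str, pd.DataFrame] = {}
    for mid, chunk in periodograms.groupby(level="measurement_id", sort=True):
        chunk = chunk.droplevel("measurement_id")
        mat = pd.DataFrame(np.nan, index=roster, columns=roster)
        subs = [s for s in roster if s in chunk.index]
        if subs:
            d = cdist(chunk.loc[subs].to_numpy(), chunk.loc[subs].to_numpy())
            mat.loc[subs, subs] = d
        np.fill_diagonal(mat.values, 0.0)
        out[mid] = mat
    return out, roster


@dataclass(frozen=True)
class SimilarityRadius:
    d_q: float
    level: float
    n_signals: int
    n_pairs: int
    seed: int


def bootstrap_periodogram_distances(
    pool: np.ndarray,
    grid: TimeGrid | None = None,
    n_signals: int = DEFAULT_N_SIGNALS,
    n_pairs: int = DEFAULT_N_PAIRS,
    seed: int = 0,
) -> np.ndarray:
    """Distances between periodograms of random pairs of bootstrap signals.

    ``n_pairs`` unordered pairs are sampled uniformly (with replacement)
    from the n_signals bootstrap set; sampling pairs rather than
    enumerating all ~n^2/2 keeps the cost linear while estimating the same
    distance distribution.
    """
    grid = grid or TimeGrid()
    grids = spectral_grids(grid)
    rng = np.random.default_rng(seed)
    signals = bootstrap_series(pool, n_signals, len(grids.times), rng)
    power = _batch_power(signals, grids.times, grids.freqs)
    i = rng.integers(0, n_signals, size=n_pairs)
    j = rng.integers(0, n_signals, size=n_pairs)
    keep = i != j
    return np.linalg.norm(power[i[keep]] - power[j[keep]], axis=1)


def similarity_radius(
    pool: np.ndarray,
    grid: TimeGrid | None = None,
    n_signals: int = DEFAULT_N_SIGNALS,
    level: float = DEFAULT_RADIUS_LEVEL,
    n_pairs: int = DEFAULT_N_PAIRS,
    seed: int = 0,
) -> SimilarityRadius:
    """Similarity radius d_q: the ``level`` quantile of null periodogram
    distances among bootstrap signals drawn from the cohort value pool."""
    distances = bootstrap_periodogram_distances(
        pool, grid, n_signals=n_signals, n_pairs=n_pairs, seed=seed
    )
    return SimilarityRadius(
        d_q=float(np.quantile(distances, level)),
        level=level, n_signals=n_signals, n_pairs=n_pairs, seed=seed,
    )


def restricted_adjacency(
    distances: dict[str, pd.DataFrame],
    radius: SimilarityRadius | float,
    roster: list[str] | None = None,
) -> tuple[pd.DataFrame, nx.Graph, dict[tuple[str, str], list[str]]]:
    """Binarize each distance matrix strictly below d_q and sum.

    Returns the integer adjacency frame, the corresponding weighted graph
    (isolated subjects included as nodes), and, per edge, the list of
    measurements driving it.
    """
    d_q = radius.d_q if isinstance(radius, SimilarityRadius) else float(radius)
    if roster is None:
        roster = sorted(next(iter(distances.values())).index) if distances else []
    n = len(roster)
    adj = np.zeros((n, n), dtype=int)
    edge_measurements: dict[tuple[str, str], list[str]] = {}
    for mid in sorted(distances):
        d = distances[mid].reindex(index=roster, columns=roster).to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            r = (d < d_q) & ~np.isnan(d)
        np.fill_diagonal(r, False)
        adj += r.astype(int)
        for a, b in zip(*np.nonzero(np.triu(r, k=1))):
            edge_measurements.setdefault((roster[a], roster[b]), []).append(mid)
    adjacency = pd.DataFrame(adj, index=roster, columns=roster)
    g = nx.Graph()
    g.add_nodes_from(roster)
    for a in range(n):
        for b in range(a + 1, n):
            if adj[a, b] > 0:
                g.add_edge(roster[a], roster[b], weight=int(adj[a, b]))
    return adjacency, g, edge_measurements


def gsvd_embedding(
    adjacency: np.ndarray, dim: int = 2, reg: float = 0.01
) -> np.ndarray:
    """Regularized degree-normalized spectral (generalized-SVD) embedding.

    A constant reg * mean(A) (or reg when A is all-zero) is added to every
    entry, the matrix is normalized by its row and column degree square
    roots, and the leading ``dim`` singular vectors — scaled by their
    singular values and the inverse degree square roots — give the node
    coordinates.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    mean = a.mean()
    a = a + reg * (mean if mean > 0 else 1.0)
    d1 = a.sum(axis=1)
    d2 = a.sum(axis=0)
    norm = np.sqrt(np.outer(d1, d2))
    u, s, _ = np.linalg.svd(a / norm)
    dim = min(dim, n)
    return (u[:, :dim] * s[:dim]) / np.sqrt(d1)[:, None]


def _select_k(points: np.ndarray, k_cap: int, rng: np.random.Generator) -> int:
    """Silhouette-selected k for one k-means run (ties -> smallest k)."""
    n = len(points)
    n_distinct = len(np.unique(points.round(decimals=10), axis=0))
    best_k, best_score = 2, -np.inf
    for k in range(2, min(n - 1, n_distinct, k_cap) + 1):
        km = KMeans(n_clusters=k, n_init=3,
                    random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(points)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(points, labels)
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return best_k


@dataclass
class CommunityLabeling:
    """Consensus communities of the cohort graph."""

    labels: pd.Series              # final community per node
    frequencies: pd.DataFrame      # node x community membership frequency
    k: int
    dim: int
    n_runs: int


def consensus_communities(
    adjacency: pd.DataFrame,
    dim: int = 2,
    k_mode: str = "auto",
    k: int | None = None,
    n_runs: int = 1000,
    seed: int = 0,
    k_cap: int = 8,
    reg: float = 0.01,
) -> CommunityLabeling:
    """Consensus embed-and-cluster community detection.

    The embedding is deterministic; each of the ``n_runs`` repetitions draws
    a fresh k-means initialization (and, in ``auto`` mode, re-selects k by
    silhouette).  Run labels are aligned to a reference partition derived
    from the co-association matrix via the Hungarian method, and each node
    is assigned its most frequent aligned label.
    """
    roster = list(adjacency.index)
    n = len(roster)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if k_mode not in ("auto", "fixed"):
        raise ValueError("k_mode must be 'auto' or 'fixed'")
    if k_mode == "fixed":
        if k is None:
            raise ValueError("fixed k_mode requires k")
        if k > n:
            raise ValueError(f"k={k} exceeds the number of nodes ({n})")
    points = gsvd_embedding(adjacency.to_numpy(), dim=dim, reg=reg)
    rng = np.random.default_rng(seed)
    runs = np.empty((n_runs, n), dtype=int)
    ks = np.empty(n_runs, dtype=int)
    with warnings.catch_warnings():
        # duplicate embedding coordinates can leave k-means with fewer
        # distinct clusters than requested; that is expected on toy graphs
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        for r in range(n_runs):
            k_run = k if k_mode == "fixed" else _select_k(points, k_cap, rng)
            km = KMeans(n_clusters=k_run, n_init=1,
                        random_state=int(rng.integers(2**31)))
            runs[r] = km.fit_predict(points)
            ks[r] = k_run
    # co-association: fraction of runs in which two nodes share a cluster
    coassoc = np.zeros((n, n))
    for r in range(n_runs):
        coassoc += runs[r][:, None] == runs[r][None, :]
    coassoc /= n_runs
    k_final = int(k) if k_mode == "fixed" else int(np.bincount(ks).argmax())
    k_final = min(k_final, n)
    if n > 2 and k_final > 1:
        link = linkage(squareform(1.0 - coassoc, checks=False), method="average")
        reference = fcluster(link, k_final, criterion="maxclust") - 1
    else:
        reference = np.zeros(n, dtype=int) if k_final == 1 else np.arange(n)
    n_labels = max(k_final, reference.max() + 1, runs.max() + 1)
    counts = np.zeros((n, n_labels))
    for r in range(n_runs):
        overlap = np.zeros((n_labels, n_labels))
        for lab, ref in zip(runs[r], reference):
            overlap[lab, ref] += 1
        rows, cols = linear_sum_assignment(-overlap)
        mapping = dict(zip(rows, cols))
        aligned = np.array([mapping[lab] for lab in runs[r]])
        counts[np.arange(n), aligned] += 1
    freqs = counts / n_runs
    final = freqs.argmax(axis=1)
    # relabel communities in order of first appearance for determinism
    remap: dict[int, int] = {}
    for lab in final:
        if lab not in remap:
            remap[lab] = len(remap)
    order = sorted(remap, key=remap.get)
    return CommunityLabeling(
        labels=pd.Series([remap[lab] for lab in final], index=roster, name="community"),
        frequencies=pd.DataFrame(freqs[:, order], index=roster,
                                 columns=[remap[lab] for lab in order]),
        k=k_final, dim=dim, n_runs=n_runs,
    )


def community_report(
    labeling: CommunityLabeling,
    edge_measurements: dict[tuple[str, str], list[str]],
    top: int = 5,
) -> dict:
    """Per-community sizes and the measurements driving intra-community edges."""
    report = {}
    for community in sorted(labeling.labels.unique()):
        members = sorted(labeling.labels[labeling.labels == community].index)
        counts: dict[str, int] = {}
        for (a, b), mids in edge_measurements.items():
            if a in members and b in members:
                for mid in mids:
                    counts[mid] = counts.get(mid, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
        report[str(community)] = {
            "size": len(members),
            "members": members,
            "top_measurements": [{"measurement_id": m, "edges": c} for m, c in ranked],
        }
    return report


def write_graphml(
    g: nx.Graph, labeling: CommunityLabeling | None, path
) -> None:
    """GraphML export with community and membership-frequency node attributes."""
    out = g.copy()
    if labeling is not None:
        for node in out.nodes:
            out.nodes[node]["community"] = int(labeling.labels[node])
            for community in labeling.frequencies.columns:
                out.nodes[node][f"freq_{community}"] = float(
                    labeling.frequencies.loc[node, community]
                )
    nx.write_graphml(out, path)


def write_edgelist(g: nx.Graph, path) -> None:
    rows = [(a, b, d["weight"]) for a, b, d in sorted(g.edges(data=True))]
    pd.DataFrame(rows, columns=["subject_a", "subject_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )
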