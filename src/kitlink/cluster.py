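"""SNN-graph community detection and one-vs-rest Wilcoxon marker genes.

Cells are connected by a shared-nearest-neighbor (SNN) graph: k-nearest
neighbors by Euclidean distance in the PCA embedding, edge weight equal
to the Jaccard overlap of the two cells' neighbor sets, weights below a
pruning floor dropped.  Communities are found by seeded modularity
optimization with a resolution parameter (Leiden refinement of the
Louvain objective), swept over a 0.1–2.0 grid when choosing a
resolution.  Markers are one-vs-rest two-sided Wilcoxon rank-sum tests
with detection-fraction, log-fold-change and Bonferroni filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors


@dataclass
class ClusterConfig:
    k_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 0.9
    sweep_range: tuple[float, float, float] = (0.1, 2.0, 0.1)
    random_seed: int = 0


@dataclass
class MarkerThresholds:
    min_pct: float = 0.10
    min_avg_lfc: float = 0.25
    max_adj_p: float = 0.01


def build_snn_graph(embedding: np.ndarray,
                    cfg: ClusterConfig = ClusterConfig()) -> igraph.Graph:
    """Jaccard-weighted shared-nearest-neighbor graph over cells.

    Neighbor sets include the cell itself, so duplicated cells share all
    k neighbors and get weight 1.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    k = cfg.k_neighbors
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    # row i marks i's k-neighbor set (self included by construction)
    A = sp.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), idx.ravel())),
        shape=(n, n))
    shared = (A @ A.T).tocoo()
    r, c, s = shared.row, shared.col, shared.data
    upper = r < c
    r, c, s = r[upper], c[upper], s[upper]
    jac = s / (2 * k - s)
    keep = jac >= cfg.snn_prune
    g = igraph.Graph(n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())),
                     edge_attrs={"weight": jac[keep].tolist()})
    return g


def louvain_cluster(graph: igraph.Graph,
                    cfg: ClusterConfig = ClusterConfig(),
                    resolution: float | None = None) -> np.ndarray:
    """Seeded modularity clustering; labels 0..K−1 by descending size."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    res = cfg.resolution if resolution is None else resolution
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.edge_attributes() else None,
        resolution_parameter=res, seed=cfg.random_seed, n_iterations=-1)
    labels = np.asarray(part.membership)
    order = np.argsort([-np.sum(labels == l) for l in range(labels.max() + 1)],
                       kind="stable")
    remap = np.empty(labels.max() + 1, dtype=int)
    remap[order] = np.arange(len(order))
    return remap[labels]


@dataclass
class SweepResult:
    table: pd.DataFrame                      # resolution, n_clusters
    labels: dict[float, np.ndarray]          # resolution → per-cell labels
    crossover: pd.DataFrame                  # res, cluster, next_cluster, fraction


def resolution_sweep(graph: igraph.Graph,
                     cfg: ClusterConfig = ClusterConfig()) -> SweepResult:
    """Cluster at every grid resolution with a shared seed.

    Also emits, for each consecutive resolution pair, how each cluster's
    cells redistribute over the clusters of the next resolution (the
    fractions per source cluster sum to 1); the best-matching target is
    the one receiving the largest fraction.
    """
    lo, hi, step = cfg.sweep_range
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    labels = {}
    rows = []
    for res in grid:
        lab = louvain_cluster(graph, cfg, resolution=float(res))
        labels[float(res)] = lab
        rows.append({"resolution": float(res),
                     "n_clusters": int(lab.max() + 1)})
    xover = []
    for r0, r1 in zip(grid[:-1], grid[1:]):
        a, b = labels[float(r0)], labels[float(r1)]
        tab = pd.crosstab(a, b, normalize="index")
        for cl in tab.index:
            for nxt in tab.columns:
                f = float(tab.loc[cl, nxt])
                if f > 0:
                    xover.append({"resolution": float(r0), "cluster": int(cl),
                                  "next_cluster": int(nxt), "fraction": f,
                                  "best": nxt == tab.loc[cl].idxmax()})
    return SweepResult(table=pd.DataFrame(rows), labels=labels,
                       crossover=pd.DataFrame(xover))


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact enumeration for tie-free small groups."""
    if len(x) <= 10 and len(y) <= 10:
        vals = np.concatenate([x, y])
        if len(np.unique(vals)) == len(vals):
            return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                            method="exact").pvalue)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic",
                                    use_continuity=False).pvalue)


def find_markers(
    norm_matrix,
    labels,
    t: MarkerThresholds = MarkerThresholds(),
    gene_names=None,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers per cluster.

    Genes enter the test when detected in at least ``min_pct`` of either
    group and when the average log fold change (difference of means of
    the log-normalized values) is at least ``min_avg_lfc`` in magnitude;
    Bonferroni correction is over the genes tested within each cluster,
    and only genes with adjusted p ≤ ``max_adj_p`` are reported.
    """
    X = norm_matrix.toarray() if sp.issparse(norm_matrix) else np.asarray(
        norm_matrix, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if gene_names is None:
        gene_names = np.array([f"g{i}" for i in range(X.shape[1])])
    gene_names = np.asarray(gene_names)

    out = []
    for cl in uniq:
        in_mask = labels == cl
        n_in = int(in_mask.sum())
        if n_in < 3:
            warnings.warn(f"cluster {cl!r} has {n_in} cells; skipped",
                          stacklevel=2)
            continue
        A, B = X[in_mask], X[~in_mask]
        pct_in = (A > 0).mean(axis=0)
        pct_out = (B > 0).mean(axis=0)
        lfc = A.mean(axis=0) - B.mean(axis=0)
        tested = np.flatnonzero(
            ((pct_in >= t.min_pct) | (pct_out >= t.min_pct))
            & (np.abs(lfc) >= t.min_avg_lfc))
        if len(tested) == 0:
            continue
        if n_in <= 10 and len(B) <= 10:
            p = np.array([_rank_sum_p(A[:, j], B[:, j]) for j in tested])
        else:
            p = stats.mannwhitneyu(A[:, tested], B[:, tested], axis=0,
                                   alternative="two-sided",
                                   method="asymptotic",
                                   use_continuity=False).pvalue
        adj = np.minimum(p * len(tested), 1.0)
        keep = adj <= t.max_adj_p
        for j, pj, aj in zip(tested[keep], p[keep], adj[keep]):
            out.append({"cluster": cl, "gene": gene_names[j],
                        "avg_lfc": float(lfc[j]),
                        "pct_in": float(pct_in[j]),
                        "pct_out": float(pct_out[j]),
                        "p": float(pj), "adj_p": float(aj)})
    df = pd.DataFrame(out, columns=["cluster", "gene", "avg_lfc", "pct_in",
                                    "pct_out", "p", "adj_p"])
    if len(df):
        df = df.sort_values(["cluster", "adj_p", "p", "gene"],
                            ascending=[True, True, True, True],
                            ignore_index=True)
    return df
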