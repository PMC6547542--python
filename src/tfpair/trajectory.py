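"""Simplified single-cell stage: clustering, markers, MST pseudotime.

All downstream decisions (clustering, the centroid tree, pseudotime) operate
in PCA space so that runs are deterministic and checkable against planted
truth; any nonlinear embedding is for display only. Pseudotime is the distance
along a minimum spanning tree over cluster centroids from the root centroid to
each cell's projection onto its nearest tree edge, and branch points are tree
nodes of degree >= 3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CellMatrix",
    "TrajectoryResult",
    "GenotypeComparison",
    "preprocess_cells",
    "reduce_and_cluster",
    "find_markers",
    "pseudotime_order",
    "compare_genotypes",
]


@dataclass
class CellMatrix:
    """Cells x genes matrix with per-cell metadata.

    ``values`` holds raw counts (non-negative) or, after preprocessing,
    depth-normalized log1p expression (``log_transformed`` set).
    """

    values: pd.DataFrame
    meta: pd.DataFrame  # index: cell ids; must carry a 'genotype' column
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same cell index")
        if "genotype" not in self.meta.columns:
            raise ValueError("meta requires a 'genotype' column")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def cell_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def total_counts(self) -> pd.Series:
        return self.values.sum(axis=1)

    def to_tsv(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="cell_id")
        self.meta.to_csv(meta_path, sep="\t", index_label="cell_id")

    @classmethod
    def from_tsv(cls, values_path, meta_path, **kwargs) -> "CellMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="cell_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
        return cls(values, meta.loc[values.index], **kwargs)

    def to_mtx(self, mtx_path, cells_path, genes_path) -> None:
        """MatrixMarket triplet plus cell-id and gene-id files."""
        from scipy import io as sio
        from scipy import sparse

        sio.mmwrite(str(mtx_path), sparse.csr_matrix(self.values.to_numpy()))
        pd.Series(self.cell_ids).to_csv(cells_path, sep="\t", index=False, header=["cell_id"])
        pd.Series(self.gene_ids).to_csv(genes_path, sep="\t", index=False, header=["gene_id"])


def preprocess_cells(
    matrix: CellMatrix,
    min_counts: float = 0,
    min_genes: int = 0,
    target_sum: Optional[float] = None,
) -> CellMatrix:
    """Filter poor cells, depth-normalize, log1p-transform.

    Cells with total counts below ``min_counts`` or fewer than ``min_genes``
    detected genes are dropped; the rest are scaled to a common per-cell total
    (median of kept totals unless ``target_sum`` is given) and log(1 + x)
    transformed.
    """
    if min_counts < 0 or min_genes < 0:
        raise ValueError("thresholds must be >= 0")
    totals = matrix.total_counts
    detected = (matrix.values > 0).sum(axis=1)
    keep = (totals >= min_counts) & (detected >= min_genes) & (totals > 0)
    if not keep.any():
        raise ValueError("all cells removed by filtering")
    values = matrix.values.loc[keep]
    totals = totals.loc[keep]
    if target_sum is None:
        target_sum = float(np.median(totals))
    scaled = values.div(totals, axis=0) * target_sum
    logged = np.log1p(scaled)
    return CellMatrix(logged, matrix.meta.loc[keep].copy(), log_transformed=True)


def reduce_and_cluster(
    matrix: CellMatrix, k: int, d: int = 10, seed: int = 0
) -> Tuple[pd.DataFrame, pd.Series]:
    """Top-d principal components and a k-means partition in that space.

    Deterministic for a fixed seed (full SVD, k-means++ with 10 restarts).
    Returns (coordinates cells x d, cluster labels 0..k-1).
    """
    n_cells, n_genes = matrix.values.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({n_cells})")
    if d < 2:
        raise ValueError("d must be >= 2")
    d = min(d, n_cells, n_genes)
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(matrix.values.to_numpy(dtype=float))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    coord_df = pd.DataFrame(
        coords, index=matrix.values.index, columns=[f"PC{i + 1}" for i in range(d)]
    )
    return coord_df, pd.Series(labels, index=matrix.values.index, name="cluster")


def find_markers(
    matrix: CellMatrix,
    labels: pd.Series,
    pseudocount: float = 1.0,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Cluster-vs-rest marker genes.

    Per cluster, genes are ranked by log2 fold change of mean (de-logged)
    expression in the cluster vs all other cells, with a two-sided Wilcoxon
    rank-sum p on the (log) values and a BH q within the cluster. Ties in fold
    change break by gene id. Clusters with fewer than ``min_cells`` cells are
    excluded with a warning.
    """
    labels = labels.loc[matrix.values.index]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("find_markers requires >= 2 clusters")
    linear = np.expm1(matrix.values) if matrix.log_transformed else matrix.values
    frames = []
    for cl in clusters:
        in_mask = (labels == cl).to_numpy()
        if in_mask.sum() < min_cells:
            warnings.warn(f"cluster {cl!r} has < {min_cells} cells; excluded from markers")
            continue
        mean_in = linear.loc[in_mask].mean(axis=0)
        mean_out = linear.loc[~in_mask].mean(axis=0)
        log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
        vin = matrix.values.loc[in_mask].to_numpy()
        vout = matrix.values.loc[~in_mask].to_numpy()
        pvals = stats.ranksums(vin, vout, axis=0).pvalue
        sub = pd.DataFrame(
            {
                "cluster": cl,
                "gene": matrix.gene_ids,
                "log2fc": log2fc.to_numpy(),
                "p": pvals,
            }
        )
        sub["q"] = multipletests(sub["p"].to_numpy(), method="fdr_bh")[1]
        sub = sub.sort_values(["log2fc", "gene"], ascending=[False, True], kind="mergesort")
        sub["rank"] = np.arange(1, len(sub) + 1)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


@dataclass
class TrajectoryResult:
    """Reduced coordinates, clusters, centroid tree and pseudotime."""

    coordinates: pd.DataFrame
    labels: pd.Series
    centroids: pd.DataFrame  # index: cluster ids; columns as coordinates
    edges: List[Tuple[int, int, float]]  # (cluster u, cluster v, length)
    root_cluster: int
    pseudotime: pd.Series
    branch_points: int

    def to_json(self, path) -> None:
        payload = {
            "root_cluster": int(self.root_cluster),
            "branch_points": int(self.branch_points),
            "edges": [[int(u), int(v), float(w)] for u, v, w in self.edges],
            "clusters": [int(c) for c in self.centroids.index],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def per_cell_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels, "pseudotime": self.pseudotime},
            index=self.coordinates.index,
        )


def _project_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Clamped projection of each point onto segment ab: (t in [0,1], dist)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        t = np.zeros(len(points))
    else:
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    dist = np.linalg.norm(points - proj, axis=1)
    return t, dist


def pseudotime_order(
    coordinates: pd.DataFrame, labels: pd.Series, root_cluster: int
) -> TrajectoryResult:
    """MST-over-centroids pseudotime.

    A minimum spanning tree connects the cluster centroids in reduced space;
    each cell is projected onto its nearest tree edge and its pseudotime is the
    tree distance from the root centroid to that projection. Branch points are
    centroid nodes of tree degree >= 3.
    """
    labels = labels.loc[coordinates.index]
    clusters = sorted(labels.unique())
    if root_cluster not in clusters:
        raise ValueError(f"unknown root cluster {root_cluster!r}; clusters: {clusters}")
    X = coordinates.to_numpy(dtype=float)
    centroids = np.vstack([X[(labels == c).to_numpy()].mean(axis=0) for c in clusters])
    centroid_df = pd.DataFrame(
        centroids, index=pd.Index(clusters, name="cluster"), columns=coordinates.columns
    )

    if len(clusters) == 1:
        return TrajectoryResult(
            coordinates=coordinates,
            labels=labels,
            centroids=centroid_df,
            edges=[],
            root_cluster=root_cluster,
            pseudotime=pd.Series(0.0, index=coordinates.index, name="pseudotime"),
            branch_points=0,
        )

    diff = centroids[:, None, :] - centroids[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=-1))
    mst = minimum_spanning_tree(dmat).toarray()
    tree = nx.Graph()
    tree.add_nodes_from(clusters)
    edges: List[Tuple[int, int, float]] = []
    for i, j in zip(*np.nonzero(mst)):
        u, v = clusters[i], clusters[j]
        w = float(dmat[i, j])
        tree.add_edge(u, v, weight=w)
        edges.append((u, v, w))
    d_root = nx.single_source_dijkstra_path_length(tree, root_cluster, weight="weight")

    idx = {c: i for i, c in enumerate(clusters)}
    best_dist = np.full(len(X), np.inf)
    best_time = np.zeros(len(X))
    for u, v, w in edges:
        a, b = centroids[idx[u]], centroids[idx[v]]
        t, dist = _project_to_segment(X, a, b)
        time_uv = np.minimum(d_root[u] + t * w, d_root[v] + (1.0 - t) * w)
        better = dist < best_dist
        best_dist[better] = dist[better]
        best_time[better] = time_uv[better]

    branch_points = sum(1 for _c in tree.nodes if tree.degree[_c] >= 3)
    return TrajectoryResult(
        coordinates=coordinates,
        labels=labels,
        centroids=centroid_df,
        edges=sorted(edges),
        root_cluster=root_cluster,
        pseudotime=pd.Series(best_time, index=coordinates.index, name="pseudotime"),
        branch_points=branch_points,
    )


@dataclass
class GenotypeComparison:
    """Cluster-composition and branching differences between two genotypes."""

    cluster_count_diff: int  # clusters(B) - clusters(A)
    a_only_clusters: List[int]
    b_only_clusters: List[int]
    matched_pairs: List[Tuple[int, int, float]]  # (cluster A, cluster B, profile r)
    branch_points: Dict[str, int]
    differential: Dict[Tuple[int, int], pd.DataFrame]

    def to_json(self, path) -> None:
        payload = {
            "cluster_count_diff": self.cluster_count_diff,
            "a_only_clusters": [int(c) for c in self.a_only_clusters],
            "b_only_clusters": [int(c) for c in self.b_only_clusters],
            "matched_pairs": [
                [int(a), int(b), float(r)] for a, b, r in self.matched_pairs
            ],
            "branch_points": self.branch_points,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _cluster_profiles(matrix: CellMatrix, labels: pd.Series) -> pd.DataFrame:
    labels = labels.loc[matrix.values.index]
    return matrix.values.groupby(labels).mean()


def compare_genotypes(
    result_a: TrajectoryResult,
    matrix_a: CellMatrix,
    result_b: TrajectoryResult,
    matrix_b: CellMatrix,
    match_cutoff: float = 0.9,
    pseudocount: float = 1.0,
) -> GenotypeComparison:
    """Compare two genotypes' cluster structure and branching.

    Clusters are matched across genotypes by Pearson correlation of their mean
    log-expression profiles: a cluster is genotype-specific when its best
    correlation against every cluster of the other genotype falls below
    ``match_cutoff``. For each matched pair, per-gene differential expression
    between the genotypes' member cells is reported (log2 fold change with
    pseudocount, two-sided rank-sum p, BH q).
    """
    if list(matrix_a.gene_ids) != list(matrix_b.gene_ids):
        raise ValueError("gene universes differ between the two genotypes")
    prof_a = _cluster_profiles(matrix_a, result_a.labels)
    prof_b = _cluster_profiles(matrix_b, result_b.labels)
    corr = np.corrcoef(prof_a.to_numpy(), prof_b.to_numpy())[: len(prof_a), len(prof_a):]
    corr_df = pd.DataFrame(corr, index=prof_a.index, columns=prof_b.index)

    a_only = [int(c) for c in corr_df.index if corr_df.loc[c].max() < match_cutoff]
    b_only = [int(c) for c in corr_df.columns if corr_df[c].max() < match_cutoff]
    matched: List[Tuple[int, int, float]] = []
    for cb in corr_df.columns:
        if int(cb) in b_only:
            continue
        ca = corr_df[cb].idxmax()
        matched.append((int(ca), int(cb), float(corr_df.loc[ca, cb])))

    lin_a = np.expm1(matrix_a.values) if matrix_a.log_transformed else matrix_a.values
    lin_b = np.expm1(matrix_b.values) if matrix_b.log_transformed else matrix_b.values
    differential: Dict[Tuple[int, int], pd.DataFrame] = {}
    for ca, cb, _r in matched:
        cells_a = result_a.labels.index[result_a.labels == ca]
        cells_b = result_b.labels.index[result_b.labels == cb]
        mean_a = lin_a.loc[cells_a].mean(axis=0)
        mean_b = lin_b.loc[cells_b].mean(axis=0)
        log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
        pvals = stats.ranksums(
            matrix_b.values.loc[cells_b].to_numpy(),
            matrix_a.values.loc[cells_a].to_numpy(),
            axis=0,
        ).pvalue
        table = pd.DataFrame(
            {"gene": matrix_a.gene_ids, "log2fc": log2fc.to_numpy(), "p": pvals}
        )
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["log2fc", "gene"], kind="mergesort").reset_index(drop=True)
        differential[(ca, cb)] = table

    return GenotypeComparison(
        cluster_count_diff=len(prof_b) - len(prof_a),
        a_only_clusters=sorted(a_only),
        b_only_clusters=sorted(b_only),
        matched_pairs=sorted(matched),
        branch_points={"A": result_a.branch_points, "B": result_b.branch_points},
        differential=differential,
    )
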