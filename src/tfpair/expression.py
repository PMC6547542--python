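"""Bulk-expression comparison of two mutant genotypes against wild type.

Covers differential-gene selection by a fold-change rule, row Z-scoring,
hierarchical "covariance" clustering of expression patterns, the 8-way
directional grouping of mutant-vs-WT changes, promoter-proximity target
assignment of ChIP peaks to genes, and Venn overlaps of gene sets.

The 8-group directional map (mutant A changes on the first axis, mutant B on
the second) is a fixed convention:

    1 both up | 2 A up only | 3 B up only | 4 A up, B down
    5 A down, B up | 6 B down only | 7 A down only | 8 both down

so that Groups 1/8 are the shared up-/down-regulated genes and Groups 4/5 the
completely reciprocal changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .intervals import GenomeAnnotation, PeakSet

__all__ = [
    "ExpressionMatrix",
    "GroupAssignment",
    "GROUP_DIRECTIONS",
    "select_differential",
    "row_zscore",
    "cluster_covariant",
    "assign_direction_groups",
    "map_peaks_to_genes",
    "overlap_targets",
]

# (direction in mutant A, direction in mutant B) -> group index
GROUP_DIRECTIONS: Dict[Tuple[str, str], int] = {
    ("up", "up"): 1,
    ("up", "unchanged"): 2,
    ("unchanged", "up"): 3,
    ("up", "down"): 4,
    ("down", "up"): 5,
    ("unchanged", "down"): 6,
    ("down", "unchanged"): 7,
    ("down", "down"): 8,
}


@dataclass
class ExpressionMatrix:
    """Genes x (stage, genotype, replicate) expression values, linear scale."""

    data: pd.DataFrame  # MultiIndex columns (stage, genotype, replicate)
    log_state: bool = False

    def __post_init__(self) -> None:
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 3:
            raise ValueError("columns must be a (stage, genotype, replicate) MultiIndex")
        if cols.duplicated().any():
            raise ValueError("duplicate (stage, genotype, replicate) columns")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if not self.log_state and (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("linear-scale expression must be non-negative")
        self.data.columns = self.data.columns.set_names(["stage", "genotype", "replicate"])

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def stages(self) -> List[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("stage")))

    @property
    def genotypes(self) -> List[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("genotype")))

    def mean_expression(self, stage: str, genotype: str) -> pd.Series:
        """Replicate-mean expression for one (stage, genotype)."""
        sub = self.data.loc[:, (stage, genotype)]
        if isinstance(sub, pd.Series):
            return sub
        return sub.mean(axis=1)

    def to_tsv(self, path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{s}_{g}_{r}" for s, g, r in self.data.columns]
        flat.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        flat = pd.read_csv(path, sep="\t", index_col="gene_id")
        tuples = []
        for col in flat.columns:
            parts = col.split("_")
            if len(parts) != 3:
                raise ValueError(
                    f"column {col!r} must encode stage_genotype_replicate"
                )
            tuples.append(tuple(parts))
        flat.columns = pd.MultiIndex.from_tuples(
            tuples, names=["stage", "genotype", "replicate"]
        )
        return cls(flat)


def _require_genotypes(expr: ExpressionMatrix, genotypes: Iterable[str]) -> None:
    have = set(expr.genotypes)
    missing = [g for g in genotypes if g not in have]
    if missing:
        raise ValueError(f"genotype column(s) missing from expression matrix: {missing}")


def select_differential(
    expr: ExpressionMatrix,
    wt: str = "WT",
    mutants: Optional[Sequence[str]] = None,
    fold_threshold: float = 2.0,
    min_expr: float = 1.0,
) -> List[str]:
    """Genes >= fold_threshold changed between WT and any mutant at any stage.

    Replicate means are floored at ``min_expr`` before forming ratios, which
    guards fold changes between near-zero values. The threshold is inclusive.
    Returns gene ids in matrix order.
    """
    if mutants is None:
        mutants = [g for g in expr.genotypes if g != wt]
    _require_genotypes(expr, [wt, *mutants])
    hit = pd.Series(False, index=expr.data.index)
    for stage in expr.stages:
        wt_mean = expr.mean_expression(stage, wt).clip(lower=min_expr)
        for mut in mutants:
            mut_mean = expr.mean_expression(stage, mut).clip(lower=min_expr)
            ratio = mut_mean / wt_mean
            hit |= (ratio >= fold_threshold) | (1.0 / ratio >= fold_threshold)
    return list(expr.data.index[hit])


def row_zscore(df: pd.DataFrame) -> pd.DataFrame:
    """Centre and scale each row to population SD 1; constant rows map to 0."""
    if df.shape[1] < 2:
        raise ValueError("row_zscore requires >= 2 columns")
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def cluster_covariant(
    z: pd.DataFrame, k: int
) -> Tuple[pd.Series, pd.DataFrame]:
    """Agglomerative clustering of expression patterns into exactly K clusters.

    Distance is correlation distance (1 - Pearson r between row profiles; rows
    with zero variance are assigned distance 1 to everything), linkage is
    average. Returns (gene -> cluster id in 1..K, per-cluster mean Z profile).
    """
    n = z.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must satisfy 1 <= k <= n_genes, got k={k}, n={n}")
    if n == 1:
        labels = pd.Series([1], index=z.index, name="cluster")
    else:
        values = z.to_numpy(dtype=float)
        centered = values - values.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        unit = centered / safe[:, None]
        corr = unit @ unit.T
        corr[norms == 0, :] = 0.0
        corr[:, norms == 0] = 0.0
        np.fill_diagonal(corr, 1.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        link = linkage(squareform(dist, checks=False), method="average")
        labels = pd.Series(
            fcluster(link, t=k, criterion="maxclust"), index=z.index, name="cluster"
        )
    profiles = z.groupby(labels).mean()
    profiles.index.name = "cluster"
    return labels, profiles


@dataclass
class GroupAssignment:
    """Directional group labels for one cell type (stage).

    ``table`` columns: group (1..8, or 0 meaning unchanged), dir_a, dir_b,
    fold_a, fold_b where fold is the mutant/WT pseudofloored ratio.
    """

    table: pd.DataFrame
    cell_type: str
    mutant_a: str
    mutant_b: str
    fold_threshold: float

    def genes_in_group(self, group: int) -> List[str]:
        return list(self.table.index[self.table["group"] == group])

    @property
    def counts(self) -> Dict[int, int]:
        vc = self.table["group"].value_counts()
        return {g: int(vc.get(g, 0)) for g in range(9)}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def _direction(ratio: pd.Series, fold_threshold: float) -> np.ndarray:
    return np.where(
        ratio >= fold_threshold, "up", np.where(1.0 / ratio >= fold_threshold, "down", "unchanged")
    )


def assign_direction_groups(
    expr: ExpressionMatrix,
    cell_type: str,
    wt: str = "WT",
    mutant_a: str = "mutA",
    mutant_b: str = "mutB",
    fold_threshold: float = 2.0,
    min_expr: float = 1.0,
) -> GroupAssignment:
    """Map every >= fold-changed gene to one of the 8 directional groups.

    A gene is grouped iff it changes at least ``fold_threshold`` (inclusive)
    vs WT in at least one mutant at this cell type; genes unchanged in both
    mutants receive group 0. The group index follows ``GROUP_DIRECTIONS``.
    """
    if cell_type not in expr.stages:
        raise ValueError(f"unknown cell type {cell_type!r}; stages: {expr.stages}")
    _require_genotypes(expr, [wt, mutant_a, mutant_b])
    wt_mean = expr.mean_expression(cell_type, wt).clip(lower=min_expr)
    fold_a = expr.mean_expression(cell_type, mutant_a).clip(lower=min_expr) / wt_mean
    fold_b = expr.mean_expression(cell_type, mutant_b).clip(lower=min_expr) / wt_mean
    dir_a = _direction(fold_a, fold_threshold)
    dir_b = _direction(fold_b, fold_threshold)
    group = np.array(
        [GROUP_DIRECTIONS.get((da, db), 0) for da, db in zip(dir_a, dir_b)], dtype=int
    )
    table = pd.DataFrame(
        {"group": group, "dir_a": dir_a, "dir_b": dir_b, "fold_a": fold_a, "fold_b": fold_b},
        index=expr.data.index,
    )
    return GroupAssignment(
        table, cell_type=cell_type, mutant_a=mutant_a, mutant_b=mutant_b,
        fold_threshold=fold_threshold,
    )


def map_peaks_to_genes(
    peaks: PeakSet, annotation: GenomeAnnotation, max_distance: Optional[int] = None
) -> Dict[str, List[str]]:
    """Assign peaks to genes by TSS proximity.

    A gene is a target iff at least one peak overlaps its TSS or lies within
    ``max_distance`` base pairs of it (default: the annotation's promoter
    window). A peak may serve several genes. Returns gene -> sorted peak ids,
    genes with no peak omitted.
    """
    if max_distance is None:
        max_distance = annotation.promoter_window
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    by_chrom: Dict[str, List] = {}
    for iv in peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    targets: Dict[str, List[str]] = {}
    for rec in annotation.tss.itertuples(index=False):
        hits = []
        for iv in by_chrom.get(rec.chrom, []):
            if iv.start <= rec.pos < iv.end:
                gap = 0
            elif rec.pos < iv.start:
                gap = iv.start - rec.pos
            else:
                gap = rec.pos - (iv.end - 1)
            if gap <= max_distance:
                hits.append(iv.id)
        if hits:
            targets[rec.gene_id] = sorted(hits)
    return targets


def overlap_targets(sets: Mapping[str, Iterable[str]]) -> Dict[str, int]:
    """Exclusive-region counts of a 2- or 3-set Venn partition.

    Keys name the sets whose exclusive region is counted, joined by '&'
    (e.g. 'A', 'A&B', 'A&B&C'); values sum to the size of the union.
    """
    names = list(sets.keys())
    if not (2 <= len(names) <= 3):
        raise ValueError("overlap_targets supports 2 or 3 sets")
    as_sets = {name: set(v) for name, v in sets.items()}
    counts: Dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(as_sets[n] for n in combo))
            outside = set.union(set(), *(as_sets[n] for n in names if n not in combo))
            counts["&".join(combo)] = len(inside - outside)
    return counts
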