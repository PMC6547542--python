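"""Comparative factor occupancy on a shared peak universe.

Tag counts for two ChIP'd factors (and for chromatin accessibility) are
compared after per-sample depth normalization. The central operations are the
shared/specific peak classifier — a peak is factor-specific when its
pseudocounted, normalized fold difference between the two ChIPs is at least
``fold_threshold`` (the boundary value itself counts as specific) — and the
de-novo acquisition/loss detector that contrasts the second factor's signal
between wild-type and a mutant genotype at the first factor's specific sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "TagCountTable",
    "PeakClassification",
    "DeNovoResult",
    "normalize_tags",
    "correlation_matrix",
    "differential_sites",
    "classify_shared_specific",
    "detect_de_novo",
    "rank_matrix",
]

DEFAULT_NORM_TARGET = 1e7
DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class TagCountTable:
    """Peaks x samples non-negative signal matrix.

    ``data`` is indexed by peak id with one column per sample. ``normalized``
    records whether every column has been scaled to sum to ``norm_target``.
    """

    data: pd.DataFrame
    normalized: bool = False
    norm_target: Optional[float] = None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate peak ids in TagCountTable")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids in TagCountTable")
        values = self.data.to_numpy(dtype=float)
        if values.size and (values < 0).any():
            raise ValueError("tag counts must be non-negative")
        if self.normalized:
            if self.norm_target is None:
                raise ValueError("normalized table requires norm_target")
            sums = values.sum(axis=0)
            if not np.allclose(sums, self.norm_target, rtol=1e-6):
                raise ValueError("normalized table columns do not sum to norm_target")

    @property
    def peak_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    def column(self, sample: str) -> pd.Series:
        if sample not in self.data.columns:
            raise KeyError(f"unknown sample id {sample!r}")
        return self.data[sample]

    def mean_of(self, samples: Union[str, Sequence[str]]) -> pd.Series:
        """Replicate-averaged signal column."""
        if isinstance(samples, str):
            samples = [samples]
        for s in samples:
            if s not in self.data.columns:
                raise KeyError(f"unknown sample id {s!r}")
        return self.data[list(samples)].mean(axis=1)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="peak_id")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "TagCountTable":
        df = pd.read_csv(path, sep="\t", index_col="peak_id")
        return cls(df, **kwargs)


def normalize_tags(
    table: TagCountTable, norm_target: float = DEFAULT_NORM_TARGET
) -> TagCountTable:
    """Scale every sample column so it sums to ``norm_target``.

    The input table is left unmodified.
    """
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"cannot normalize all-zero sample(s): {list(zero.index)}")
    scaled = table.data / sums * norm_target
    return TagCountTable(scaled, normalized=True, norm_target=norm_target)


def correlation_matrix(table: TagCountTable) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation of log2(normalized count + 1)."""
    if table.data.shape[0] < 2:
        raise ValueError("correlation requires >= 2 peaks")
    work = table if table.normalized else normalize_tags(table)
    logged = np.log2(work.data.to_numpy(dtype=float) + 1.0)
    sds = logged.std(axis=0)
    flat = [s for s, sd in zip(work.sample_ids, sds) if sd == 0]
    if flat:
        raise ValueError(f"zero-variance sample(s) after log transform: {flat}")
    corr = np.corrcoef(logged, rowvar=False)
    return pd.DataFrame(corr, index=work.sample_ids, columns=work.sample_ids)


def _aligned(a: pd.Series, b: pd.Series) -> None:
    if len(a) != len(b) or not (a.index == b.index).all():
        raise ValueError("columns are not aligned to the same peak universe")


def differential_sites(
    a: pd.Series,
    b: pd.Series,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Tuple[List[str], List[str]]:
    """Sites gained (up in b) or lost (down in b) at >= ``fold_threshold``.

    The threshold is inclusive: a fold exactly equal to it qualifies.
    Returns ``(gained_ids, lost_ids)`` in peak-universe order.
    """
    _aligned(a, b)
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    ratio = (b + pseudocount) / (a + pseudocount)
    gained = list(a.index[ratio >= fold_threshold])
    lost = list(a.index[(1.0 / ratio) >= fold_threshold])
    return gained, lost


@dataclass
class PeakClassification:
    """Per-peak shared/specific labels with the fold values they rest on.

    ``table`` columns: label in {shared, tf1_specific, tf2_specific}; fold
    (>= 1, larger-over-smaller pseudocounted ratio); tf1, tf2 (the averaged,
    normalized signals used).
    """

    table: pd.DataFrame
    fold_threshold: float
    pseudocount: float

    LABELS = ("shared", "tf1_specific", "tf2_specific")

    def ids_with_label(self, label: str) -> List[str]:
        if label not in self.LABELS:
            raise KeyError(f"unknown label {label!r}")
        return list(self.table.index[self.table["label"] == label])

    @property
    def counts(self) -> Dict[str, int]:
        vc = self.table["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in self.LABELS}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="peak_id")


def classify_shared_specific(
    table: TagCountTable,
    tf1_samples: Union[str, Sequence[str]],
    tf2_samples: Union[str, Sequence[str]],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PeakClassification:
    """Partition the peak universe into shared / tf1-specific / tf2-specific.

    Replicate columns are averaged per factor; a peak is tfX-specific when the
    pseudocounted ratio favouring tfX is *equal to or more than*
    ``fold_threshold``, otherwise shared. Requires a normalized table so the
    classification cannot reflect sequencing depth.
    """
    if not table.normalized:
        raise ValueError("classify_shared_specific requires a normalized TagCountTable")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    tf1 = table.mean_of(tf1_samples)
    tf2 = table.mean_of(tf2_samples)
    r = (tf1 + pseudocount) / (tf2 + pseudocount)
    label = np.where(
        r >= fold_threshold,
        "tf1_specific",
        np.where(1.0 / r >= fold_threshold, "tf2_specific", "shared"),
    )
    fold = np.maximum(r, 1.0 / r)
    out = pd.DataFrame(
        {"label": label, "fold": fold, "tf1": tf1, "tf2": tf2}, index=table.data.index
    )
    return PeakClassification(out, fold_threshold=fold_threshold, pseudocount=pseudocount)


@dataclass
class DeNovoResult:
    """Acquired/lost/unchanged labels for the second factor at specific sites."""

    table: pd.DataFrame  # columns: label, fold (mutant/WT pseudocounted ratio)
    fold_threshold: float
    pseudocount: float

    LABELS = ("acquired", "lost", "unchanged")

    def ids_with_label(self, label: str) -> List[str]:
        if label not in self.LABELS:
            raise KeyError(f"unknown label {label!r}")
        return list(self.table.index[self.table["label"] == label])

    @property
    def counts(self) -> Dict[str, int]:
        vc = self.table["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in self.LABELS}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="peak_id")


def detect_de_novo(
    table: TagCountTable,
    specific_ids: Iterable[str],
    wt_samples: Union[str, Sequence[str]],
    mut_samples: Union[str, Sequence[str]],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DeNovoResult:
    """Detect de-novo acquisition/loss of the second factor in a mutant.

    Restricted to ``specific_ids`` (the first factor's specific peaks):
    acquired when mutant/WT >= threshold, lost when WT/mutant >= threshold
    (both inclusive), otherwise unchanged.
    """
    if not table.normalized:
        raise ValueError("detect_de_novo requires a normalized TagCountTable")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    ids = list(specific_ids)
    missing = set(ids) - set(table.data.index)
    if missing:
        raise KeyError(f"specific ids outside the peak universe: {sorted(missing)[:5]}")
    wt = table.mean_of(wt_samples).loc[ids]
    mut = table.mean_of(mut_samples).loc[ids]
    fold = (mut + pseudocount) / (wt + pseudocount)
    label = np.where(
        fold >= fold_threshold,
        "acquired",
        np.where(1.0 / fold >= fold_threshold, "lost", "unchanged"),
    )
    out = pd.DataFrame({"label": label, "fold": fold}, index=pd.Index(ids, name="peak_id"))
    return DeNovoResult(out, fold_threshold=fold_threshold, pseudocount=pseudocount)


def rank_matrix(
    table: TagCountTable, rank_by: str, descending: bool = True
) -> TagCountTable:
    """Reorder peaks by one sample's signal (ties broken by peak id).

    All other columns are carried along; the result is ready for heat-map
    export.
    """
    if rank_by not in table.data.columns:
        raise KeyError(f"unknown sample id {rank_by!r}")
    order = (
        table.data[[rank_by]]
        .assign(_id=table.data.index.astype(str))
        .sort_values([rank_by, "_id"], ascending=[not descending, True], kind="mergesort")
        .index
    )
    return TagCountTable(
        table.data.loc[order], normalized=table.normalized, norm_target=table.norm_target
    )
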