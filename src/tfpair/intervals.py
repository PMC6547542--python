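"""Genomic interval plumbing.

All coordinates are 0-based, half-open ``[start, end)`` — the native BED
convention — so file round-trips never shift positions. Overlap queries are
backed by interval trees; the quadratic brute-force equivalents live in the
test suite as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GenomeAnnotation",
    "read_bed",
    "write_bed",
    "overlap_pairs",
    "filter_high_confidence",
    "annotate_location",
    "merge_union",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    id: str
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.id!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """An ordered collection of intervals with unique ids."""

    intervals: List[GenomicInterval] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [iv.id for iv in self.intervals]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate interval ids in PeakSet {self.label!r}: {sorted(dups)[:5]}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def ids(self) -> List[str]:
        return [iv.id for iv in self.intervals]

    def by_id(self) -> Dict[str, GenomicInterval]:
        return {iv.id: iv for iv in self.intervals}

    def subset(self, keep_ids: Iterable[str], label: Optional[str] = None) -> "PeakSet":
        """Subset by id, preserving the original interval order."""
        keep = set(keep_ids)
        missing = keep - set(self.ids)
        if missing:
            raise KeyError(f"ids not in PeakSet {self.label!r}: {sorted(missing)[:5]}")
        return PeakSet(
            [iv for iv in self.intervals if iv.id in keep],
            label if label is not None else self.label,
        )


@dataclass
class GenomeAnnotation:
    """TSS records plus the promoter-window convention.

    ``promoter_window`` is applied symmetrically around each TSS regardless of
    strand: a peak is promoter-proximal iff it overlaps
    ``[tss - window, tss + window)`` for any gene.
    """

    tss: pd.DataFrame  # columns: gene_id, chrom, pos, strand
    promoter_window: int = 1000

    REQUIRED_COLUMNS = ("gene_id", "chrom", "pos", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.tss.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        if self.tss["gene_id"].duplicated().any():
            dups = self.tss.loc[self.tss["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in annotation: {dups[:5]}")
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be > 0")

    def __len__(self) -> int:
        return len(self.tss)

    @property
    def gene_ids(self) -> List[str]:
        return self.tss["gene_id"].tolist()

    def promoter_intervals(self) -> List[Tuple[str, int, int, str]]:
        """(chrom, win_start, win_end, gene_id) windows, clipped at 0."""
        w = self.promoter_window
        out = []
        for rec in self.tss.itertuples(index=False):
            out.append((rec.chrom, max(0, rec.pos - w), rec.pos + w, rec.gene_id))
        return out

    def to_tsv(self, path) -> None:
        self.tss.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, promoter_window: int = 1000) -> "GenomeAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        return cls(df, promoter_window=promoter_window)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def _format_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    return format(score, "g")


def read_bed(path, label: str = "") -> PeakSet:
    """Read a 3- to 6-column BED file.

    3-column records receive auto-assigned ids ``peak_1``, ``peak_2``, ...;
    missing score/strand fields default to ``None``/``'.'``.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"peak_{len(intervals) + 1}"
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: bad score {fields[4]!r}") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(intervals, label=label or str(path))


def write_bed(peaks: PeakSet, path) -> None:
    """Write a 6-column BED file (score '.' when unset)."""
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{_format_score(iv.score)}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Overlap logic
# ---------------------------------------------------------------------------

def _build_trees(peaks: PeakSet) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap_pairs(
    a: PeakSet, b: PeakSet, min_overlap: int = 1
) -> List[Tuple[str, str]]:
    """All (id_a, id_b) pairs whose intersection length >= ``min_overlap``.

    Output sorted by (id_a, id_b).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = _build_trees(b)
    pairs: List[Tuple[str, str]] = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                pairs.append((iv.id, hit.data.id))
    pairs.sort()
    return pairs


def filter_high_confidence(
    chip: PeakSet, atac: PeakSet, min_overlap: int = 1
) -> PeakSet:
    """Keep the ChIP peaks supported by >= 1 accessible-chromatin interval.

    The returned subset preserves the input order.
    """
    hit_ids = {ia for ia, _ in overlap_pairs(chip, atac, min_overlap=min_overlap)}
    return PeakSet(
        [iv for iv in chip if iv.id in hit_ids],
        label=f"{chip.label}|high_confidence",
    )


def annotate_location(
    peaks: PeakSet, annotation: GenomeAnnotation
) -> Dict[str, str]:
    """Label every peak 'promoter' or 'distal'.

    A peak is a promoter peak iff it overlaps the symmetric window
    ``[tss - w, tss + w)`` of any gene; otherwise distal.
    """
    trees: Dict[str, IntervalTree] = {}
    for chrom, ws, we, _gene in annotation.promoter_intervals():
        if we > ws:
            trees.setdefault(chrom, IntervalTree()).addi(ws, we)
    labels: Dict[str, str] = {}
    for iv in peaks:
        tree = trees.get(iv.chrom)
        hit = bool(tree is not None and tree.overlap(iv.start, iv.end))
        labels[iv.id] = "promoter" if hit else "distal"
    return labels


def merge_union(sets: Sequence[PeakSet], label: str = "union") -> PeakSet:
    """Union of all intervals, merging overlapping or bookended (gap 0) runs.

    Result is sorted by (chrom, start); merged intervals receive fresh ids
    ``merged_1``, ``merged_2``, ... in output order.
    """
    if not sets:
        raise ValueError("merge_union requires at least one PeakSet")
    all_ivs = sorted(
        (iv for ps in sets for iv in ps), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    merged: List[Tuple[str, int, int]] = []
    for iv in all_ivs:
        if merged and merged[-1][0] == iv.chrom and iv.start <= merged[-1][2]:
            chrom, s, e = merged[-1]
            merged[-1] = (chrom, s, max(e, iv.end))
        else:
            merged.append((iv.chrom, iv.start, iv.end))
    return PeakSet(
        [
            GenomicInterval(chrom, s, e, f"merged_{i + 1}")
            for i, (chrom, s, e) in enumerate(merged)
        ],
        label=label,
    )
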