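"""PWM scanning and motif-content summaries for peak sequences.

A position weight matrix is scored as log2 odds against a background base
composition; a window is a hit when its score meets the matrix's threshold
(default: 80% of the maximum achievable score). Per-peak multiplicities count
non-overlapping hits selected greedily left to right, which mirrors how
"number of motifs per peak" bar charts are usually produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PositionWeightMatrix",
    "MotifCountTable",
    "scan_pwm",
    "count_motifs_per_peak",
    "motif_count_distribution",
    "motif_enrichment",
    "gc_box_pwm",
    "read_pwms_tabular",
    "write_pwms_tabular",
    "read_jaspar",
    "read_fasta",
    "write_fasta",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_THRESHOLD_FRACTION = 0.8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """Base-probability matrix (rows = positions, columns = A, C, G, T)."""

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: Optional[float] = None  # log2-odds bits; None -> 80% of max

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM {self.name!r}: probs must be L x 4")
        if self.probs.shape[0] < 4:
            raise ValueError(f"PWM {self.name!r}: length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def threshold(self) -> float:
        if self.score_threshold is not None:
            return float(self.score_threshold)
        return DEFAULT_THRESHOLD_FRACTION * self.max_score

    @classmethod
    def from_counts(
        cls, name: str, counts: np.ndarray, pseudocount: float = 0.5, **kwargs
    ) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, counts / counts.sum(axis=1, keepdims=True), **kwargs)


def gc_box_pwm(
    name: str = "GCbox", sharpness: float = 0.97, score_threshold: Optional[float] = None
) -> PositionWeightMatrix:
    """A synthetic Sp-family-style GC-box matrix (consensus GGGGCGGGGC).

    Synthetic stand-in for testing and simulation; the consensus follows the
    canonical GC-box element recognised by Sp-family zinc fingers, with
    ``sharpness`` probability on the consensus base at every position.
    """
    consensus = "GGGGCGGGGC"
    off = (1.0 - sharpness) / 3.0
    probs = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus):
        probs[i, _BASE_INDEX[base]] = sharpness
    return PositionWeightMatrix(name, probs, score_threshold=score_threshold)


# ---------------------------------------------------------------------------
# PWM tabular / JASPAR I/O
# ---------------------------------------------------------------------------

def write_pwms_tabular(pwms: Sequence[PositionWeightMatrix], path) -> None:
    """Minimal tabular format: '>name' header then L rows of 4 probabilities."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.probs:
                fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


def read_pwms_tabular(path) -> List[PositionWeightMatrix]:
    pwms: List[PositionWeightMatrix] = []
    name, rows = None, []
    def flush():
        if name is not None:
            pwms.append(PositionWeightMatrix(name, np.array(rows, dtype=float)))
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].strip(), []
            else:
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: PWM row must have 4 values: {line!r}")
                rows.append(vals)
    flush()
    return pwms


def read_jaspar(path, pseudocount: float = 0.5) -> List[PositionWeightMatrix]:
    """Read JASPAR-style count matrices ('>id name' then 'A [ ... ]' rows)."""
    pwms: List[PositionWeightMatrix] = []
    name, counts = None, {}
    def flush():
        if name is not None:
            missing = [b for b in BASES if b not in counts]
            if missing:
                raise ValueError(f"JASPAR record {name!r} missing rows for {missing}")
            mat = np.array([counts[b] for b in BASES], dtype=float).T
            pwms.append(PositionWeightMatrix.from_counts(name, mat, pseudocount=pseudocount))
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, counts = line[1:].split()[0], {}
            else:
                base = line[0].upper()
                body = line[1:].replace("[", " ").replace("]", " ")
                counts[base] = [float(v) for v in body.split()]
    flush()
    return pwms


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write peak sequences keyed by id."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    from Bio.SeqIO import parse as seqio_parse

    return {rec.id: str(rec.seq) for rec in seqio_parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lookup = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lookup[ord(base)] = idx
    lookup[ord("N")] = -1
    codes = lookup[arr]
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return codes


def scan_pwm(
    sequence: str, pwm: PositionWeightMatrix
) -> List[Tuple[int, str, float]]:
    """All threshold-passing windows on both strands.

    Returns (offset, strand, score) triples with 0-based forward-strand
    offsets, ordered by offset then strand ('+' before '-'). Windows containing
    N are skipped; a sequence shorter than the motif yields no hits.
    """
    L = len(pwm)
    codes = _encode(sequence)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    lo = pwm.log_odds
    # reverse-complement scoring: reverse positions and complement bases
    # (complement(b) == 3 - b, i.e. a flip of the base axis)
    rc_lo = lo[::-1, ::-1]
    safe = np.where(windows >= 0, windows, 0)
    pos = np.arange(L)
    fwd = lo[pos, safe].sum(axis=1)
    rev = rc_lo[pos, safe].sum(axis=1)
    thr = pwm.threshold()
    hits: List[Tuple[int, str, float]] = []
    for off in np.nonzero(valid)[0]:
        if fwd[off] >= thr:
            hits.append((int(off), "+", float(fwd[off])))
        if rev[off] >= thr:
            hits.append((int(off), "-", float(rev[off])))
    return hits


@dataclass
class MotifCountTable:
    """Non-overlapping hit counts per peak per motif, with scan parameters."""

    counts: pd.DataFrame  # index: peak ids; columns: motif names; int counts
    thresholds: Dict[str, float] = field(default_factory=dict)
    strands: str = "both"

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("motif counts must be >= 0")

    @property
    def peak_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def motif_names(self) -> List[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="peak_id")


def _greedy_nonoverlapping(
    hits: List[Tuple[int, str, float]], motif_length: int
) -> int:
    """Count hits left to right, skipping any window that overlaps a kept one."""
    kept = 0
    last_end = -1
    for off, _strand, _score in sorted(hits, key=lambda h: (h[0], h[1])):
        if off >= last_end:
            kept += 1
            last_end = off + motif_length
    return kept


def count_motifs_per_peak(
    sequences: Mapping[str, str], pwms: Sequence[PositionWeightMatrix]
) -> MotifCountTable:
    """Per-peak, per-motif counts of non-overlapping threshold-passing hits."""
    names = [p.name for p in pwms]
    if len(set(names)) != len(names):
        raise ValueError("duplicate PWM names")
    peak_ids = list(sequences.keys())
    data = np.zeros((len(peak_ids), len(pwms)), dtype=int)
    for j, pwm in enumerate(pwms):
        for i, pid in enumerate(peak_ids):
            seq = sequences[pid]
            if seq is None:
                raise ValueError(f"missing sequence for peak {pid!r}")
            data[i, j] = _greedy_nonoverlapping(scan_pwm(seq, pwm), len(pwm))
    counts = pd.DataFrame(data, index=pd.Index(peak_ids, name="peak_id"), columns=names)
    return MotifCountTable(counts, thresholds={p.name: p.threshold() for p in pwms})


def motif_count_distribution(
    counts: MotifCountTable,
    classes: Mapping[str, str],
    locations: Mapping[str, str],
    cap: int = 9,
) -> pd.DataFrame:
    """Histogram of peaks by motif count, per (class, stratum, motif).

    Strata are 'all', 'promoter' and 'distal'; count bins are 0..cap-1 plus a
    final '>=cap' bin. Tidy output with columns class, stratum, motif, bin,
    n_peaks; per-(class, stratum, motif) totals equal the stratum size.
    """
    missing = [p for p in counts.peak_ids if p not in classes or p not in locations]
    if missing:
        raise ValueError(f"peaks without class or location labels: {missing[:5]}")
    bins = [str(i) for i in range(cap)] + [f">={cap}"]
    rows = []
    df = counts.counts
    cls = pd.Series({p: classes[p] for p in counts.peak_ids})
    loc = pd.Series({p: locations[p] for p in counts.peak_ids})
    for class_label in sorted(cls.unique()):
        in_class = cls.index[cls == class_label]
        for stratum in ("all", "promoter", "distal"):
            ids = in_class if stratum == "all" else [p for p in in_class if loc[p] == stratum]
            sub = df.loc[list(ids)]
            for motif in counts.motif_names:
                capped = np.minimum(sub[motif].to_numpy(), cap)
                hist = np.bincount(capped, minlength=cap + 1)
                for b, n in zip(bins, hist):
                    rows.append((class_label, stratum, motif, b, int(n)))
    return pd.DataFrame(rows, columns=["class", "stratum", "motif", "bin", "n_peaks"])


def motif_enrichment(
    counts: MotifCountTable,
    foreground_ids: Iterable[str],
    background_ids: Iterable[str],
) -> pd.DataFrame:
    """Presence/absence motif enrichment of foreground vs background peaks.

    Per motif, a 2x2 table (has >= 1 hit vs none, foreground vs background)
    gives an odds ratio (Haldane 0.5 correction when any cell is zero), a
    two-sided Fisher exact p, and a Benjamini-Hochberg q across motifs.
    """
    fg = list(foreground_ids)
    bg = list(background_ids)
    if not fg or not bg:
        raise ValueError("foreground and background must both be nonempty")
    if set(fg) & set(bg):
        raise ValueError("foreground and background must be disjoint")
    missing = (set(fg) | set(bg)) - set(counts.peak_ids)
    if missing:
        raise KeyError(f"ids missing from the count table: {sorted(missing)[:5]}")
    df = counts.counts
    rows = []
    for motif in counts.motif_names:
        fg_with = int((df.loc[fg, motif] > 0).sum())
        bg_with = int((df.loc[bg, motif] > 0).sum())
        fg_without = len(fg) - fg_with
        bg_without = len(bg) - bg_with
        table = [[fg_with, fg_without], [bg_with, bg_without]]
        _or, p = stats.fisher_exact(table, alternative="two-sided")
        cells = [fg_with, fg_without, bg_with, bg_without]
        if 0 in cells:
            a, b, c, d = (v + 0.5 for v in cells)
        else:
            a, b, c, d = cells
        odds = (a * d) / (b * c)
        rows.append((motif, odds, p, fg_with, len(fg), bg_with, len(bg)))
    out = pd.DataFrame(
        rows,
        columns=["motif", "odds_ratio", "p", "fg_with_hit", "fg_n", "bg_with_hit", "bg_n"],
    )
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
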