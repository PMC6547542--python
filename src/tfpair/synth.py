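"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the statistical structure of a
two-factor occupancy study across genotypes: a shared peak universe carrying
shared, factor-specific and background peaks; negative-binomial tag counts
with a planted specific-site fold difference and de-novo compensation in
binding-null mutants; peak sequences with promoter-heavy motif multiplicities;
a staged bulk expression matrix with planted directional groups and pattern
clusters; and single-cell matrices sampled along a branched lineage, with an
optional mutant-only extra cluster.

Every sub-generator draws from its own child stream of a single master seed
(``default_rng([seed, stream_code])``) so datasets can be regenerated module
by module. Calling any generator twice with the same config yields identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .expression import GROUP_DIRECTIONS, ExpressionMatrix
from .intervals import GenomeAnnotation, GenomicInterval, PeakSet
from .motifs import PositionWeightMatrix, reverse_complement
from .occupancy import TagCountTable
from .trajectory import CellMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_annotation",
    "generate_peak_landscape",
    "accessible_peak_set",
    "simulate_tag_counts",
    "simulate_atac_counts",
    "generate_sequences_with_motifs",
    "simulate_expression",
    "simulate_single_cells",
]

# fixed child-stream codes for the master seed
STREAMS = {
    "annotation": 1,
    "peaks": 2,
    "tags": 3,
    "atac": 4,
    "sequences": 5,
    "expression": 6,
    "cells": 7,
}

PEAK_CLASSES = ("shared", "tf1_specific", "tf2_specific", "background")
TOPOLOGIES = ("linear", "bifurcating", "multifurcating")

# group -> (direction in mutant A, direction in mutant B)
DIRECTIONS_BY_GROUP = {g: dirs for dirs, g in GROUP_DIRECTIONS.items()}

# default mix: 3% of genes in each of the 8 directional groups, 76% unchanged
DEFAULT_GROUP_PROPORTIONS = (0.03,) * 8 + (0.76,)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the study conditions."""

    seed: int = 0

    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    gene_spacing: int = 5_000
    promoter_window: int = 1_000

    # peak landscape
    n_peaks_shared: int = 1_000
    n_peaks_tf1_specific: int = 400
    n_peaks_tf2_specific: int = 400
    n_background: int = 200
    peak_width: int = 200
    accessible_background_fraction: float = 0.5

    # tag counts
    effect_fold: float = 4.0
    compensated_fraction: float = 0.3
    dispersion: float = 0.1
    mean_depth: float = 50.0
    background_depth: float = 5.0
    n_replicates_chip: int = 3
    n_replicates_atac: int = 2
    n_replicates: int = 2  # bulk expression replicates
    n_atac_gained: int = 10
    n_atac_lost: int = 10

    # condition labels; genotypes[0] is wild type
    stages: Tuple[str, ...] = ("ESC", "Flk1", "HE1", "HE2", "Prog")
    genotypes: Tuple[str, ...] = ("WT", "mutA", "mutB")
    binding_null_genotypes: Tuple[str, ...] = ("mutA", "mutB")

    # motif planting
    promoter_motif_rate: float = 3.0
    distal_motif_rate: float = 0.7

    # bulk expression
    group_proportions: Tuple[float, ...] = DEFAULT_GROUP_PROPORTIONS
    expression_fold: float = 4.0
    expression_noise_sd: float = 0.1  # log2 units per replicate

    # single cells
    n_cells_per_genotype: int = 300
    trajectory_topology: str = "bifurcating"
    extra_cluster_in_mutant: bool = True
    extra_cluster_fraction: float = 0.15
    sc_noise: float = 0.2  # gamma-Poisson overdispersion CV; 0 = exact means
    n_sc_de_genes: int = 2
    sc_de_fold: float = 4.0
    kit_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if not 0 <= self.compensated_fraction <= 1:
            raise ValueError("compensated_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.group_proportions) != 9:
            raise ValueError("group_proportions must have length 9 (8 groups + unchanged)")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1 within 1e-9")
        if any(p < 0 for p in self.group_proportions):
            raise ValueError("group_proportions must be non-negative")
        if self.trajectory_topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown trajectory topology {self.trajectory_topology!r}; "
                f"choose from {TOPOLOGIES}"
            )
        if len(self.genotypes) < 2:
            raise ValueError("need a wild type and at least one mutant genotype")

    @property
    def wild_type(self) -> str:
        return self.genotypes[0]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), STREAMS[stream]])

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "genotypes", "binding_null_genotypes", "group_proportions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted ground truth; the recovery target for every pipeline stage."""

    peak_class_truth: Dict[str, str] = field(default_factory=dict)
    peak_location: Dict[str, str] = field(default_factory=dict)  # planting intent
    accessible_ids: Set[str] = field(default_factory=set)
    compensated_ids: Set[str] = field(default_factory=set)
    atac_gained_ids: Set[str] = field(default_factory=set)
    atac_lost_ids: Set[str] = field(default_factory=set)
    motif_placements: Dict[str, List[Tuple[int, str, str]]] = field(default_factory=dict)
    gene_group_truth: Dict[str, int] = field(default_factory=dict)  # 0 = unchanged
    gene_cluster_truth: Dict[str, int] = field(default_factory=dict)
    cell_time_truth: Dict[str, float] = field(default_factory=dict)
    cell_branch_truth: Dict[str, str] = field(default_factory=dict)
    cell_cluster_truth: Dict[str, str] = field(default_factory=dict)
    sc_de_gene_ids: List[str] = field(default_factory=list)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        for name in self.__dataclass_fields__:
            mine, theirs = getattr(self, name), getattr(other, name)
            if isinstance(mine, dict):
                mine.update(theirs)
            elif isinstance(mine, set):
                mine |= theirs
            elif isinstance(mine, list):
                mine.extend(theirs)
        return self


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place TSS records on a grid with jitter; strands drawn 50/50.

    Genes are spaced ``gene_spacing`` apart (round-robin across chromosomes)
    with every promoter window guaranteed inside chromosome bounds.
    """
    rng = config.rng("annotation")
    w, spacing = config.promoter_window, config.gene_spacing
    slots_per_chrom = max(0, (config.chrom_length - 2 * w) // spacing)
    capacity = config.n_chroms * slots_per_chrom
    if config.n_genes > capacity:
        raise ValueError(
            f"cannot place {config.n_genes} genes at spacing {spacing} on "
            f"{config.n_chroms} x {config.chrom_length} bp (capacity {capacity})"
        )
    records = []
    for i in range(config.n_genes):
        chrom_idx = i % config.n_chroms
        slot = i // config.n_chroms
        jitter = int(rng.integers(0, max(1, spacing // 2)))
        pos = w + slot * spacing + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        records.append((f"gene_{i + 1:04d}", f"chr{chrom_idx + 1}", pos, strand))
    tss = pd.DataFrame(records, columns=["gene_id", "chrom", "pos", "strand"])
    return GenomeAnnotation(tss, promoter_window=w)


# ---------------------------------------------------------------------------
# Peak landscape
# ---------------------------------------------------------------------------

def generate_peak_landscape(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> Tuple[PeakSet, SyntheticTruth]:
    """Plant a non-overlapping peak universe with class and location truth.

    Each class is split half promoter / half distal. Promoter peaks occupy
    non-overlapping slots inside promoter windows; distal peaks are rejection-
    sampled outside every promoter window. The universe never self-overlaps.
    Accessibility is true for all non-background peaks plus a configured
    fraction of background peaks.
    """
    rng = config.rng("peaks")
    width = config.peak_width
    class_counts = [
        ("shared", config.n_peaks_shared),
        ("tf1_specific", config.n_peaks_tf1_specific),
        ("tf2_specific", config.n_peaks_tf2_specific),
        ("background", config.n_background),
    ]
    n_total = sum(n for _c, n in class_counts)
    if n_total == 0:
        return PeakSet([], label="universe"), SyntheticTruth()

    # non-overlapping candidate slots inside promoter windows
    promoter_slots: List[Tuple[str, int]] = []
    gap = 10
    for chrom, ws, we, _gene in annotation.promoter_intervals():
        pos = ws
        while pos + width <= we:
            promoter_slots.append((chrom, pos))
            pos += width + gap
    rng.shuffle(promoter_slots)

    window_trees: Dict[str, IntervalTree] = {}
    for chrom, ws, we, _gene in annotation.promoter_intervals():
        window_trees.setdefault(chrom, IntervalTree()).addi(ws, we)
    occupied: Dict[str, IntervalTree] = {}
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]

    placements: List[Tuple[str, int, str, str]] = []  # chrom, start, class, location
    slot_cursor = 0
    for class_label, n in class_counts:
        n_promoter = n // 2
        for j in range(n):
            want_promoter = j < n_promoter and len(annotation) > 0
            if want_promoter:
                if slot_cursor >= len(promoter_slots):
                    raise ValueError(
                        "not enough promoter-window space for the requested peak counts"
                    )
                chrom, start = promoter_slots[slot_cursor]
                slot_cursor += 1
            else:
                chrom = start = None
                for _try in range(500):
                    c = chroms[int(rng.integers(0, len(chroms)))]
                    s = int(rng.integers(0, config.chrom_length - width))
                    if c in window_trees and window_trees[c].overlap(s, s + width):
                        continue
                    if c in occupied and occupied[c].overlap(s, s + width):
                        continue
                    chrom, start = c, s
                    break
                if chrom is None:
                    raise ValueError(
                        "could not place a distal peak without overlap; "
                        "genome too small for the requested peak counts"
                    )
            occupied.setdefault(chrom, IntervalTree()).addi(start, start + width)
            placements.append(
                (chrom, start, class_label, "promoter" if want_promoter else "distal")
            )

    placements.sort(key=lambda p: (p[0], p[1]))
    truth = SyntheticTruth()
    intervals = []
    for i, (chrom, start, class_label, location) in enumerate(placements):
        pid = f"peak_{i + 1:05d}"
        intervals.append(GenomicInterval(chrom, start, start + width, pid))
        truth.peak_class_truth[pid] = class_label
        truth.peak_location[pid] = location

    non_background = [p for p, c in truth.peak_class_truth.items() if c != "background"]
    background = [p for p, c in truth.peak_class_truth.items() if c == "background"]
    n_open_bg = int(round(config.accessible_background_fraction * len(background)))
    open_bg = list(rng.choice(background, size=n_open_bg, replace=False)) if n_open_bg else []
    truth.accessible_ids = set(non_background) | set(open_bg)

    tf1_ids = sorted(p for p, c in truth.peak_class_truth.items() if c == "tf1_specific")
    n_comp = int(round(config.compensated_fraction * len(tf1_ids)))
    truth.compensated_ids = (
        set(rng.choice(tf1_ids, size=n_comp, replace=False)) if n_comp else set()
    )

    closed_bg = sorted(set(background) - set(open_bg))
    open_ids = sorted(truth.accessible_ids)
    truth.atac_gained_ids = set(
        rng.choice(closed_bg, size=min(config.n_atac_gained, len(closed_bg)), replace=False)
    ) if closed_bg and config.n_atac_gained else set()
    truth.atac_lost_ids = set(
        rng.choice(open_ids, size=min(config.n_atac_lost, len(open_ids)), replace=False)
    ) if open_ids and config.n_atac_lost else set()

    return PeakSet(intervals, label="universe"), truth


def accessible_peak_set(peaks: PeakSet, truth: SyntheticTruth) -> PeakSet:
    """The accessible-chromatin subset of the universe (the ATAC peak set)."""
    return peaks.subset(truth.accessible_ids & set(peaks.ids), label="atac")


# ---------------------------------------------------------------------------
# Tag counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if (mean < 0).any():
        raise ValueError("negative mean in count simulation")
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _chip_mean(
    config: SimulationConfig,
    factor: str,
    genotype: str,
    peak_class: str,
    compensated: bool,
) -> float:
    m, bg, f = config.mean_depth, config.background_depth, config.effect_fold
    if peak_class == "background":
        return bg
    if factor == "tf1":
        if genotype in config.binding_null_genotypes:
            return bg
        if peak_class == "tf2_specific":
            return max(bg, m / f)
        return m
    # factor tf2
    if peak_class == "tf1_specific":
        if genotype != config.wild_type and compensated:
            return m  # de-novo acquisition in the mutant
        return max(bg, m / f)
    return m


def simulate_tag_counts(
    peaks: PeakSet, truth: SyntheticTruth, config: SimulationConfig
) -> Dict[Tuple[str, str], TagCountTable]:
    """Per-(factor, genotype) raw ChIP tag-count tables over the universe.

    Shared peaks carry equal expected signal for both factors; factor-1
    specific peaks have an expectation ratio of ``effect_fold`` in wild type;
    in mutant genotypes the compensated subset of those peaks gains factor-2
    signal up to the occupied mean, and factor-1 signal drops to the
    background level in binding-null genotypes.
    """
    if len(peaks) == 0:
        raise ValueError("peak universe is empty")
    missing = [p for p in peaks.ids if p not in truth.peak_class_truth]
    if missing:
        raise ValueError(f"peaks without class truth: {missing[:5]}")
    bad = {p: c for p, c in truth.peak_class_truth.items() if c not in PEAK_CLASSES}
    if bad:
        raise ValueError(f"malformed truth classes: {dict(list(bad.items())[:3])}")
    rng = config.rng("tags")
    ids = peaks.ids
    out: Dict[Tuple[str, str], TagCountTable] = {}
    for factor in ("tf1", "tf2"):
        for genotype in config.genotypes:
            means = np.array(
                [
                    _chip_mean(
                        config,
                        factor,
                        genotype,
                        truth.peak_class_truth[p],
                        p in truth.compensated_ids,
                    )
                    for p in ids
                ]
            )
            cols = {}
            for r in range(config.n_replicates_chip):
                cols[f"{factor}_{genotype}_rep{r + 1}"] = _nb_draw(
                    rng, means, config.dispersion
                )
            out[(factor, genotype)] = TagCountTable(
                pd.DataFrame(cols, index=pd.Index(ids, name="peak_id"), dtype=float)
            )
    return out


def simulate_atac_counts(
    peaks: PeakSet, truth: SyntheticTruth, config: SimulationConfig
) -> TagCountTable:
    """Accessibility tag counts per genotype over the universe.

    Accessible peaks carry the occupied mean, closed peaks the background
    mean; a small planted set of sites is gained or lost in the mutants.
    """
    rng = config.rng("atac")
    ids = peaks.ids
    cols = {}
    for genotype in config.genotypes:
        means = []
        for p in ids:
            open_ = p in truth.accessible_ids
            if genotype != config.wild_type:
                if p in truth.atac_gained_ids:
                    open_ = True
                elif p in truth.atac_lost_ids:
                    open_ = False
            means.append(config.mean_depth if open_ else config.background_depth)
        means = np.array(means)
        for r in range(config.n_replicates_atac):
            cols[f"atac_{genotype}_rep{r + 1}"] = _nb_draw(rng, means, config.dispersion)
    return TagCountTable(pd.DataFrame(cols, index=pd.Index(ids, name="peak_id"), dtype=float))


# ---------------------------------------------------------------------------
# Sequences with planted motifs
# ---------------------------------------------------------------------------

def _plant_offsets(
    rng: np.random.Generator, n: int, seq_len: int, motif_len: int
) -> List[int]:
    """Sample ``n`` non-overlapping motif offsets; capacity error if impossible."""
    if n * motif_len > seq_len:
        raise ValueError(
            f"cannot pack {n} motifs of length {motif_len} into {seq_len} bp"
        )
    offsets: List[int] = []
    for _ in range(n):
        placed = False
        for _try in range(200):
            off = int(rng.integers(0, seq_len - motif_len + 1))
            if all(abs(off - o) >= motif_len for o in offsets):
                offsets.append(off)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {n} non-overlapping motifs in {seq_len} bp"
            )
    return sorted(offsets)


def _scrub_spurious(
    rng: np.random.Generator,
    seq: List[str],
    patterns: Sequence[str],
    protected: Set[int],
) -> None:
    """Redraw unprotected bases until no exact pattern occurrence remains
    outside the planted footprints (in-place)."""
    text = "".join(seq)
    for _iteration in range(200):
        dirty = False
        text = "".join(seq)
        for pat in patterns:
            start = text.find(pat)
            while start != -1:
                window = set(range(start, start + len(pat)))
                editable = sorted(window - protected)
                if editable:
                    pos = editable[int(rng.integers(0, len(editable)))]
                    choices = [b for b in "ACGT" if b != seq[pos]]
                    seq[pos] = choices[int(rng.integers(0, 3))]
                    dirty = True
                start = text.find(pat, start + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub spurious motif matches from background")


def generate_sequences_with_motifs(
    peaks: PeakSet,
    truth: SyntheticTruth,
    pwms: Sequence[PositionWeightMatrix],
    config: SimulationConfig,
) -> Dict[str, str]:
    """Random background sequences with planted consensus motif instances.

    Promoter-located peaks draw their per-motif multiplicity from a
    high-multiplicity distribution (Poisson with mean ``promoter_motif_rate``)
    and distal peaks from a low one (``distal_motif_rate``); planted instances
    never overlap, strands are drawn 50/50, and the background is rejection-
    scrubbed of chance exact-consensus occurrences so planted counts are the
    true counts. Placements are recorded in the truth table.
    """
    rng = config.rng("sequences")
    for pwm in pwms:
        if len(pwm) >= config.peak_width:
            raise ValueError(f"motif {pwm.name!r} is not shorter than the peak width")
    sequences: Dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for iv in peaks:
        width = len(iv)
        seq = list(bases[rng.integers(0, 4, size=width)])
        location = truth.peak_location.get(iv.id, "distal")
        rate = (
            config.promoter_motif_rate if location == "promoter" else config.distal_motif_rate
        )
        placements: List[Tuple[int, str, str]] = []
        protected: Set[int] = set()
        for pwm in pwms:
            k = int(rng.poisson(rate))
            if k == 0:
                continue
            taken = sorted(protected)
            # sample offsets avoiding earlier PWMs' footprints as well
            offsets: List[int] = []
            for _ in range(k):
                placed = False
                for _try in range(200):
                    off = int(rng.integers(0, width - len(pwm) + 1))
                    footprint = range(off, off + len(pwm))
                    if any(p in protected for p in footprint):
                        continue
                    if any(abs(off - o) < len(pwm) for o in offsets):
                        continue
                    offsets.append(off)
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        f"could not pack {k} instances of {pwm.name!r} into peak {iv.id}"
                    )
            for off in sorted(offsets):
                strand = "+" if rng.random() < 0.5 else "-"
                inst = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
                seq[off : off + len(pwm)] = list(inst)
                protected.update(range(off, off + len(pwm)))
                placements.append((off, strand, pwm.name))
        patterns = []
        for pwm in pwms:
            patterns.extend([pwm.consensus, reverse_complement(pwm.consensus)])
        _scrub_spurious(rng, seq, patterns, protected)
        sequences[iv.id] = "".join(seq)
        truth.motif_placements[iv.id] = sorted(placements)
    return sequences


# ---------------------------------------------------------------------------
# Bulk expression
# ---------------------------------------------------------------------------

def _stage_patterns(n_stages: int) -> np.ndarray:
    """Planted expression-pattern templates (log2 offsets per stage)."""
    t = np.linspace(0.0, 1.0, n_stages)
    return np.vstack(
        [
            np.zeros(n_stages),  # flat
            3.0 * (t - 0.5),  # up-ramp
            -3.0 * (t - 0.5),  # down-ramp
            1.5 - 3.0 * np.abs(2.0 * t - 1.0),  # mid-peak
        ]
    )


def simulate_expression(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Staged, replicated log-normal expression with planted structure.

    Each gene gets a baseline (log2 ~ U(3, 8)), one of four stage-pattern
    templates (the planted clusters) and a directional group: 'up'/'down' in a
    mutant multiplies the wild-type mean by ``expression_fold`` (or its
    inverse) at every stage. Replicates add log2-normal noise of SD
    ``expression_noise_sd``.
    """
    if config.n_replicates < 2:
        raise ValueError("at least 2 replicates are required for replicate averaging")
    rng = config.rng("expression")
    genes = annotation.gene_ids
    stages, genotypes = config.stages, config.genotypes
    patterns = _stage_patterns(len(stages))
    columns = pd.MultiIndex.from_tuples(
        [
            (s, g, f"r{r + 1}")
            for s in stages
            for g in genotypes
            for r in range(config.n_replicates)
        ],
        names=["stage", "genotype", "replicate"],
    )
    truth = SyntheticTruth()
    if not genes:
        empty = pd.DataFrame(
            np.zeros((0, len(columns))), index=pd.Index([], name="gene_id"), columns=columns
        )
        return ExpressionMatrix(empty), truth

    n = len(genes)
    baseline = rng.uniform(3.0, 8.0, size=n)
    cluster_ids = rng.integers(0, len(patterns), size=n)
    group_codes = rng.choice(9, size=n, p=np.asarray(config.group_proportions))
    groups = np.where(group_codes == 8, 0, group_codes + 1)  # 1..8, 0 = unchanged

    log2_fold = np.log2(config.expression_fold)
    dir_offset = {"up": log2_fold, "down": -log2_fold, "unchanged": 0.0}
    mut_a = genotypes[1] if len(genotypes) > 1 else None
    mut_b = genotypes[2] if len(genotypes) > 2 else None

    data = np.zeros((n, len(columns)))
    for j, (stage, genotype, _rep) in enumerate(columns):
        s_idx = stages.index(stage)
        log2_mean = baseline + patterns[cluster_ids, s_idx]
        if genotype != config.wild_type:
            offsets = np.zeros(n)
            for gi in range(n):
                g = groups[gi]
                if g == 0:
                    continue
                da, db = DIRECTIONS_BY_GROUP[g]
                if genotype == mut_a:
                    offsets[gi] = dir_offset[da]
                elif genotype == mut_b:
                    offsets[gi] = dir_offset[db]
            log2_mean = log2_mean + offsets
        noise = (
            rng.normal(0.0, config.expression_noise_sd, size=n)
            if config.expression_noise_sd > 0
            else 0.0
        )
        data[:, j] = np.exp2(log2_mean + noise)

    expr = ExpressionMatrix(
        pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=columns)
    )
    truth.gene_group_truth = dict(zip(genes, (int(g) for g in groups)))
    truth.gene_cluster_truth = dict(zip(genes, (int(c) for c in cluster_ids)))
    return expr, truth


# ---------------------------------------------------------------------------
# Single cells
# ---------------------------------------------------------------------------

SC_GENE_GROUPS = {
    "ramp": 40,
    "brA": 10,
    "brB": 10,
    "brC": 10,
    "extra": 10,
    "hk": 20,
}
RAMP_AMPLITUDE = 20.0
BRANCH_AMPLITUDE = 40.0
EXTRA_AMPLITUDE = 40.0
KIT_MEAN = 20.0


def _sc_gene_panel() -> List[str]:
    genes = ["Kit"]
    for group, count in SC_GENE_GROUPS.items():
        genes.extend(f"{group}_{i + 1:02d}" for i in range(count))
    return genes


def _sc_cell_means(
    t: float, branch: str, genes: Sequence[str], hk_base: Mapping[str, float]
) -> np.ndarray:
    """Expected expression of one cell at latent time t on a branch."""
    means = np.empty(len(genes))
    for gi, g in enumerate(genes):
        if g == "Kit":
            means[gi] = KIT_MEAN
        elif g.startswith("ramp"):
            i = int(g.split("_")[1])
            means[gi] = 1.0 + RAMP_AMPLITUDE * (t if i <= SC_GENE_GROUPS["ramp"] // 2 else 1.0 - t)
        elif g.startswith("br"):
            gene_branch = "branch_" + g[2]
            on = branch == gene_branch
            means[gi] = 1.0 + (BRANCH_AMPLITUDE * max(t - 0.5, 0.0) if on else 0.0)
        elif g.startswith("extra"):
            means[gi] = 1.0 + (EXTRA_AMPLITUDE if branch == "extra" else 0.0)
        else:  # housekeeping
            means[gi] = hk_base[g]
    return means


def simulate_single_cells(
    config: SimulationConfig,
) -> Tuple[Dict[str, CellMatrix], SyntheticTruth]:
    """Cells sampled along a branched lineage for two genotypes.

    Latent time is uniform on [0, 1]; for branched topologies cells past the
    t = 0.5 split are assigned a branch at random. Expression combines shared
    ramp programs, branch-specific programs switching on after the split,
    housekeeping genes, and a constitutive Kit gene used to emulate
    Kit-sorting of the input cells. With ``extra_cluster_in_mutant`` the
    second genotype carries an extra planted population expressing its own
    program; a small planted set of genes is down-regulated genotype-wide in
    the mutant. Noise is gamma-Poisson with CV ``sc_noise`` (exact means when
    0).
    """
    if config.n_cells_per_genotype < 20:
        raise ValueError("n_cells_per_genotype must be >= 20")
    rng = config.rng("cells")
    genes = _sc_gene_panel()
    hk_genes = [g for g in genes if g.startswith("hk")]
    hk_base = dict(zip(hk_genes, rng.uniform(5.0, 30.0, size=len(hk_genes))))
    sc_de = sorted(rng.choice(hk_genes, size=min(config.n_sc_de_genes, len(hk_genes)),
                              replace=False)) if config.n_sc_de_genes else []

    topology = config.trajectory_topology
    branches_after_split = {
        "linear": ["trunk"],
        "bifurcating": ["branch_A", "branch_B"],
        "multifurcating": ["branch_A", "branch_B", "branch_C"],
    }[topology]

    wt, mutant = config.genotypes[0], config.genotypes[1]
    truth = SyntheticTruth()
    truth.sc_de_gene_ids = [str(g) for g in sc_de]
    matrices: Dict[str, CellMatrix] = {}
    for genotype in (wt, mutant):
        n = config.n_cells_per_genotype
        n_extra = (
            int(round(config.extra_cluster_fraction * n))
            if (genotype == mutant and config.extra_cluster_in_mutant)
            else 0
        )
        times = rng.uniform(0.0, 1.0, size=n - n_extra)
        rows, ids = [], []
        for i, t in enumerate(times):
            if topology == "linear":
                branch = "trunk"
                cluster = f"bin{min(int(t * 4), 3) + 1}"
            else:
                if t < 0.5:
                    branch = "trunk"
                    cluster = "trunk_early" if t < 0.25 else "trunk_late"
                else:
                    branch = branches_after_split[int(rng.integers(0, len(branches_after_split)))]
                    cluster = branch
            cid = f"{genotype}_c{i + 1:04d}"
            ids.append(cid)
            truth.cell_time_truth[cid] = float(t)
            truth.cell_branch_truth[cid] = branch
            truth.cell_cluster_truth[cid] = cluster
            rows.append(_sc_cell_means(t, branch, genes, hk_base))
        for j in range(n_extra):
            cid = f"{genotype}_c{n - n_extra + j + 1:04d}"
            ids.append(cid)
            truth.cell_time_truth[cid] = 1.0
            truth.cell_branch_truth[cid] = "extra"
            truth.cell_cluster_truth[cid] = "extra"
            rows.append(_sc_cell_means(1.0, "extra", genes, hk_base))
        means = np.vstack(rows)
        if genotype == mutant and sc_de:
            cols = [genes.index(g) for g in sc_de]
            means[:, cols] /= config.sc_de_fold
        if config.sc_noise > 0:
            shape = 1.0 / (config.sc_noise**2)
            rates = means * rng.gamma(shape, 1.0 / shape, size=means.shape)
            values = rng.poisson(rates).astype(float)
        else:
            values = means
        df = pd.DataFrame(values, index=pd.Index(ids, name="cell_id"), columns=genes)
        kit = df["Kit"]
        keep = kit >= config.kit_threshold
        df = df.loc[keep]
        meta = pd.DataFrame({"genotype": genotype}, index=df.index)
        meta["total_counts"] = df.sum(axis=1)
        for cid in list(truth.cell_time_truth):
            if cid.startswith(f"{genotype}_") and cid not in df.index:
                del truth.cell_time_truth[cid]
                del truth.cell_branch_truth[cid]
                del truth.cell_cluster_truth[cid]
        matrices[genotype] = CellMatrix(df, meta)
    return matrices, truth
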