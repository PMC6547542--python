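"""End-to-end orchestration: dataset simulation and the analysis pipeline.

``simulate`` writes a complete synthetic dataset (inputs plus truth tables) to
a directory; ``run_pipeline`` consumes such a directory — or any directory
laid out the same way with real data — and executes every analysis stage in
order, writing each intermediate as TSV/BED/JSON plus a machine-readable
``summary.json``. Running the pipeline on a freshly simulated dataset is the
repository's canonical integration test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import expression as xp
from . import intervals as iv
from . import motifs as mt
from . import occupancy as oc
from . import synth
from . import trajectory as tj

__all__ = ["PipelineConfig", "PipelineError", "simulate", "run_pipeline"]

logger = logging.getLogger("tfpair")


def _setup_logging(log_path: Optional[Path] = None) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    stderr = logging.StreamHandler(sys.stderr)
    stderr.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(stderr)
    if log_path is not None:
        fh = logging.FileHandler(log_path, mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        logger.addHandler(fh)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    dataset_dir: str
    output_dir: str
    fold_threshold: float = 2.0
    pseudocount: float = 1.0
    min_overlap: int = 1
    norm_target: float = 1e7
    promoter_window: int = 1_000
    min_expr: float = 1.0
    n_expression_clusters: int = 13
    sc_k: int = 4
    sc_k_mutant: Optional[int] = None  # default: sc_k + 1
    sc_d: int = 10
    sc_min_counts: float = 0.0
    sc_min_genes: int = 0
    match_cutoff: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be > 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate_paths(self) -> None:
        root = Path(self.dataset_dir)
        if not root.is_dir():
            raise FileNotFoundError(f"dataset directory not found: {root}")
        for name in ("annotation.tsv", "peaks_universe.bed"):
            if not (root / name).exists():
                raise FileNotFoundError(f"required input missing: {root / name}")


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def simulate(config: synth.SimulationConfig, outdir) -> Dict[str, str]:
    """Write a full synthetic dataset (inputs + truth tables) to ``outdir``.

    Returns the manifest (logical name -> relative path), which is also
    written as ``manifest.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    manifest: Dict[str, str] = {}

    def record(name: str, relpath: str) -> Path:
        manifest[name] = relpath
        return out / relpath

    config.to_yaml(record("config", "config.yaml"))

    annotation = synth.generate_annotation(config)
    annotation.to_tsv(record("annotation", "annotation.tsv"))

    peaks, truth = synth.generate_peak_landscape(config, annotation)
    iv.write_bed(peaks, record("peaks_universe", "peaks_universe.bed"))
    iv.write_bed(
        synth.accessible_peak_set(peaks, truth), record("atac_peaks", "atac_peaks.bed")
    )

    if len(peaks):
        chip = synth.simulate_tag_counts(peaks, truth, config)
        for (factor, genotype), table in chip.items():
            table.to_tsv(record(f"chip_{factor}_{genotype}", f"chip_{factor}_{genotype}.tsv"))
        atac = synth.simulate_atac_counts(peaks, truth, config)
        atac.to_tsv(record("atac_counts", "atac_counts.tsv"))

        pwms = [mt.gc_box_pwm()]
        mt.write_pwms_tabular(pwms, record("pwms", "pwms.txt"))
        sequences = synth.generate_sequences_with_motifs(peaks, truth, pwms, config)
        mt.write_fasta(sequences, record("sequences", "sequences.fasta"))

    expr, expr_truth = synth.simulate_expression(annotation, config)
    truth.merge(expr_truth)
    expr.to_tsv(record("expression", "expression.tsv"))

    cells, cell_truth = synth.simulate_single_cells(config)
    truth.merge(cell_truth)
    for genotype, cm in cells.items():
        cm.to_tsv(
            record(f"cells_{genotype}_counts", f"cells_{genotype}_counts.tsv"),
            record(f"cells_{genotype}_meta", f"cells_{genotype}_meta.tsv"),
        )

    # truth tables
    peak_truth = pd.DataFrame(
        {
            "class": pd.Series(truth.peak_class_truth),
            "location": pd.Series(truth.peak_location),
        }
    )
    if len(peak_truth):
        peak_truth["accessible"] = peak_truth.index.isin(truth.accessible_ids)
        peak_truth["compensated"] = peak_truth.index.isin(truth.compensated_ids)
        peak_truth["atac_gained"] = peak_truth.index.isin(truth.atac_gained_ids)
        peak_truth["atac_lost"] = peak_truth.index.isin(truth.atac_lost_ids)
    peak_truth.to_csv(record("truth_peaks", "truth/peaks.tsv"), sep="\t", index_label="peak_id")

    placements = [
        (pid, off, strand, name)
        for pid, plist in sorted(truth.motif_placements.items())
        for off, strand, name in plist
    ]
    pd.DataFrame(placements, columns=["peak_id", "offset", "strand", "motif"]).to_csv(
        record("truth_motifs", "truth/motif_placements.tsv"), sep="\t", index=False
    )

    gene_truth = pd.DataFrame(
        {
            "group": pd.Series(truth.gene_group_truth),
            "pattern_cluster": pd.Series(truth.gene_cluster_truth),
        }
    )
    gene_truth.to_csv(record("truth_genes", "truth/genes.tsv"), sep="\t", index_label="gene_id")

    cell_truth_df = pd.DataFrame(
        {
            "latent_time": pd.Series(truth.cell_time_truth),
            "branch": pd.Series(truth.cell_branch_truth),
            "cluster": pd.Series(truth.cell_cluster_truth),
        }
    )
    cell_truth_df.to_csv(record("truth_cells", "truth/cells.tsv"), sep="\t", index_label="cell_id")
    with open(record("truth_sc_de_genes", "truth/sc_de_genes.json"), "w") as fh:
        json.dump(truth.sc_de_gene_ids, fh)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _replicate_columns(table: oc.TagCountTable, prefix: str) -> List[str]:
    cols = [c for c in table.sample_ids if c.startswith(prefix)]
    if not cols:
        raise KeyError(f"no sample columns with prefix {prefix!r}")
    return cols


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every analysis stage in order and write the report bundle.

    Stage order: high-confidence filtering, normalization, accessibility
    correlation and differential sites, shared/specific classification,
    de-novo detection, motif counting/distributions/enrichment, differential
    gene selection, pattern clustering, directional grouping, target mapping,
    Venn overlaps and — when single-cell inputs are present — the genotype
    trajectory comparison. Returns the summary dictionary (also written as
    ``summary.json``).
    """
    config.validate_paths()
    root = Path(config.dataset_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    logger.info("pipeline start: dataset=%s seed=%d", root, config.seed)

    sim_cfg = None
    if (root / "config.yaml").exists():
        sim_cfg = synth.SimulationConfig.from_yaml(root / "config.yaml")
    genotypes = list(sim_cfg.genotypes) if sim_cfg else ["WT", "mutA", "mutB"]
    wt, mutants = genotypes[0], genotypes[1:]
    stages_labels = list(sim_cfg.stages) if sim_cfg else None

    summary: Dict = {
        "parameters": dataclasses.asdict(config),
        "genotypes": genotypes,
    }

    def stage(name):
        logger.info("stage: %s", name)

    # --- inputs -----------------------------------------------------------
    try:
        stage("load")
        annotation = iv.GenomeAnnotation.from_tsv(
            root / "annotation.tsv", promoter_window=config.promoter_window
        )
        universe = iv.read_bed(root / "peaks_universe.bed", label="universe")
        atac_peaks = (
            iv.read_bed(root / "atac_peaks.bed", label="atac")
            if (root / "atac_peaks.bed").exists()
            else iv.PeakSet([], label="atac")
        )
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    # --- high-confidence filter ------------------------------------------
    try:
        stage("high_confidence_filter")
        hc = iv.filter_high_confidence(universe, atac_peaks, min_overlap=config.min_overlap)
        iv.write_bed(hc, out / "high_confidence_peaks.bed")
        summary["high_confidence"] = {"n_universe": len(universe), "n_high_confidence": len(hc)}
    except Exception as exc:
        raise PipelineError("high_confidence_filter", str(exc)) from exc

    # --- accessibility: correlation + differential ------------------------
    atac_norm = None
    if (root / "atac_counts.tsv").exists():
        try:
            stage("accessibility")
            atac_table = oc.TagCountTable.from_tsv(root / "atac_counts.tsv")
            atac_norm = oc.normalize_tags(atac_table, config.norm_target)
            corr = oc.correlation_matrix(atac_norm)
            corr.to_csv(out / "atac_correlation.tsv", sep="\t")
            diff_summary = {}
            for mut in mutants:
                a = atac_norm.mean_of(_replicate_columns(atac_norm, f"atac_{wt}_"))
                b = atac_norm.mean_of(_replicate_columns(atac_norm, f"atac_{mut}_"))
                gained, lost = oc.differential_sites(
                    a, b, config.fold_threshold, config.pseudocount
                )
                pd.DataFrame(
                    {"peak_id": gained + lost, "status": ["gained"] * len(gained) + ["lost"] * len(lost)}
                ).to_csv(out / f"atac_differential_{mut}.tsv", sep="\t", index=False)
                diff_summary[mut] = {"gained": len(gained), "lost": len(lost)}
            summary["accessibility"] = {
                "min_correlation": float(np.min(corr.to_numpy())),
                "differential": diff_summary,
            }
        except Exception as exc:
            raise PipelineError("accessibility", str(exc)) from exc

    # --- shared/specific classification ----------------------------------
    classification = None
    chip_norm: Dict[Tuple[str, str], oc.TagCountTable] = {}
    if (root / f"chip_tf1_{wt}.tsv").exists():
        try:
            stage("classification")
            for factor in ("tf1", "tf2"):
                for genotype in genotypes:
                    path = root / f"chip_{factor}_{genotype}.tsv"
                    if path.exists():
                        chip_norm[(factor, genotype)] = oc.normalize_tags(
                            oc.TagCountTable.from_tsv(path), config.norm_target
                        )
            merged = pd.concat(
                [chip_norm[("tf1", wt)].data, chip_norm[("tf2", wt)].data], axis=1
            )
            wt_table = oc.TagCountTable(
                merged, normalized=False
            )  # re-normalize jointly below
            wt_norm = oc.normalize_tags(wt_table, config.norm_target)
            cls_full = oc.classify_shared_specific(
                wt_norm,
                _replicate_columns(wt_norm, "tf1_"),
                _replicate_columns(wt_norm, "tf2_"),
                config.fold_threshold,
                config.pseudocount,
            )
            hc_ids = [p for p in hc.ids if p in cls_full.table.index]
            classification = oc.PeakClassification(
                cls_full.table.loc[hc_ids],
                fold_threshold=config.fold_threshold,
                pseudocount=config.pseudocount,
            )
            classification.to_tsv(out / "peak_classification.tsv")
            ranked = oc.rank_matrix(wt_norm, wt_norm.sample_ids[0], descending=True)
            ranked.to_tsv(out / "ranked_tag_counts.tsv")
            summary["classification"] = classification.counts
        except Exception as exc:
            raise PipelineError("classification", str(exc)) from exc

    # --- de-novo acquisition / loss ---------------------------------------
    if classification is not None:
        try:
            stage("de_novo")
            specific = classification.ids_with_label("tf1_specific")
            denovo_summary = {}
            for mut in mutants:
                if ("tf2", mut) not in chip_norm:
                    continue
                merged = pd.concat(
                    [chip_norm[("tf2", wt)].data, chip_norm[("tf2", mut)].data], axis=1
                )
                tf2_norm = oc.normalize_tags(oc.TagCountTable(merged), config.norm_target)
                res = oc.detect_de_novo(
                    tf2_norm,
                    specific,
                    _replicate_columns(tf2_norm, f"tf2_{wt}_"),
                    _replicate_columns(tf2_norm, f"tf2_{mut}_"),
                    config.fold_threshold,
                    config.pseudocount,
                )
                res.to_tsv(out / f"de_novo_{mut}.tsv")
                denovo_summary[mut] = res.counts
            summary["de_novo"] = denovo_summary
        except Exception as exc:
            raise PipelineError("de_novo", str(exc)) from exc

    # --- motif content -----------------------------------------------------
    if (root / "sequences.fasta").exists() and classification is not None:
        try:
            stage("motifs")
            sequences = mt.read_fasta(root / "sequences.fasta")
            pwms = mt.read_pwms_tabular(root / "pwms.txt")
            hc_seqs = {p: sequences[p] for p in classification.table.index}
            counts = mt.count_motifs_per_peak(hc_seqs, pwms)
            counts.to_tsv(out / "motif_counts.tsv")
            locations = iv.annotate_location(
                hc.subset(list(classification.table.index)), annotation
            )
            classes = classification.table["label"].to_dict()
            dist = mt.motif_count_distribution(counts, classes, locations)
            dist.to_csv(out / "motif_count_distribution.tsv", sep="\t", index=False)
            shared_ids = classification.ids_with_label("shared")
            enrich = {}
            for label in ("tf1_specific", "tf2_specific"):
                fg = classification.ids_with_label(label)
                if fg and shared_ids:
                    table = mt.motif_enrichment(counts, fg, shared_ids)
                    table.to_csv(out / f"motif_enrichment_{label}.tsv", sep="\t", index=False)
                    enrich[label] = {
                        row.motif: float(row.odds_ratio) for row in table.itertuples()
                    }
            mean_by_stratum = {
                stratum: float(
                    counts.counts.loc[
                        [p for p, loc in locations.items() if loc == stratum]
                    ].mean().mean()
                )
                for stratum in ("promoter", "distal")
                if any(loc == stratum for loc in locations.values())
            }
            summary["motifs"] = {
                "mean_count_by_stratum": mean_by_stratum,
                "enrichment_odds_ratios": enrich,
            }
        except Exception as exc:
            raise PipelineError("motifs", str(exc)) from exc

    # --- bulk expression ----------------------------------------------------
    target_map = {}
    expr = None
    if (root / "expression.tsv").exists():
        try:
            stage("expression")
            expr = xp.ExpressionMatrix.from_tsv(root / "expression.tsv")
            de_genes = xp.select_differential(
                expr, wt=wt, mutants=mutants,
                fold_threshold=config.fold_threshold, min_expr=config.min_expr,
            )
            pd.Series(de_genes, name="gene_id").to_csv(
                out / "differential_genes.tsv", sep="\t", index=False
            )
            summary["expression"] = {"n_differential": len(de_genes)}
            if de_genes:
                means = pd.DataFrame(
                    {
                        f"{s}_{g}": expr.mean_expression(s, g).loc[de_genes]
                        for s in expr.stages
                        for g in expr.genotypes
                    }
                )
                z = xp.row_zscore(np.log2(means + 1.0))
                k = min(config.n_expression_clusters, len(de_genes))
                labels, profiles = xp.cluster_covariant(z, k)
                labels.to_csv(out / "expression_clusters.tsv", sep="\t", index_label="gene_id")
                profiles.to_csv(out / "expression_cluster_profiles.tsv", sep="\t")
                summary["expression"]["n_clusters"] = int(labels.nunique())
            group_summary = {}
            for cell_type in expr.stages:
                ga = xp.assign_direction_groups(
                    expr, cell_type, wt=wt,
                    mutant_a=mutants[0], mutant_b=mutants[1] if len(mutants) > 1 else mutants[0],
                    fold_threshold=config.fold_threshold, min_expr=config.min_expr,
                )
                ga.to_tsv(out / f"direction_groups_{cell_type}.tsv")
                group_summary[cell_type] = {str(g): n for g, n in ga.counts.items()}
            summary["expression"]["groups"] = group_summary
        except Exception as exc:
            raise PipelineError("expression", str(exc)) from exc

    # --- target mapping + venn ---------------------------------------------
    if expr is not None and classification is not None:
        try:
            stage("targets")
            cls_ids = {
                "tf1": classification.ids_with_label("tf1_specific")
                + classification.ids_with_label("shared"),
                "tf2": classification.ids_with_label("tf2_specific")
                + classification.ids_with_label("shared"),
            }
            target_summary = {}
            per_factor_targets = {}
            for factor, ids in cls_ids.items():
                tm = xp.map_peaks_to_genes(
                    hc.subset([p for p in ids if p in set(hc.ids)]),
                    annotation,
                    max_distance=config.promoter_window,
                )
                per_factor_targets[factor] = set(tm)
                rows = [(g, ",".join(ps)) for g, ps in sorted(tm.items())]
                pd.DataFrame(rows, columns=["gene_id", "peak_ids"]).to_csv(
                    out / f"targets_{factor}.tsv", sep="\t", index=False
                )
                target_summary[factor] = len(tm)
            summary["targets"] = target_summary

            first_stage = expr.stages[0]
            ga = xp.assign_direction_groups(
                expr, first_stage, wt=wt,
                mutant_a=mutants[0], mutant_b=mutants[1] if len(mutants) > 1 else mutants[0],
                fold_threshold=config.fold_threshold, min_expr=config.min_expr,
            )
            up = set(ga.table.index[ga.table["dir_a"] == "up"])
            down = set(ga.table.index[ga.table["dir_a"] == "down"])
            venns = {
                "targets_vs_up": xp.overlap_targets(
                    {"tf1_targets": per_factor_targets["tf1"], "up": up}
                ),
                "targets_vs_down": xp.overlap_targets(
                    {"tf1_targets": per_factor_targets["tf1"], "down": down}
                ),
            }
            with open(out / "venn_overlaps.json", "w") as fh:
                json.dump(venns, fh, indent=2, sort_keys=True)
            summary["venn"] = venns

            group_targets = {}
            for g in range(1, 9):
                genes = set(ga.genes_in_group(g))
                group_targets[str(g)] = {
                    "n_genes": len(genes),
                    "tf1_targets": len(genes & per_factor_targets["tf1"]),
                    "tf2_targets": len(genes & per_factor_targets["tf2"]),
                }
            summary["group_targets"] = group_targets
        except Exception as exc:
            raise PipelineError("targets", str(exc)) from exc

    # --- single cells --------------------------------------------------------
    sc_genotypes = [g for g in genotypes if (root / f"cells_{g}_counts.tsv").exists()]
    if len(sc_genotypes) >= 2:
        try:
            stage("single_cells")
            results, matrices = {}, {}
            ks = {sc_genotypes[0]: config.sc_k}
            ks[sc_genotypes[1]] = (
                config.sc_k_mutant if config.sc_k_mutant is not None else config.sc_k + 1
            )
            for genotype in sc_genotypes[:2]:
                cm = tj.CellMatrix.from_tsv(
                    root / f"cells_{genotype}_counts.tsv", root / f"cells_{genotype}_meta.tsv"
                )
                pre = tj.preprocess_cells(
                    cm, min_counts=config.sc_min_counts, min_genes=config.sc_min_genes
                )
                coords, labels = tj.reduce_and_cluster(
                    pre, k=ks[genotype], d=config.sc_d, seed=config.seed
                )
                markers = tj.find_markers(pre, labels)
                markers.to_csv(out / f"markers_{genotype}.tsv", sep="\t", index=False)
                totals = pre.values.sum(axis=1).groupby(labels).mean()
                root_cluster = int(totals.idxmin())
                res = tj.pseudotime_order(coords, labels, root_cluster)
                res.to_json(out / f"trajectory_{genotype}.json")
                res.per_cell_table().to_csv(
                    out / f"pseudotime_{genotype}.tsv", sep="\t", index_label="cell_id"
                )
                results[genotype], matrices[genotype] = res, pre
            ga_, gb_ = sc_genotypes[0], sc_genotypes[1]
            comparison = tj.compare_genotypes(
                results[ga_], matrices[ga_], results[gb_], matrices[gb_],
                match_cutoff=config.match_cutoff,
            )
            comparison.to_json(out / "genotype_comparison.json")
            summary["single_cells"] = {
                "genotypes": [ga_, gb_],
                "cluster_counts": {g: int(results[g].labels.nunique()) for g in (ga_, gb_)},
                "branch_points": {
                    ga_: results[ga_].branch_points,
                    gb_: results[gb_].branch_points,
                },
                "a_only_clusters": comparison.a_only_clusters,
                "b_only_clusters": comparison.b_only_clusters,
            }
        except Exception as exc:
            raise PipelineError("single_cells", str(exc)) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
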