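"""Generator determinism, planted-structure realization, truth consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfpair import (
    SimulationConfig,
    annotate_location,
    gc_box_pwm,
    generate_annotation,
    generate_peak_landscape,
    generate_sequences_with_motifs,
    preprocess_cells,
    reduce_and_cluster,
    simulate_atac_counts,
    simulate_expression,
    simulate_single_cells,
    simulate_tag_counts,
)
from tfpair.motifs import reverse_complement
from tfpair.synth import _chip_mean, _plant_offsets

SMALL = dict(
    n_genes=40,
    n_peaks_shared=60,
    n_peaks_tf1_specific=20,
    n_peaks_tf2_specific=20,
    n_background=10,
    n_cells_per_genotype=60,
)


class TestConfigValidation:
    def test_group_proportions_must_be_simplex(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(group_proportions=(0.2,) * 9)
        with pytest.raises(ValueError, match="length 9"):
            SimulationConfig(group_proportions=(1.0,))

    def test_effect_fold_and_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(effect_fold=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(compensated_fraction=1.5)

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError, match="topology"):
            SimulationConfig(trajectory_topology="circle")

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=9, effect_fold=3.0, stages=("a", "b"))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestAnnotation:
    def test_zero_genes_gives_empty_annotation(self):
        ann = generate_annotation(SimulationConfig(n_genes=0))
        assert len(ann) == 0

    def test_deterministic_under_seed(self):
        a = generate_annotation(SimulationConfig(seed=5, **SMALL))
        b = generate_annotation(SimulationConfig(seed=5, **SMALL))
        pd.testing.assert_frame_equal(a.tss, b.tss)

    def test_promoter_windows_inside_chromosome_bounds(self):
        cfg = SimulationConfig(seed=2, n_chroms=1, chrom_length=1_000_000, n_genes=100)
        ann = generate_annotation(cfg)
        for chrom, ws, we, _g in ann.promoter_intervals():
            assert 0 <= ws < we <= cfg.chrom_length

    def test_strands_roughly_balanced(self):
        ann = generate_annotation(SimulationConfig(seed=0, n_chroms=4, n_genes=400))
        frac = (ann.tss["strand"] == "+").mean()
        assert 0.4 < frac < 0.6

    def test_capacity_error_when_genome_too_small(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_annotation(SimulationConfig(n_genes=1000, n_chroms=1,
                                                 chrom_length=100_000))


class TestPeakLandscape:
    def test_empty_when_all_counts_zero(self):
        cfg = SimulationConfig(n_peaks_shared=0, n_peaks_tf1_specific=0,
                               n_peaks_tf2_specific=0, n_background=0)
        peaks, truth = generate_peak_landscape(cfg, generate_annotation(cfg))
        assert len(peaks) == 0 and truth.peak_class_truth == {}

    def test_class_histogram_matches_request(self):
        cfg = SimulationConfig(seed=1, n_genes=40, n_peaks_shared=10,
                               n_peaks_tf1_specific=5, n_peaks_tf2_specific=5,
                               n_background=5)
        peaks, truth = generate_peak_landscape(cfg, generate_annotation(cfg))
        assert len(peaks) == 25
        hist = pd.Series(truth.peak_class_truth).value_counts().to_dict()
        assert hist == {"shared": 10, "tf1_specific": 5, "tf2_specific": 5,
                        "background": 5}

    def test_no_two_peaks_overlap_brute_force(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        peaks, _ = generate_peak_landscape(cfg, generate_annotation(cfg))
        ivs = sorted(peaks, key=lambda p: (p.chrom, p.start))
        for a, b in zip(ivs, ivs[1:]):
            assert a.chrom != b.chrom or b.start >= a.end

    def test_planted_locations_agree_with_annotator(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        ann = generate_annotation(cfg)
        peaks, truth = generate_peak_landscape(cfg, ann)
        assert annotate_location(peaks, ann) == truth.peak_location

    def test_truth_ids_resolve_in_dataset(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        peaks, truth = generate_peak_landscape(cfg, generate_annotation(cfg))
        universe = set(peaks.ids)
        assert set(truth.peak_class_truth) == universe
        assert truth.accessible_ids <= universe
        assert truth.compensated_ids <= universe
        assert all(
            truth.peak_class_truth[p] == "tf1_specific" for p in truth.compensated_ids)


class TestTagCounts:
    def test_deterministic_and_seed_sensitive(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        ann = generate_annotation(cfg)
        peaks, truth = generate_peak_landscape(cfg, ann)
        t1 = simulate_tag_counts(peaks, truth, cfg)
        t2 = simulate_tag_counts(peaks, truth, cfg)
        pd.testing.assert_frame_equal(t1[("tf1", "WT")].data, t2[("tf1", "WT")].data)
        cfg_b = SimulationConfig(seed=8, **SMALL)
        peaks_b, truth_b = generate_peak_landscape(cfg_b, generate_annotation(cfg_b))
        t3 = simulate_tag_counts(peaks_b, truth_b, cfg_b)
        assert not t1[("tf1", "WT")].data.equals(t3[("tf1", "WT")].data)

    def test_unit_effect_fold_means_symmetric_factors(self):
        cfg = SimulationConfig(effect_fold=1.0, dispersion=0.0)
        for cls in ("shared", "tf1_specific", "tf2_specific"):
            m1 = _chip_mean(cfg, "tf1", "WT", cls, compensated=False)
            m2 = _chip_mean(cfg, "tf2", "WT", cls, compensated=False)
            assert m1 == m2 == cfg.mean_depth

    def test_planted_mean_realized_within_five_percent(self):
        cfg = SimulationConfig(seed=11)  # 2,000 peaks
        ann = generate_annotation(cfg)
        peaks, truth = generate_peak_landscape(cfg, ann)
        tables = simulate_tag_counts(peaks, truth, cfg)
        shared = [p for p, c in truth.peak_class_truth.items() if c == "shared"]
        observed = tables[("tf1", "WT")].data.loc[shared].to_numpy().mean()
        assert observed == pytest.approx(cfg.mean_depth, rel=0.05)

    def test_effect_ratio_converges_at_low_dispersion(self):
        cfg = SimulationConfig(seed=13, dispersion=0.0)
        ann = generate_annotation(cfg)
        peaks, truth = generate_peak_landscape(cfg, ann)
        tables = simulate_tag_counts(peaks, truth, cfg)
        spec = [p for p, c in truth.peak_class_truth.items() if c == "tf1_specific"]
        tf1 = tables[("tf1", "WT")].data.loc[spec].to_numpy().mean()
        tf2 = tables[("tf2", "WT")].data.loc[spec].to_numpy().mean()
        assert tf1 / tf2 == pytest.approx(cfg.effect_fold, rel=0.05)

    def test_binding_null_genotype_drops_factor_one_to_background(self):
        cfg = SimulationConfig(seed=13, dispersion=0.0)
        ann = generate_annotation(cfg)
        peaks, truth = generate_peak_landscape(cfg, ann)
        tables = simulate_tag_counts(peaks, truth, cfg)
        shared = [p for p, c in truth.peak_class_truth.items() if c == "shared"]
        mut = tables[("tf1", "mutA")].data.loc[shared].to_numpy().mean()
        assert mut == pytest.approx(cfg.background_depth, rel=0.1)

    def test_empty_universe_rejected(self):
        from tfpair import PeakSet, SyntheticTruth

        cfg = SimulationConfig(n_peaks_shared=0, n_peaks_tf1_specific=0,
                               n_peaks_tf2_specific=0, n_background=0)
        with pytest.raises(ValueError, match="empty"):
            simulate_tag_counts(PeakSet([]), SyntheticTruth(), cfg)

    def test_atac_counts_track_accessibility(self):
        cfg = SimulationConfig(seed=17, dispersion=0.0, **SMALL)
        ann = generate_annotation(cfg)
        peaks, truth = generate_peak_landscape(cfg, ann)
        atac = simulate_atac_counts(peaks, truth, cfg)
        wt_cols = [c for c in atac.sample_ids if c.startswith("atac_WT_")]
        open_mean = atac.data.loc[sorted(truth.accessible_ids), wt_cols].to_numpy().mean()
        closed = sorted(set(peaks.ids) - truth.accessible_ids)
        closed_mean = atac.data.loc[closed, wt_cols].to_numpy().mean()
        assert open_mean == pytest.approx(cfg.mean_depth, rel=0.1)
        assert closed_mean == pytest.approx(cfg.background_depth, rel=0.3)


class TestSequences:
    @pytest.fixture
    def planted(self):
        cfg = SimulationConfig(seed=19, **SMALL)
        ann = generate_annotation(cfg)
        peaks, truth = generate_peak_landscape(cfg, ann)
        pwm = gc_box_pwm()
        seqs = generate_sequences_with_motifs(peaks, truth, [pwm], cfg)
        return cfg, peaks, truth, pwm, seqs

    def test_zero_planted_peaks_contain_no_consensus(self, planted):
        _cfg, _peaks, truth, pwm, seqs = planted
        empty = [p for p, pl in truth.motif_placements.items() if not pl]
        assert empty, "expected some peaks without planted instances"
        rc = reverse_complement(pwm.consensus)
        for pid in empty:
            assert pwm.consensus not in seqs[pid]
            assert rc not in seqs[pid]

    def test_forward_placements_match_by_slicing(self, planted):
        _cfg, _peaks, truth, pwm, seqs = planted
        checked = 0
        for pid, placements in truth.motif_placements.items():
            for off, strand, _name in placements:
                if strand == "+":
                    assert seqs[pid][off : off + len(pwm)] == pwm.consensus
                    checked += 1
        assert checked > 0

    def test_reverse_placements_are_reverse_complements(self, planted):
        _cfg, _peaks, truth, pwm, seqs = planted
        rc = reverse_complement(pwm.consensus)
        checked = 0
        for pid, placements in truth.motif_placements.items():
            for off, strand, _name in placements:
                if strand == "-":
                    assert seqs[pid][off : off + len(pwm)] == rc
                    checked += 1
        assert checked > 0

    def test_planted_instances_never_overlap(self, planted):
        _cfg, _peaks, truth, pwm, _seqs = planted
        for placements in truth.motif_placements.values():
            offsets = sorted(off for off, _s, _n in placements)
            assert all(b - a >= len(pwm) for a, b in zip(offsets, offsets[1:]))

    def test_impossible_packing_is_capacity_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="pack"):
            _plant_offsets(rng, n=30, seq_len=100, motif_len=10)

    def test_motif_longer_than_peak_rejected(self):
        cfg = SimulationConfig(seed=19, peak_width=8, **SMALL)
        ann = generate_annotation(cfg)
        peaks, truth = generate_peak_landscape(cfg, ann)
        with pytest.raises(ValueError, match="shorter"):
            generate_sequences_with_motifs(peaks, truth, [gc_box_pwm()], cfg)


class TestExpressionSimulation:
    def test_all_unchanged_zero_noise_means_mutants_equal_wt(self):
        cfg = SimulationConfig(
            seed=23, n_genes=30,
            group_proportions=(0.0,) * 8 + (1.0,), expression_noise_sd=0.0)
        expr, _ = simulate_expression(generate_annotation(cfg), cfg)
        for stage in cfg.stages:
            wt = expr.mean_expression(stage, "WT")
            for mut in ("mutA", "mutB"):
                assert np.allclose(expr.mean_expression(stage, mut), wt)

    def test_planted_group_realizes_exact_fold(self):
        # group 2 = up in mutant A only
        cfg = SimulationConfig(
            seed=29, n_genes=30, expression_fold=4.0, expression_noise_sd=0.0,
            group_proportions=(0.0, 1.0) + (0.0,) * 7)
        expr, truth = simulate_expression(generate_annotation(cfg), cfg)
        assert set(truth.gene_group_truth.values()) == {2}
        wt = expr.mean_expression("HE1", "WT")
        assert np.allclose(expr.mean_expression("HE1", "mutA") / wt, 4.0)
        assert np.allclose(expr.mean_expression("HE1", "mutB") / wt, 1.0)

    def test_group_histogram_matches_proportions(self):
        cfg = SimulationConfig(seed=31, n_chroms=10, chrom_length=3_000_000,
                               n_genes=5_000)
        expr, truth = simulate_expression(generate_annotation(cfg), cfg)
        groups = pd.Series(truth.gene_group_truth)
        for g in range(1, 9):
            frac = (groups == g).mean()
            assert frac == pytest.approx(0.03, abs=0.01)  # ~4 sigma multinomial
        assert (groups == 0).mean() == pytest.approx(0.76, abs=0.02)

    def test_single_replicate_rejected(self):
        cfg = SimulationConfig(n_replicates=1)
        with pytest.raises(ValueError, match="replicates"):
            simulate_expression(generate_annotation(cfg), cfg)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=37, n_genes=30)
        ann = generate_annotation(cfg)
        a, _ = simulate_expression(ann, cfg)
        b, _ = simulate_expression(ann, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestSingleCellSimulation:
    def test_minimum_cell_count_enforced(self):
        with pytest.raises(ValueError, match=">= 20"):
            simulate_single_cells(SimulationConfig(n_cells_per_genotype=5))

    def test_linear_noiseless_first_pc_orders_cells_by_time(self):
        cfg = SimulationConfig(seed=41, trajectory_topology="linear", sc_noise=0.0,
                               extra_cluster_in_mutant=False, n_cells_per_genotype=150)
        cells, truth = simulate_single_cells(cfg)
        pre = preprocess_cells(cells["WT"])
        coords, _ = reduce_and_cluster(pre, k=2, d=5, seed=0)
        t = pd.Series(truth.cell_time_truth).loc[pre.cell_ids]
        rho = stats.spearmanr(coords["PC1"], t).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_no_extra_cluster_means_identical_cluster_sets(self):
        cfg = SimulationConfig(seed=43, extra_cluster_in_mutant=False,
                               n_cells_per_genotype=80)
        _, truth = simulate_single_cells(cfg)
        by_genotype = {}
        for cid, cl in truth.cell_cluster_truth.items():
            by_genotype.setdefault(cid.split("_")[0], set()).add(cl)
        (a, b) = by_genotype.values()
        assert a == b

    def test_bifurcating_topology_has_three_branch_labels(self):
        cfg = SimulationConfig(seed=47, extra_cluster_in_mutant=False,
                               n_cells_per_genotype=80)
        _, truth = simulate_single_cells(cfg)
        assert set(truth.cell_branch_truth.values()) == {
            "trunk", "branch_A", "branch_B"}

    def test_extra_cluster_only_in_mutant(self):
        cfg = SimulationConfig(seed=53, n_cells_per_genotype=80)
        _, truth = simulate_single_cells(cfg)
        extra = {cid for cid, cl in truth.cell_cluster_truth.items() if cl == "extra"}
        assert extra and all(cid.startswith("mutA_") for cid in extra)

    def test_truth_ids_resolve_in_matrices(self):
        cfg = SimulationConfig(seed=59, n_cells_per_genotype=60)
        cells, truth = simulate_single_cells(cfg)
        all_cells = set().union(*(set(cm.cell_ids) for cm in cells.values()))
        assert set(truth.cell_time_truth) == all_cells
        assert set(truth.cell_branch_truth) == all_cells
        assert set(truth.cell_cluster_truth) == all_cells

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=61, n_cells_per_genotype=60)
        a, _ = simulate_single_cells(cfg)
        b, _ = simulate_single_cells(cfg)
        pd.testing.assert_frame_equal(a["WT"].values, b["WT"].values)
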