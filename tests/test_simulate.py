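"""Synthetic-data generator: determinism, moment structure, truth consistency."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from factorialseq import io as fio
from factorialseq.intervals import count_sites_per_gene, tile_windows
from factorialseq.motifs import bundled_pwms, reverse_complement
from factorialseq.simulate import (
    CONDITIONS,
    SimConfig,
    classify_effect,
    expected_integration_class,
    simulate_annotation,
    simulate_counts,
    simulate_sequences,
    window_truth,
    write_fixtures,
)


class TestAnnotation:
    def test_zero_genes_still_generates_peaks(self):
        sc = SimConfig(seed=1, n_genes=0, n_peaks=20, chrom_lengths={"chr1": 500_000})
        genes, peaks, sites, acc, dhs, truth = simulate_annotation(sc)
        assert len(genes) == 0 and len(peaks) == 20 and len(sites) == 0

    def test_same_seed_identical(self, small_config, tmp_path):
        outs = []
        for sub in ("a", "b"):
            genes, peaks, sites, acc, dhs, truth = simulate_annotation(small_config)
            gc, gd = simulate_counts(truth.genes, small_config.replicates, small_config, stage="rna-counts")
            seqs, plantings = simulate_sequences(dhs, small_config.pwm_set, small_config)
            write_fixtures(tmp_path / sub, genes, peaks, sites, acc, dhs, truth,
                           {"rna": (gc, gd)}, sequences=seqs, plantings=plantings)
            outs.append(tmp_path / sub)
        files = sorted(p.name for p in outs[0].iterdir())
        assert files == sorted(p.name for p in outs[1].iterdir())
        for f in files:
            assert filecmp.cmp(outs[0] / f, outs[1] / f, shallow=False), f

    def test_genes_non_overlapping_and_sorted(self, small_config):
        genes, *_ = simulate_annotation(small_config)
        for _, g in genes.groupby("chrom"):
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()
        assert set(genes["strand"]) <= {"+", "-"}

    def test_peak_minimum_length(self, small_config):
        _, peaks, *_ = simulate_annotation(small_config)
        assert ((peaks["end"] - peaks["start"]) >= 200).all()

    def test_dense_gene_site_count_verified_by_independent_recount(self, small_config):
        genes, peaks, sites, acc, dhs, truth = simulate_annotation(small_config)
        recount = count_sites_per_gene(sites, genes)
        dense = truth.genes[truth.genes["n_binding_sites"] > 10]
        assert len(dense) == small_config.n_high_binding_genes
        for g in dense.index:
            assert recount[g] == truth.genes.loc[g, "n_binding_sites"] == small_config.sites_per_high_gene

    def test_chrom_too_small_raises(self):
        sc = SimConfig(seed=1, n_genes=500, n_peaks=10, chrom_lengths={"chr1": 10_000})
        with pytest.raises(ValueError, match="too small"):
            simulate_annotation(sc)

    def test_accessibility_labels_known_cell_types(self, small_config):
        *_, truth = simulate_annotation(small_config)
        assert set(truth.peaks["accessibility_class"]) <= {
            "pan-accessible", "enterocyte-specific", "ISC-specific",
            "enterocyte-restricted", "ISC-restricted", "other"}


class TestEffectClasses:
    def test_truth_labels_rederivable_from_betas(self, small_config):
        *_, truth = simulate_annotation(small_config)
        assert truth.consistent()

    @pytest.mark.parametrize(
        "bm,bf,bi,expected",
        [(0, 0, 0, "null"), (1.5, 0, 0, "microbe-only"), (0, -2, 0, "meal-only"),
         (1, 1, 0, "additive"), (0, 0, 2, "interaction-positive"), (0, 2, -2, "interaction-negative")],
    )
    def test_classify_effect(self, bm, bf, bi, expected):
        assert classify_effect(bm, bf, bi) == expected

    def test_integration_class_red_blue(self):
        assert expected_integration_class(0, 0, 2) == "red"
        assert expected_integration_class(0, 2, -2) == "blue"
        assert expected_integration_class(0, 0, 0) == "none"
        # additive patterns can still match the definitions:
        # microbe-up + meal-up -> up with meal given microbes AND up with
        # microbes given meal = red; microbe-down + meal-up = blue
        assert expected_integration_class(1, 1, 0) == "red"
        assert expected_integration_class(-1, 1, 0) == "blue"
        # microbe-up + meal-down: dual-responsive but neither pattern
        assert expected_integration_class(1, -1, 0) == "other-dual"


class TestCounts:
    def test_poisson_mean_recovered(self):
        sc = SimConfig(seed=2, library_size_range=(1.0, 1.0))
        truth = pd.DataFrame(
            {"beta_microbes": 0.0, "beta_meal": 0.0, "beta_interaction": 0.0,
             "base_mean": 50.0, "alpha": 1e-12},
            index=[f"f{i}" for i in range(1000)])
        counts, design = simulate_counts(truth, {c: 1 for c in CONDITIONS}, sc)
        means = counts.mean(axis=1)
        grand = means.mean()
        se = np.sqrt(50 / (1000 * len(design.columns) if hasattr(design, "columns") else 4))
        se = np.sqrt(50 / (1000 * 4))
        assert abs(grand - 50) < 3 * se

    def test_interaction_ratio_of_ratios(self):
        sc = SimConfig(seed=3, library_size_range=(1.0, 1.0))
        n = 2000
        truth = pd.DataFrame(
            {"beta_microbes": 0.0, "beta_meal": 0.0, "beta_interaction": 2.0,
             "base_mean": 200.0, "alpha": 0.01},
            index=[f"f{i}" for i in range(n)])
        counts, design = simulate_counts(truth, {c: 2 for c in CONDITIONS}, sc)
        d = design.set_index("sample")
        def cell_mean(cond):
            cols = [s for s in counts.columns if s.startswith(cond.replace("+", "p") + "_")]
            return counts[cols].to_numpy().mean()
        ratio = (cell_mean("CV+HFM") / cell_mean("CV")) / (cell_mean("GF+HFM") / cell_mean("GF"))
        assert 3.8 < ratio < 4.2

    def test_same_seed_identical_matrix(self):
        sc = SimConfig(seed=4)
        truth = pd.DataFrame(
            {"beta_microbes": 0.5, "beta_meal": 0.0, "beta_interaction": 0.0,
             "base_mean": 100.0, "alpha": 0.05},
            index=[f"f{i}" for i in range(50)])
        c1, _ = simulate_counts(truth, sc.replicates, sc)
        c2, _ = simulate_counts(truth, sc.replicates, sc)
        pd.testing.assert_frame_equal(c1, c2)

    def test_nonfinite_mean_rejected(self):
        sc = SimConfig(seed=4)
        truth = pd.DataFrame(
            {"beta_microbes": np.inf, "beta_meal": 0.0, "beta_interaction": 0.0,
             "base_mean": 100.0, "alpha": 0.05}, index=["f0"])
        with pytest.raises(ValueError, match="non-finite"):
            simulate_counts(truth, sc.replicates, sc)

    def test_nb_moment_structure(self):
        # pooled within-cell sample variance ~ mu + alpha mu^2 across 2000 features
        sc = SimConfig(seed=6, library_size_range=(1.0, 1.0))
        mu, alpha = 100.0, 0.1
        truth = pd.DataFrame(
            {"beta_microbes": 0.0, "beta_meal": 0.0, "beta_interaction": 0.0,
             "base_mean": mu, "alpha": alpha},
            index=[f"f{i}" for i in range(2000)])
        counts, design = simulate_counts(truth, {c: 5 for c in CONDITIONS}, sc)
        v = counts.var(axis=1, ddof=1).mean()
        expect = mu + alpha * mu**2
        assert abs(v - expect) / expect < 0.1

    def test_unbalanced_replicate_layout(self):
        sc = SimConfig(seed=7)
        truth = pd.DataFrame({"beta_microbes": 0.0, "beta_meal": 0.0, "beta_interaction": 0.0,
                              "base_mean": 50.0, "alpha": 0.05}, index=["f0"])
        counts, design = simulate_counts(truth, sc.chip_replicates, sc)
        assert counts.shape == (1, 2 + 5 + 2 + 5)
        cond = design.groupby(["microbes", "meal"]).size()
        assert cond[("CV", "HFM")] == 5 and cond[("GF", "none")] == 2


class TestSequences:
    def _regions(self, n, length):
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * (length + 10),
             "end": np.arange(n) * (length + 10) + length,
             "name": [f"r{i}" for i in range(n)], "score": 0.0, "strand": "."})

    def test_no_planting_by_default(self):
        sc = SimConfig(seed=8)
        pwm = bundled_pwms()[0]
        seqs, planted = simulate_sequences(self._regions(30, 300), [pwm], sc)
        assert len(planted) == 0
        consensus = pwm.consensus
        occurrences = sum(consensus in s or reverse_complement(consensus) in s for s in seqs.values())
        assert occurrences == 0  # a 13-mer is vanishingly unlikely in 9 kb of background

    def test_forced_plant_fills_whole_region(self):
        sc = SimConfig(seed=9)
        pwm = bundled_pwms()[0]
        regions = self._regions(5, len(pwm))
        seqs, planted = simulate_sequences(regions, [pwm], sc, plant_in={f"r{i}" for i in range(5)})
        for s in seqs.values():
            assert s in (pwm.consensus, reverse_complement(pwm.consensus))
        assert len(planted) == 5

    def test_motif_longer_than_region_rejected(self):
        sc = SimConfig(seed=9)
        pwm = bundled_pwms()[0]
        regions = self._regions(1, len(pwm) - 1)
        with pytest.raises(ValueError, match="longer than region"):
            simulate_sequences(regions, [pwm], sc, plant_in={"r0"})

    def test_gc_content_of_background(self):
        sc = SimConfig(seed=10, gc_content=0.5)
        regions = self._regions(1, 100_000)
        seqs, _ = simulate_sequences(regions, [], sc)
        s = seqs["r0"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.49 <= gc <= 0.51


class TestWindowTruth:
    def test_windows_inherit_parent_effects(self, small_config):
        genes, peaks, *_ , truth = simulate_annotation(small_config)
        windows = tile_windows(peaks)
        wt = window_truth(windows, truth.peaks, small_config)
        assert len(wt) == len(windows)
        for wname, row in wt.sample(10, random_state=0).iterrows():
            parent = truth.peaks.loc[row["parent_peak"]]
            assert row["beta_interaction"] == parent["beta_interaction"]
            assert row["class"] == parent["class"]


class TestFixtureRoundTrip:
    def test_bed_line_format(self, tmp_path):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [400]})
        fio.write_bed(df, tmp_path / "x.bed", n_fields=3)
        assert (tmp_path / "x.bed").read_text() == "chr1\t100\t400\n"

    def test_counts_tsv_shape(self, tmp_path):
        counts = pd.DataFrame(np.arange(12).reshape(3, 4),
                              index=["f1", "f2", "f3"], columns=["a", "b", "c", "d"])
        fio.write_counts(counts, tmp_path / "c.tsv")
        lines = (tmp_path / "c.tsv").read_text().strip().split("\n")
        assert len(lines) == 4 and len(lines[1].split("\t")) == 5
        back = fio.read_counts(tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(back, counts)

    def test_interval_round_trip(self, tmp_path, interval_factory, rng):
        df = interval_factory(rng, 50)
        fio.write_bed(df, tmp_path / "iv.bed")
        back = fio.read_bed(tmp_path / "iv.bed")
        pd.testing.assert_frame_equal(back[["chrom", "start", "end", "name"]],
                                      df[["chrom", "start", "end", "name"]])

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"r1": "ACGTACGT", "r2": "GGGCCCAT"}
        fio.write_fasta(seqs, tmp_path / "s.fa")
        assert fio.read_fasta(tmp_path / "s.fa") == seqs

    def test_full_fixture_round_trip(self, small_config, tmp_path):
        genes, peaks, sites, acc, dhs, truth = simulate_annotation(small_config)
        gc, gd = simulate_counts(truth.genes, small_config.replicates, small_config)
        manifest = write_fixtures(tmp_path, genes, peaks, sites, acc, dhs, truth, {"rna": (gc, gd)})
        back_genes = fio.read_bed(manifest["genes"])
        pd.testing.assert_frame_equal(back_genes, genes)
        back_counts = fio.read_counts(manifest["counts_rna"])
        pd.testing.assert_frame_equal(back_counts, gc, check_names=False)
        sheet = fio.read_sample_sheet(manifest["samples_rna"])
        assert list(sheet["sample"]) == list(gc.columns)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        sc = SimConfig(effect_fractions={"null": 0.5, "microbe-only": 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            sc.validate()

    def test_replicates_must_cover_conditions(self):
        sc = SimConfig(replicates={"GF": 4})
        with pytest.raises(ValueError, match="conditions"):
            sc.validate()
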