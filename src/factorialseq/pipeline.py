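"""End-to-end orchestration: simulate (or ingest) -> differential testing ->
window-to-peak joining -> directional grouping -> integration and
accessibility classification -> gene linkage -> motif enrichment ->
ordination statistics.

Every stage writes plain TSV/BED artifacts under the run directory and the
run ends with a JSON manifest recording the seed, per-table row counts and
file paths.  Given the same config (including seed) the outputs are
byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import nbglm
from .classify import (
    assign_directional_groups,
    classify_accessibility,
    classify_integration,
    overlap_matrix,
)
from .intervals import (
    bin_genes_by_site_count,
    count_sites_per_gene,
    join_windows_to_peaks,
    nearest_feature,
    tile_windows,
)
from .motifs import bundled_pwms, read_pwms, run_reciprocal_enrichment
from .sample_stats import euclidean_distance, log_normal_matrix, pca_counts, permanova
from .simulate import (
    SimConfig,
    simulate_annotation,
    simulate_counts,
    simulate_sequences,
    stage_rng,
    window_truth,
    write_fixtures,
)

log = logging.getLogger("factorialseq")


@dataclass
class PipelineConfig:
    """Run configuration: exactly one of ``simulate`` / ``inputs`` drives the run."""

    out_dir: str = "run"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    thresholds: nbglm.Thresholds = field(default_factory=nbglm.Thresholds)
    window_width: int = 300
    window_step: int = 200
    dhs_max_dist: int = 1000
    motif_min_sequences: int = 5
    pwm_file: str | None = None
    n_top: int = 500
    n_perm: int = 999

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        thr = raw.pop("thresholds", {})
        window = raw.pop("window", {})
        linkage = raw.pop("linkage", {})
        motif = raw.pop("motif", {})
        stats = raw.pop("stats", {})
        cfg = cls(
            out_dir=raw.pop("out_dir", "run"),
            seed=int(raw.pop("seed", 0)),
            simulate=raw.pop("simulate", None),
            inputs=raw.pop("inputs", None),
            thresholds=nbglm.Thresholds(**thr),
            window_width=int(window.get("width", 300)),
            window_step=int(window.get("step", 200)),
            dhs_max_dist=int(linkage.get("dhs_max_dist", 1000)),
            motif_min_sequences=int(motif.get("min_sequences", 5)),
            pwm_file=motif.get("pwm_file"),
            n_top=int(stats.get("n_top", 500)),
            n_perm=int(stats.get("n_perm", 999)),
        )
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' and 'inputs' must be configured")
        if self.window_step > self.window_width:
            raise ValueError("window width must be >= step")
        for v in (self.thresholds.padj, self.thresholds.lenient_gene_p, self.thresholds.lenient_window_p):
            if not 0 < v <= 1:
                raise ValueError("p-value thresholds must be in (0, 1]")


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(fio.read_config(path))


def validate_inputs(paths: dict) -> list[str]:
    """Sanity-check input files; returns a list of fatal findings."""
    findings = []
    for key in ("gene_counts", "gene_samples"):
        if key not in paths:
            findings.append(f"missing required input: {key}")
    if findings:
        return findings
    try:
        counts = fio.read_counts(paths["gene_counts"])
        sheet = fio.read_sample_sheet(paths["gene_samples"])
        missing = set(counts.columns) - set(sheet["sample"])
        if missing:
            findings.append(f"samples in counts missing from sheet: {sorted(missing)}")
    except Exception as exc:  # surfaced, not swallowed: validation is the product here
        findings.append(str(exc))
    for key in ("peaks", "genes", "binding_sites", "dhs"):
        if key in paths:
            try:
                fio.read_bed(paths[key])
            except Exception as exc:
                findings.append(f"{key}: {exc}")
    return findings


def _flagged(result: pd.DataFrame, flag: str) -> pd.DataFrame:
    out = result[["baseMean", "log2FC", "SE", "p", "padj"]].copy()
    out["significant"] = result[flag].astype(bool)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    config.validate()
    out = fio.ensure_dir(config.out_dir)
    results_dir = fio.ensure_dir(out / "results")
    manifest: dict = {"seed": config.seed, "artifacts": {}, "row_counts": {}}

    def save(name: str, df: pd.DataFrame, index_label="feature"):
        path = results_dir / f"{name}.tsv"
        fio.write_table(df, path, index_label=index_label)
        manifest["artifacts"][name] = str(path.relative_to(out))
        manifest["row_counts"][name] = int(len(df))

    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sc = SimConfig(**sim_kwargs)
            genes, peaks, binding_sites, accessibility, dhs, truth = simulate_annotation(sc)
            gene_counts, gene_design = simulate_counts(truth.genes, sc.replicates, sc, stage="rna-counts")
            windows = tile_windows(peaks, config.window_width, config.window_step)
            wtruth = window_truth(windows, truth.peaks, sc)
            window_counts, chip_design = simulate_counts(wtruth, sc.chip_replicates, sc, stage="chip-counts")
            rng = stage_rng(sc.seed, "plant-select")
            blue_peaks = truth.peaks.index[truth.peaks["integration_class"] == "blue"]
            chosen = [p for p in blue_peaks if rng.random() < sc.motif_plant_rate]
            plant_in = {f"dhs_{p}" for p in chosen}
            pwms = sc.pwm_set
            sequences, plantings = simulate_sequences(dhs, pwms, sc, plant_in=plant_in)
            fixtures = write_fixtures(
                out / "fixtures", genes, peaks, binding_sites, accessibility, dhs, truth,
                {"rna": (gene_counts, gene_design), "chip": (window_counts, chip_design)},
                sequences=sequences, plantings=plantings,
            )
            fio.write_bed(windows.assign(name=windows["name"]), out / "fixtures" / "windows.bed")
            fixtures["windows"] = str(out / "fixtures" / "windows.bed")
            manifest["fixtures"] = {k: str(Path(v).relative_to(out)) for k, v in fixtures.items()}
        else:
            stage = "ingest"
            paths = config.inputs
            findings = validate_inputs(paths)
            if findings:
                raise ValueError("input validation failed: " + "; ".join(findings))
            gene_counts = fio.read_counts(paths["gene_counts"])
            gene_design = fio.read_sample_sheet(paths["gene_samples"])
            genes = fio.read_bed(paths["genes"]) if "genes" in paths else None
            peaks = fio.read_bed(paths["peaks"]) if "peaks" in paths else None
            binding_sites = fio.read_bed(paths["binding_sites"]) if "binding_sites" in paths else None
            dhs = fio.read_bed(paths["dhs"]) if "dhs" in paths else None
            accessibility = {
                ct: fio.read_bed(p) for ct, p in paths.get("accessibility", {}).items()
            }
            windows = tile_windows(peaks, config.window_width, config.window_step) if peaks is not None else None
            window_counts = fio.read_counts(paths["window_counts"]) if "window_counts" in paths else None
            chip_design = fio.read_sample_sheet(paths["window_samples"]) if "window_samples" in paths else None
            sequences = fio.read_fasta(paths["sequences"]) if "sequences" in paths else None
            pwms = read_pwms(config.pwm_file) if config.pwm_file else bundled_pwms()

        stage = "differential-genes"
        log.info("differential testing: %d genes", len(gene_counts))
        gene_results = nbglm.run_differential(gene_counts, gene_design, config.thresholds)
        for name, res in gene_results.items():
            save(f"genes_{_slug(name)}", res)
            log.info("genes %s: %d standard-significant", name, int(res["sig_standard"].sum()))

        peak_tables = {}
        window_results = None
        if window_counts is not None:
            stage = "differential-windows"
            log.info("differential testing: %d windows", len(window_counts))
            window_results = nbglm.run_differential(window_counts, chip_design, config.thresholds)
            for name, res in window_results.items():
                save(f"windows_{_slug(name)}", res)
            stage = "join"
            for name in nbglm.CONTRASTS:
                flag = "sig_lenient_window" if name == "interaction" else "sig_standard"
                joined = join_windows_to_peaks(_flagged(window_results[name], flag), windows)
                peak_tables[name] = joined
                save(f"peaks_{_slug(name)}", joined, index_label="peak")
                log.info("peaks %s: %d significant", name, int(joined["significant"].sum()))

        stage = "classify"
        gene_groups = assign_directional_groups(
            {c: gene_results[c] for c in nbglm.CONTRASTS if c != "interaction"}, flag="sig_standard"
        )
        save("gene_groups", gene_groups)
        counts_m, norm_m = overlap_matrix(gene_groups)
        save("gene_overlap_counts", counts_m, index_label="group")
        save("gene_overlap_normalized", norm_m, index_label="group")
        peak_groups = None
        if peak_tables:
            peak_groups = assign_directional_groups(
                {c: peak_tables[c] for c in nbglm.CONTRASTS if c != "interaction"}, flag="significant"
            )
            save("peak_groups", peak_groups, index_label="peak")
            counts_m, norm_m = overlap_matrix(peak_groups)
            save("peak_overlap_counts", counts_m, index_label="group")
            save("peak_overlap_normalized", norm_m, index_label="group")
            integration = classify_integration(peak_groups)
            save("peak_integration", integration, index_label="peak")
            log.info(
                "integration classes: %s",
                integration["integration_class"].value_counts().to_dict(),
            )
        if peaks is not None and accessibility:
            acc = classify_accessibility(peaks, accessibility)
            save("peak_accessibility", acc, index_label="peak")

        stage = "annotate"
        if peaks is not None and genes is not None and len(genes):
            near = nearest_feature(peaks, genes)
            save("peak_nearest_gene", near, index_label=None)
        if binding_sites is not None and genes is not None and len(genes):
            spg = count_sites_per_gene(binding_sites, genes)
            spg_df = spg.to_frame()
            spg_df["site_bin"] = bin_genes_by_site_count(spg)
            save("sites_per_gene", spg_df, index_label="gene")

        stage = "motifs"
        if peak_groups is not None and dhs is not None and sequences:
            links = nearest_feature(peaks, dhs, max_dist=config.dhs_max_dist)
            enr = run_reciprocal_enrichment(
                peak_groups, links, sequences, pwms, min_sequences=config.motif_min_sequences
            )
            for grp, table in enr.items():
                save(f"motifs_{_slug(grp)}", table, index_label=None)

        stage = "stats"
        for assay, (cts, des) in (("rna", (gene_counts, gene_design)),) + (
            (("chip", (window_counts, chip_design)),) if window_counts is not None else ()
        ):
            sf = nbglm.estimate_size_factors(cts)
            ord_res = pca_counts(cts, sf, n_top=config.n_top)
            save(f"pca_{assay}_coordinates", ord_res.coordinates, index_label="sample")
            save(
                f"pca_{assay}_variance",
                pd.DataFrame(
                    {"PC": [f"PC{i+1}" for i in range(len(ord_res.variance_explained))],
                     "variance_explained": ord_res.variance_explained}
                ),
                index_label=None,
            )
            D = euclidean_distance(log_normal_matrix(cts, sf, n_top=config.n_top))
            design = nbglm.validate_design(cts, des)
            rows = []
            for factor in ("microbes", "meal"):
                res = permanova(D, design[factor].to_numpy(), n_perm=config.n_perm,
                                seed=config.seed, factor=factor)
                rows.append({"factor": factor, "pseudo_F": res.pseudo_f, "R2": res.r2,
                             "p": res.p, "n_perm": res.n_perm})
            save(f"permanova_{assay}", pd.DataFrame(rows), index_label=None)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _slug(name: str) -> str:
    return name.replace("/", "_vs_").replace("+", "p").replace("|", "_")
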