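"""Synthetic factorial genomics data with known ground truth.

Emulates the study design the pipeline targets: a 2x2 factorial of
microbiota colonization (GF vs CV) and a single high-fat meal (none vs HFM),
with gene-level RNA counts, chromatin windows tiled over merged peaks,
transcription-factor binding sites clustered near a subset of genes,
per-cell-type accessibility labels, and accessible-site sequences with
planted motifs.

Counts follow a negative-binomial mean model

    mu_ij = s_j * q_i * 2 ** (bm * x_j + bf * y_j + bi * x_j * y_j)

with variance mu + alpha * mu^2; ``bi`` is the interaction log2 fold change,
the log2 ratio of (CV+HFM/CV) / (GF+HFM/GF) (positive when the meal response
is stronger with microbes present).  Effect classes plant:

- ``interaction-positive``: bi > 0, bm = bf = 0 — meal response only with
  microbes; recoverable as a "red" integration-class region.
- ``interaction-negative``: bi < 0 with bf = -bi — meal response only
  without microbes plus microbial suppression of the fed state; recoverable
  as "blue".

All randomness flows from a single seed; each stage derives its own child
stream deterministically, so identical configs give byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .intervals import as_intervals, nearest_feature
from .motifs import PWM, bundled_pwms, reverse_complement

CONDITIONS = ("GF", "GF+HFM", "CV", "CV+HFM")
EFFECT_CLASSES = (
    "null",
    "microbe-only",
    "meal-only",
    "additive",
    "interaction-positive",
    "interaction-negative",
)
CELL_TYPES = ("ISC", "TA", "EEC", "enterocyte")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Replicate defaults mirror the unbalanced designs of the emulated assays:
    RNA 4/4/4/4, chromatin-mark (H3K27ac-style) 2/5/2/5 and TF-binding
    (HNF4A-style) 3/4/3/4 per condition, all configurable.
    """

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_000_000})
    n_genes: int = 300
    n_peaks: int = 300
    replicates: dict = field(default_factory=lambda: {c: 4 for c in CONDITIONS})
    chip_replicates: dict = field(
        default_factory=lambda: {"GF": 2, "GF+HFM": 5, "CV": 2, "CV+HFM": 5}
    )
    tf_replicates: dict = field(default_factory=lambda: {"GF": 3, "GF+HFM": 4, "CV": 3, "CV+HFM": 4})
    effect_fractions: dict = field(
        default_factory=lambda: {
            "null": 0.55,
            "microbe-only": 0.10,
            "meal-only": 0.10,
            "additive": 0.10,
            "interaction-positive": 0.075,
            "interaction-negative": 0.075,
        }
    )
    effect_size_log2: tuple = (2.0, 0.5)  # (mean, sd) of |effect| magnitudes
    base_mean_log_range: tuple = (20.0, 2000.0)  # log-uniform range for q_i
    dispersion_params: tuple = (0.02, 1.0)  # alpha(mu) = a0 + a1/mu
    library_size_range: tuple = (0.7, 1.4)
    motif_plant_rate: float = 0.5
    gc_content: float = 0.45
    gene_length_range: tuple = (2000, 8000)
    peak_length_range: tuple = (200, 1500)
    n_high_binding_genes: int = 10
    sites_per_high_gene: int = 12
    dhs_width: int = 200
    pwm_set: list = field(default_factory=bundled_pwms)

    def validate(self) -> None:
        if abs(sum(self.effect_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("effect_fractions must sum to 1")
        if set(self.effect_fractions) - set(EFFECT_CLASSES):
            raise ValueError(f"unknown effect class in {sorted(self.effect_fractions)}")
        for reps in (self.replicates, self.chip_replicates, self.tf_replicates):
            if set(reps) != set(CONDITIONS):
                raise ValueError(f"replicates must name exactly the conditions {CONDITIONS}")
            if any(r < 1 for r in reps.values()):
                raise ValueError("every condition needs >= 1 replicate")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes < 0 or self.n_peaks < 0:
            raise ValueError("feature counts must be non-negative")
        if not 0.0 <= self.motif_plant_rate <= 1.0:
            raise ValueError("motif_plant_rate must be in [0, 1]")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage child stream of the global seed."""
    digest = sum(ord(c) * 31**i for i, c in enumerate(stage)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), digest]))


def classify_effect(bm: float, bf: float, bi: float, tol: float = 1e-12) -> str:
    """Effect class implied by the planted log2 effects (inverse of the planting rules)."""
    has_m, has_f, has_i = abs(bm) > tol, abs(bf) > tol, abs(bi) > tol
    if has_i:
        return "interaction-positive" if bi > 0 else "interaction-negative"
    if has_m and has_f:
        return "additive"
    if has_m:
        return "microbe-only"
    if has_f:
        return "meal-only"
    return "null"


def expected_integration_class(bm: float, bf: float, bi: float, tol: float = 1e-12) -> str:
    """Integration class a perfect detector would assign from the true effects.

    Contrast effects are CV/GF = bm, GF+HFM/GF = bf, CV+HFM/CV = bf + bi,
    CV+HFM/GF+HFM = bm + bi; "red" = up with meal given microbes and up with
    microbes given meal; "blue" = up with meal germ-free and down with
    microbes given meal.
    """
    cv_gf, hfm_gf = bm, bf
    cvhfm_cv, cvhfm_gfhfm = bf + bi, bm + bi
    sig = lambda x: abs(x) > tol
    dual = (sig(cv_gf) or sig(cvhfm_gfhfm)) and (sig(hfm_gf) or sig(cvhfm_cv))
    if sig(cvhfm_cv) and cvhfm_cv > 0 and sig(cvhfm_gfhfm) and cvhfm_gfhfm > 0:
        return "red"
    if sig(hfm_gf) and hfm_gf > 0 and sig(cvhfm_gfhfm) and cvhfm_gfhfm < 0:
        return "blue"
    return "other-dual" if dual else "none"


def _draw_effects(cls: str, rng: np.random.Generator, mean: float, sd: float):
    mag = lambda: abs(rng.normal(mean, sd)) + 1e-6
    sign = lambda: rng.choice([-1.0, 1.0])
    if cls == "null":
        return 0.0, 0.0, 0.0
    if cls == "microbe-only":
        return sign() * mag(), 0.0, 0.0
    if cls == "meal-only":
        return 0.0, sign() * mag(), 0.0
    if cls == "additive":
        return sign() * mag(), sign() * mag(), 0.0
    if cls == "interaction-positive":
        return 0.0, 0.0, mag()
    if cls == "interaction-negative":
        m = mag()
        return 0.0, m, -m
    raise ValueError(cls)


def _feature_truth(n: int, prefix: str, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = list(config.effect_fractions)
    probs = np.array([config.effect_fractions[c] for c in classes])
    labels = rng.choice(classes, size=n, p=probs)
    mean, sd = config.effect_size_log2
    lo, hi = config.base_mean_log_range
    q = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    a0, a1 = config.dispersion_params
    columns = ["class", "beta_microbes", "beta_meal", "beta_interaction",
               "base_mean", "alpha", "integration_class"]
    if n == 0:
        return pd.DataFrame(columns=columns).rename_axis("feature")
    rows = []
    for i in range(n):
        bm, bf, bi = _draw_effects(labels[i], rng, mean, sd)
        alpha = a0 + a1 / q[i]
        rows.append(
            {
                "feature": f"{prefix}_{i:05d}",
                "class": labels[i],
                "beta_microbes": bm,
                "beta_meal": bf,
                "beta_interaction": bi,
                "base_mean": q[i],
                "alpha": alpha,
                "integration_class": expected_integration_class(bm, bf, bi),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def _place_features(n: int, lengths, config: SimConfig, rng: np.random.Generator, min_gap: int = 500):
    """Place n non-overlapping intervals across chromosomes, left to right."""
    chroms = sorted(config.chrom_lengths)
    capacity = sum(config.chrom_lengths[c] for c in chroms)
    need = int(np.sum(lengths) + (n + len(chroms)) * min_gap)
    if need > capacity:
        raise ValueError(
            f"chromosomes too small: need ~{need} bp for {n} features, have {capacity} bp"
        )
    per_chrom = np.array_split(np.arange(n), len(chroms))
    rows = []
    for chrom, idx in zip(chroms, per_chrom):
        pos = min_gap
        limit = config.chrom_lengths[chrom]
        for i in idx:
            gap = int(rng.integers(min_gap, 3 * min_gap))
            start = pos + gap
            end = start + int(lengths[i])
            if end > limit:
                raise ValueError(f"chromosome {chrom} too small for the requested features")
            rows.append((chrom, start, end, i))
            pos = end
    return rows


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for recovery testing."""

    genes: pd.DataFrame
    peaks: pd.DataFrame
    config: SimConfig

    def consistent(self) -> bool:
        """Re-derive class labels from the stored effects and compare."""
        for table in (self.genes, self.peaks):
            for _, row in table.iterrows():
                if classify_effect(row["beta_microbes"], row["beta_meal"], row["beta_interaction"]) != row["class"]:
                    return False
                if (
                    expected_integration_class(
                        row["beta_microbes"], row["beta_meal"], row["beta_interaction"]
                    )
                    != row["integration_class"]
                ):
                    return False
        return True


def simulate_annotation(config: SimConfig):
    """Simulate gene models, merged peaks, binding sites, accessibility sets.

    Returns (genes, peaks, binding_sites, accessibility, dhs, truth) where
    accessibility maps cell type -> interval set and dhs holds one accessible
    site per peak (centered inside it) for sequence-level analyses.
    """
    config.validate()
    rng = stage_rng(config.seed, "annotation")

    gene_truth = _feature_truth(config.n_genes, "gene", config, rng)
    peak_truth = _feature_truth(config.n_peaks, "peak", config, rng)

    glo, ghi = config.gene_length_range
    gene_lengths = rng.integers(glo, ghi + 1, size=config.n_genes)
    gene_rows = _place_features(config.n_genes, gene_lengths, config, rng)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = pd.DataFrame(
        [
            (chrom, start, end, f"gene_{i:05d}", 0.0, strands[i])
            for chrom, start, end, i in gene_rows
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    genes = as_intervals(genes) if len(genes) else as_intervals(pd.DataFrame(columns=["chrom", "start", "end"]))

    plo, phi = config.peak_length_range
    peak_lengths = rng.integers(max(plo, 200), phi + 1, size=config.n_peaks)
    peak_rows = _place_features(config.n_peaks, peak_lengths, config, rng, min_gap=800)
    peaks = as_intervals(
        pd.DataFrame(
            [(chrom, start, end, f"peak_{i:05d}") for chrom, start, end, i in peak_rows],
            columns=["chrom", "start", "end", "name"],
        )
        if peak_rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )

    # nearest gene per peak (ground truth for linkage recovery)
    if len(genes) and len(peaks):
        near = nearest_feature(peaks, genes).set_index("query")
        peak_truth["nearest_gene"] = [near.loc[p, "reference"] if p in near.index else "" for p in peak_truth.index]
        peak_truth["nearest_gene_distance"] = [
            int(near.loc[p, "distance"]) if p in near.index else -1 for p in peak_truth.index
        ]
    else:
        peak_truth["nearest_gene"] = ""
        peak_truth["nearest_gene_distance"] = -1

    # TF binding sites: a configurable subset of genes gets a dense cluster
    # (> 10 sites inside the gene body, so each site's nearest gene is exact);
    # the rest get 0-3 scattered sites.
    site_rows = []
    gene_truth["n_binding_sites"] = 0
    if len(genes):
        order = rng.permutation(len(genes))
        dense = set(order[: min(config.n_high_binding_genes, len(genes))])
        for gi in range(len(genes)):
            g = genes.iloc[gi]
            k = config.sites_per_high_gene if gi in dense else int(rng.integers(0, 4))
            width = 20
            if k > 0:
                starts = rng.integers(g["start"], max(g["end"] - width, g["start"] + 1), size=k)
                for s in sorted(starts):
                    site_rows.append((g["chrom"], int(s), int(s) + width, f"site_{len(site_rows):05d}"))
            gene_truth.loc[g["name"], "n_binding_sites"] = k
    binding_sites = as_intervals(
        pd.DataFrame(site_rows, columns=["chrom", "start", "end", "name"])
        if site_rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )

    # accessibility: draw a cell-type pattern per peak; the labelled interval
    # is the peak footprint itself in each accessible cell type's set
    patterns = {
        "pan-accessible": [set(CELL_TYPES)],
        "enterocyte-specific": [{"enterocyte"}],
        "ISC-specific": [{"ISC"}],
        "enterocyte-restricted": [{"enterocyte", "TA"}, {"enterocyte", "EEC"}, {"enterocyte", "TA", "EEC"}],
        "ISC-restricted": [{"ISC", "TA"}, {"ISC", "EEC"}, {"ISC", "TA", "EEC"}],
        "other": [{"TA"}, {"EEC"}, {"TA", "EEC"}, set()],
    }
    label_names = list(patterns)
    label_probs = np.array([0.25, 0.15, 0.15, 0.1, 0.1, 0.25])
    acc_rows = {ct: [] for ct in CELL_TYPES}
    labels = []
    for pi in range(len(peaks)):
        lab = rng.choice(label_names, p=label_probs)
        variant = patterns[lab][int(rng.integers(0, len(patterns[lab])))]
        labels.append(lab)
        p = peaks.iloc[pi]
        for ct in variant:
            acc_rows[ct].append((p["chrom"], p["start"], p["end"], f"{ct}_{p['name']}"))
    peak_truth["accessibility_class"] = labels if len(peaks) else []
    accessibility = {
        ct: as_intervals(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
            if rows
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
        for ct, rows in acc_rows.items()
    }

    # one accessible (DHS-like) site per peak, centered inside it
    dhs_rows = []
    for pi in range(len(peaks)):
        p = peaks.iloc[pi]
        mid = (p["start"] + p["end"]) // 2
        half = config.dhs_width // 2
        s = max(p["start"], mid - half)
        e = min(p["end"], mid + half)
        dhs_rows.append((p["chrom"], s, e, f"dhs_{p['name']}"))
    dhs = as_intervals(
        pd.DataFrame(dhs_rows, columns=["chrom", "start", "end", "name"])
        if dhs_rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    peak_truth["dhs"] = [f"dhs_{p}" for p in peak_truth.index] if len(peaks) else []

    truth = SimTruth(genes=gene_truth, peaks=peak_truth, config=config)
    return genes, peaks, binding_sites, accessibility, dhs, truth


def sample_layout(replicates: dict[str, int]) -> pd.DataFrame:
    """Sample sheet for a replicate map: ids like CVpHFM_2, factors microbes/meal."""
    rows = []
    for cond in CONDITIONS:
        for r in range(1, replicates[cond] + 1):
            microbes = "CV" if cond.startswith("CV") else "GF"
            meal = "HFM" if cond.endswith("+HFM") else "none"
            rows.append({"sample": f"{cond.replace('+', 'p')}_{r}", "microbes": microbes, "meal": meal})
    return pd.DataFrame(rows)


def simulate_counts(
    truth_table: pd.DataFrame,
    replicates: dict[str, int],
    config: SimConfig,
    stage: str = "counts",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts for every feature in ``truth_table`` under the factorial design.

    Returns (counts, sample sheet).  Library size factors are drawn
    log-uniformly from ``config.library_size_range`` per sample.
    """
    rng = stage_rng(config.seed, stage)
    design = sample_layout(replicates)
    x = (design["microbes"] == "CV").to_numpy(float)
    y = (design["meal"] == "HFM").to_numpy(float)
    lo, hi = config.library_size_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(design)))
    q = truth_table["base_mean"].to_numpy()[:, None]
    bm = truth_table["beta_microbes"].to_numpy()[:, None]
    bf = truth_table["beta_meal"].to_numpy()[:, None]
    bi = truth_table["beta_interaction"].to_numpy()[:, None]
    alpha = truth_table["alpha"].to_numpy()[:, None]
    mu = s[None, :] * q * 2.0 ** (bm * x[None, :] + bf * y[None, :] + bi * (x * y)[None, :])
    if not np.isfinite(mu).all():
        raise ValueError("non-finite NB mean; check the planted effects and base means")
    counts = np.empty(mu.shape, dtype=np.int64)
    poisson_like = alpha < 1e-8
    counts[np.broadcast_to(poisson_like, mu.shape)] = rng.poisson(mu[np.broadcast_to(poisson_like, mu.shape)])
    nb_mask = np.broadcast_to(~poisson_like, mu.shape)
    if nb_mask.any():
        a = np.broadcast_to(alpha, mu.shape)[nb_mask]
        m = mu[nb_mask]
        r = 1.0 / a
        counts[nb_mask] = rng.negative_binomial(r, r / (r + m))
    return (
        pd.DataFrame(counts, index=truth_table.index, columns=list(design["sample"])),
        design,
    )


def window_truth(windows: pd.DataFrame, peak_truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-window truth: windows inherit their parent peak's effects; the base
    mean is split across the peak's windows with mild jitter."""
    rng = stage_rng(config.seed, "window-truth")
    rows = []
    a0, a1 = config.dispersion_params
    for w in windows.itertuples(index=False):
        parent = peak_truth.loc[w.parent_peak]
        q = parent["base_mean"] * float(rng.uniform(0.8, 1.2))
        rows.append(
            {
                "feature": w.name,
                "parent_peak": w.parent_peak,
                "class": parent["class"],
                "beta_microbes": parent["beta_microbes"],
                "beta_meal": parent["beta_meal"],
                "beta_interaction": parent["beta_interaction"],
                "base_mean": q,
                "alpha": a0 + a1 / q,
                "integration_class": parent["integration_class"],
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def simulate_sequences(
    regions: pd.DataFrame,
    pwms: list[PWM],
    config: SimConfig,
    plant_in: set[str] | None = None,
    plant_pwm: PWM | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Background sequences for ``regions`` with motif consensus plantings.

    Background bases are iid with the configured GC content.  Regions named
    in ``plant_in`` receive one planted consensus of ``plant_pwm`` (default:
    the first configured PWM) at a random position and strand, recorded in
    the returned planting table.
    """
    rng = stage_rng(config.seed, "sequences")
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.array(list("ACGT"))
    plant_in = plant_in or set()
    plant_pwm = plant_pwm or (pwms[0] if pwms else None)
    seqs = {}
    planted = []
    for row in regions.itertuples(index=False):
        length = row.end - row.start
        seq = "".join(bases[rng.choice(4, size=length, p=probs)])
        if row.name in plant_in:
            if plant_pwm is None or len(plant_pwm) > length:
                raise ValueError(f"motif longer than region {row.name}")
            consensus = plant_pwm.consensus
            pos = int(rng.integers(0, length - len(consensus) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = consensus if strand == "+" else reverse_complement(consensus)
            seq = seq[:pos] + insert + seq[pos + len(insert):]
            planted.append({"region": row.name, "motif": plant_pwm.name, "position": pos, "strand": strand})
        seqs[row.name] = seq
    return seqs, pd.DataFrame(planted, columns=["region", "motif", "position", "strand"])


def write_fixtures(out_dir, genes, peaks, binding_sites, accessibility, dhs, truth,
                   counts_by_assay: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
                   sequences: dict[str, str] | None = None,
                   plantings: pd.DataFrame | None = None) -> dict[str, str]:
    """Write every simulated object in the pipeline's input formats.

    Returns a manifest mapping artifact name -> file path.  Everything
    round-trips losslessly through the readers in :mod:`factorialseq.io`.
    """
    out = fio.ensure_dir(out_dir)
    manifest = {}

    def _bed(name, df):
        path = out / f"{name}.bed"
        fio.write_bed(df, path)
        manifest[name] = str(path)

    _bed("genes", genes)
    _bed("peaks", peaks)
    _bed("binding_sites", binding_sites)
    _bed("dhs", dhs)
    for ct, df in accessibility.items():
        _bed(f"accessibility_{ct}", df)
    for assay, (counts, design) in counts_by_assay.items():
        cpath = out / f"counts_{assay}.tsv"
        spath = out / f"samples_{assay}.tsv"
        fio.write_counts(counts, cpath)
        fio.write_sample_sheet(design, spath)
        manifest[f"counts_{assay}"] = str(cpath)
        manifest[f"samples_{assay}"] = str(spath)
    for name, table in (("truth_genes", truth.genes), ("truth_peaks", truth.peaks)):
        path = out / f"{name}.tsv"
        fio.write_table(table, path, index_label="feature")
        manifest[name] = str(path)
    if sequences is not None:
        path = out / "sequences.fa"
        fio.write_fasta(sequences, path)
        manifest["sequences"] = str(path)
    if plantings is not None:
        path = out / "motif_plantings.tsv"
        fio.write_table(plantings, path)
        manifest["motif_plantings"] = str(path)
    cfg = asdict(truth.config)
    cfg.pop("pwm_set", None)
    fio.write_config(cfg, out / "sim_config.yaml")
    manifest["sim_config"] = str(out / "sim_config.yaml")
    return manifest
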