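"""Readers and writers for the pipeline's plain-text formats.

BED (0-based half-open), FASTA (via Biopython), TSV count matrices with a
feature-id index column, sample sheets (sample, microbes, meal), and simple
YAML config files.  All writers produce deterministic byte output for a
given input (fixed column order, fixed float formatting).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import BED_COLUMNS, as_intervals

FLOAT_FORMAT = "%.6g"


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a canonical interval frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with < 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else f"iv_{lineno:06d}"
            score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return as_intervals(pd.DataFrame(rows, columns=BED_COLUMNS))


def write_bed(intervals: pd.DataFrame, path, n_fields: int = 6) -> None:
    df = as_intervals(intervals)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fields = [row.chrom, str(row.start), str(row.end), str(row.name), FLOAT_FORMAT % row.score, row.strand]
            fh.write("\t".join(fields[:n_fields]) + "\n")


def read_counts(path) -> pd.DataFrame:
    """Read a TSV count matrix (first column = feature id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "microbes", "meal"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return df


def write_sample_sheet(design: pd.DataFrame, path) -> None:
    df = design.reset_index() if "sample" not in design.columns else design
    df[["sample", "microbes", "meal"]].to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    """Deterministic TSV writer for result tables."""
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label, float_format=FLOAT_FORMAT)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
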