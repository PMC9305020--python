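"""PWM scanning and motif enrichment with reciprocal-direction backgrounds.

Motifs are position probability matrices scanned as log2-odds scores against
a background base composition; a window is a hit when its score reaches the
motif's bit threshold, on either strand.  Enrichment uses ZOOPS counting
(a sequence either has >= 1 hit or it does not) and a hypergeometric upper
tail for the number of hit-bearing input sequences drawn from the pooled
input + background set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PSEUDOCOUNT = 0.001
DEFAULT_THRESHOLD_FRACTION = 0.6


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix over A, C, G, T.

    ``matrix`` is L x 4 base probabilities (rows sum to 1).  The log-odds
    threshold defaults to ``threshold_fraction`` of the maximum achievable
    score given the background.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_bits: float | None = None
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must be at least 4 positions long")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        self.background = np.asarray(self.background, float)
        self.background = self.background / self.background.sum()

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = (self.matrix + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT)
        return np.log2(p / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def threshold(self) -> float:
        if self.threshold_bits is not None:
            return self.threshold_bits
        return self.threshold_fraction * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def scan_pwm(sequence: str, pwm: PWM) -> list[tuple[int, str, float]]:
    """All hits of ``pwm`` in ``sequence`` on both strands.

    Returns (position on the forward strand, strand, bits) tuples; windows
    containing a non-ACGT base are skipped; sequences shorter than the motif
    yield no hits.  Minus-strand positions refer to the forward-strand start
    of the matched window.
    """
    L = len(pwm)
    enc = _encode(sequence)
    n = len(enc) - L + 1
    if n <= 0:
        return []
    lo = pwm.log_odds
    lo_rc = lo[::-1, ::-1]  # reverse complement: reverse positions, A<->T, C<->G
    hits = []
    thr = pwm.threshold
    idx = np.arange(L)
    valid = enc >= 0
    ok_window = np.all(np.lib.stride_tricks.sliding_window_view(valid, L), axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    for pos in np.nonzero(ok_window)[0]:
        w = windows[pos]
        s_fwd = float(lo[idx, w].sum())
        if s_fwd >= thr:
            hits.append((int(pos), "+", s_fwd))
        s_rev = float(lo_rc[idx, w].sum())
        if s_rev >= thr:
            hits.append((int(pos), "-", s_rev))
    return hits


def has_hit(sequence: str, pwm: PWM) -> bool:
    return len(scan_pwm(sequence, pwm)) > 0


def enrich(
    input_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[PWM],
) -> pd.DataFrame:
    """Per-motif ZOOPS hypergeometric enrichment of input vs background.

    For a motif with k1 of n1 input sequences and k2 of n2 background
    sequences carrying >= 1 hit, the p value is the hypergeometric upper
    tail P(X >= k1) for X ~ Hypergeom(N=n1+n2, K=k1+k2, n=n1).  Fold
    enrichment is (k1/n1) / (k2/n2) (infinite when the background rate is 0
    and the input rate is not).
    """
    if not input_seqs or not background_seqs:
        raise ValueError("both the input and the background sequence sets must be non-empty")
    rows = []
    n1, n2 = len(input_seqs), len(background_seqs)
    for pwm in pwms:
        k1 = sum(has_hit(s, pwm) for s in input_seqs.values())
        k2 = sum(has_hit(s, pwm) for s in background_seqs.values())
        if k1 + k2 == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k1 - 1, n1 + n2, k1 + k2, n1))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rate_in = k1 / n1
        rate_bg = k2 / n2
        fold = np.inf if (rate_bg == 0 and rate_in > 0) else (rate_in / rate_bg if rate_bg > 0 else np.nan)
        rows.append(
            {
                "motif": pwm.name,
                "input_hits": k1,
                "input_total": n1,
                "background_hits": k2,
                "background_total": n2,
                "fold_enrichment": fold,
                "p": p,
                "neg_log10_p": -np.log10(p),
            }
        )
    return pd.DataFrame(rows).sort_values("neg_log10_p", ascending=False).reset_index(drop=True)


OPPOSITE = {"up": "down", "down": "up"}
MIN_GROUP_SEQUENCES = 5


def run_reciprocal_enrichment(
    groups: pd.DataFrame,
    region_links: pd.DataFrame,
    sequences: dict[str, str],
    pwms: list[PWM],
    min_sequences: int = MIN_GROUP_SEQUENCES,
) -> dict[str, pd.DataFrame]:
    """Motif enrichment for each directional group against its reciprocal.

    ``groups`` is a boolean frame indexed by region with one column per
    directional group ``<contrast>|up`` / ``<contrast>|down``;
    ``region_links`` maps region -> linked sequence id (columns ``query``,
    ``reference``, e.g. the nearest accessible site within 1 kb).  For every
    contrast, the up group's linked sequences are tested against the down
    group's and vice versa; a contrast whose two direction groups do not both
    reach ``min_sequences`` linked sequences is skipped.
    """
    link = region_links.set_index("query")["reference"]

    def seqs_for(col: str) -> dict[str, str]:
        regions = groups.index[groups[col]]
        out = {}
        for r in regions:
            sid = link.get(r)
            if sid is not None and sid in sequences:
                out[sid] = sequences[sid]  # dedup by sequence/region id
        return out

    results = {}
    contrasts = sorted({c.rsplit("|", 1)[0] for c in groups.columns})
    for contrast in contrasts:
        per_dir = {d: seqs_for(f"{contrast}|{d}") for d in ("up", "down")}
        if any(len(per_dir[d]) < min_sequences for d in per_dir):
            import warnings

            warnings.warn(f"contrast {contrast}: a direction group has < {min_sequences} linked sequences; pair skipped")
            continue
        for d in ("up", "down"):
            results[f"{contrast}|{d}"] = enrich(per_dir[d], per_dir[OPPOSITE[d]], pwms)
    return results


def read_pwms(path) -> list[PWM]:
    """Read PWMs from a text file: '>name' header lines, then L rows x 4 probabilities."""
    pwms = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(PWM(name=name, matrix=np.array(rows)))
                name, rows = line[1:].split()[0], []
            else:
                rows.append([float(x) for x in line.split()])
    if name is not None:
        pwms.append(PWM(name=name, matrix=np.array(rows)))
    return pwms


def write_pwms(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def _consensus_pwm(name: str, consensus: str, p: float = 0.97) -> PWM:
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, _BASE_INDEX[b]] = p
    return PWM(name=name, matrix=mat)


def bundled_pwms() -> list[PWM]:
    """A small built-in motif set for testing: nuclear-receptor-like DR1
    half-site repeats (HNF4A- and PPARA-style), a CRE-like palindrome, and a
    GC-rich control."""
    return [
        _consensus_pwm("NR_DR1_HNF4", "AGGTCAAAGGTCA"),
        _consensus_pwm("NR_DR1_PPAR", "AGGTCAAAGTTCA"),
        _consensus_pwm("CRE_PALINDROME", "TGACGTCA"),
        _consensus_pwm("GC_CONTROL", "GGGCGGGG"),
    ]
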