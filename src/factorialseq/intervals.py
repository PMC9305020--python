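"""Genomic interval algebra on BED-convention tables.

All coordinates are 0-based, half-open ``[start, end)``.  Interval sets are
plain :class:`pandas.DataFrame` objects with columns ``chrom``, ``start``,
``end`` and optionally ``name``, ``score``, ``strand``; helper functions
below guarantee the canonical column set and sort order
``(chrom, start, end, name)``.

Distance conventions: overlapping intervals have distance 0; bookended
intervals (``a.end == b.start``) also have distance 0; otherwise the
distance is the length in bp of the gap between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def make_intervals(records, names=None) -> pd.DataFrame:
    """Build a canonical interval frame from (chrom, start, end[, ...]) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "start", "end"][: len(records[0])] if records else ["chrom", "start", "end"])
    return as_intervals(df, names=names)


def as_intervals(df: pd.DataFrame, names=None) -> pd.DataFrame:
    """Coerce a frame to the canonical column set, validate, and sort."""
    df = df.copy()
    if "name" not in df.columns:
        df["name"] = [f"iv_{i:06d}" for i in range(len(df))] if names is None else list(names)
    elif names is not None:
        df["name"] = list(names)
    if "score" not in df.columns:
        df["score"] = 0.0
    if "strand" not in df.columns:
        df["strand"] = "."
    df = df[BED_COLUMNS]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if len(df):
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"interval with start >= end at row {bad}")
        if (df["chrom"].astype(str) == "").any():
            raise ValueError("empty chromosome name")
    return sort_intervals(df)


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end", "name"], kind="mergesort").reset_index(drop=True)


def total_bp(df: pd.DataFrame) -> int:
    """Total bp covered, counting overlaps once."""
    merged = merge_intervals([df])
    return int((merged["end"] - merged["start"]).sum()) if len(merged) else 0


def merge_intervals(sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of interval sets; overlapping or bookended intervals coalesce."""
    frames = [s for s in sets if s is not None and len(s)]
    if not frames:
        return as_intervals(pd.DataFrame(columns=["chrom", "start", "end"]))
    allv = sort_intervals(pd.concat([f[["chrom", "start", "end"]].assign(name="", score=0.0, strand=".") for f in frames]))
    out = []
    cur = None
    for chrom, start, end in zip(allv["chrom"], allv["start"], allv["end"]):
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                out.append(tuple(cur))
            cur = [chrom, start, end]
    if cur is not None:
        out.append(tuple(cur))
    res = pd.DataFrame(out, columns=["chrom", "start", "end"])
    res["name"] = [f"merged_{i:06d}" for i in range(len(res))]
    return as_intervals(res)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Set difference a \\ b; intervals in ``a`` may be split by ``b``."""
    if a is None or not len(a):
        return as_intervals(pd.DataFrame(columns=["chrom", "start", "end"]))
    if b is None or not len(b):
        return as_intervals(a)
    bm = merge_intervals([b])
    pieces = []
    by_chrom = {c: g for c, g in bm.groupby("chrom")}
    for row in a.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            pieces.append((row.chrom, row.start, row.end, row.name))
            continue
        pos = row.start
        for bs, be in zip(sub["start"], sub["end"]):
            if be <= pos:
                continue
            if bs >= row.end:
                break
            if bs > pos:
                pieces.append((row.chrom, pos, bs, row.name))
            pos = max(pos, be)
            if pos >= row.end:
                break
        if pos < row.end:
            pieces.append((row.chrom, pos, row.end, row.name))
    res = pd.DataFrame(pieces, columns=["chrom", "start", "end", "name"])
    return as_intervals(res)


def tile_windows(peaks: pd.DataFrame, width: int = 300, step: int = 200) -> pd.DataFrame:
    """Tile each peak with sliding windows.

    A peak shorter than ``width`` yields a single window spanning the whole
    peak.  Otherwise full-width windows start at offsets 0, step, 2*step, ...
    while they fit, plus one end-anchored window ``[end-width, end)`` when the
    last regular window does not reach the peak end, so every bp of the peak
    is covered.  Window names are ``<parent_peak>:<index>``.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if step > width:
        raise ValueError("step must be <= width")
    rows = []
    for row in peaks.itertuples(index=False):
        length = row.end - row.start
        if length <= width:
            starts = [row.start]
        else:
            starts = list(range(row.start, row.end - width + 1, step))
            if starts[-1] + width < row.end:
                starts.append(row.end - width)
        for i, s in enumerate(starts):
            rows.append((row.chrom, s, min(s + width, row.end), f"{row.name}:{i}", row.name))
    res = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "parent_peak"])
    out = as_intervals(res[["chrom", "start", "end", "name"]])
    parent = res.set_index("name")["parent_peak"]
    out["parent_peak"] = out["name"].map(parent)
    return out


def count_overlaps(fragments: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Per-target count of fragments overlapping by >= 1 bp."""
    counts = np.zeros(len(targets), dtype=np.int64)
    if not len(fragments) or not len(targets):
        return counts
    tpos = {c: idx for c, idx in targets.groupby("chrom").groups.items()}
    for chrom, frag in fragments.groupby("chrom"):
        idx = tpos.get(chrom)
        if idx is None:
            continue
        fs = np.sort(frag["start"].to_numpy())
        fe = np.sort(frag["end"].to_numpy())
        tsub = targets.loc[idx]
        # overlap iff fragment.start < target.end and fragment.end > target.start
        n_start_before = np.searchsorted(fs, tsub["end"].to_numpy(), side="left")
        n_end_at_or_before = np.searchsorted(fe, tsub["start"].to_numpy(), side="right")
        counts[np.asarray(idx, dtype=int)] += n_start_before - n_end_at_or_before
    return counts


def count_overlaps_matrix(fragment_sets: dict[str, pd.DataFrame], targets: pd.DataFrame) -> pd.DataFrame:
    """Count matrix of fragments overlapping each target, one column per sample.

    A fragment overlapping k (possibly overlapping) targets contributes to all
    k of them.  Fragments on chromosomes absent from the targets count nowhere.
    """
    data = {}
    target_chroms = set(targets["chrom"]) if len(targets) else set()
    for sample, frags in fragment_sets.items():
        if len(frags) and not set(frags["chrom"]) & target_chroms and target_chroms:
            import warnings

            warnings.warn(f"sample {sample}: no fragment chromosome matches the targets")
        data[sample] = count_overlaps(frags, targets)
    return pd.DataFrame(data, index=list(targets["name"]))


def has_overlap(query: pd.DataFrame, reference: pd.DataFrame) -> pd.Series:
    """Boolean per query interval: overlaps >= 1 bp with any reference interval."""
    return pd.Series(count_overlaps(reference, query) > 0, index=query["name"].to_numpy())


def nearest_feature(query: pd.DataFrame, reference: pd.DataFrame, max_dist: int | None = None) -> pd.DataFrame:
    """Assign each query interval to its nearest reference feature.

    Distance is the bp gap between the interval bodies (0 when overlapping or
    bookended).  Ties go to the reference feature first in
    (chrom, start, end, name) sort order.  The signed distance is positive
    when the reference lies downstream (to the right) of the query, negative
    upstream.  Queries with no same-chromosome reference are dropped, as are
    assignments farther than ``max_dist`` when given.
    """
    if not len(reference):
        raise ValueError("reference interval set is empty")
    ref = sort_intervals(reference)
    out = []
    for chrom, q in query.groupby("chrom"):
        r = ref[ref["chrom"] == chrom]
        if not len(r):
            continue
        rs = r["start"].to_numpy()[None, :]
        re_ = r["end"].to_numpy()[None, :]
        qs = q["start"].to_numpy()[:, None]
        qe = q["end"].to_numpy()[:, None]
        gap_right = np.maximum(rs - qe, 0)      # reference downstream
        gap_left = np.maximum(qs - re_, 0)      # reference upstream
        dist = np.maximum(gap_right, gap_left)  # one of the two is 0
        best = np.argmin(dist, axis=1)          # argmin takes the first min: sort-order tie rule
        rows = np.arange(len(q))
        signed = np.where(gap_right[rows, best] > 0, dist[rows, best], -dist[rows, best])
        for qi, bi, sd in zip(range(len(q)), best, signed):
            out.append((q["name"].iloc[qi], r["name"].iloc[bi], int(sd)))
    res = pd.DataFrame(out, columns=["query", "reference", "distance"])
    if max_dist is not None:
        res = res[res["distance"].abs() <= max_dist].reset_index(drop=True)
    return res


def count_sites_per_gene(sites: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Number of sites whose nearest gene is each gene; genes without sites get 0."""
    assigned = nearest_feature(sites, genes, max_dist=None)
    counts = assigned["reference"].value_counts()
    return pd.Series([int(counts.get(g, 0)) for g in genes["name"]], index=list(genes["name"]), name="n_sites")


DEFAULT_SITE_BINS = ((0, 0, "0"), (1, 4, "1-4"), (5, 10, "5-10"), (11, None, ">10"))


def bin_genes_by_site_count(counts: pd.Series, bins=DEFAULT_SITE_BINS) -> pd.Series:
    """Bin per-gene site counts into labelled categories (default 0 / 1-4 / 5-10 / >10)."""
    edges = sorted(bins, key=lambda b: b[0])
    for prev, nxt in zip(edges, edges[1:]):
        if prev[1] is None or nxt[0] <= prev[1]:
            raise ValueError("overlapping or unordered bin edges")
    def label(c):
        for lo, hi, lab in edges:
            if c >= lo and (hi is None or c <= hi):
                return lab
        raise ValueError(f"count {c} falls outside the configured bins")
    return counts.map(label).rename("site_bin")


def join_windows_to_peaks(window_results: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-window test results to their parent peaks.

    A peak is significant for the contrast iff >= 1 of its windows carries the
    significance flag; its representative statistics (log2FC, SE, p, padj,
    baseMean) come from the window with the smallest p value, ties broken by
    the leftmost window.  ``window_results`` must be indexed by window name and
    carry columns baseMean, log2FC, SE, p, padj, significant.
    """
    wmap = windows.set_index("name")
    missing = [w for w in window_results.index if w not in wmap.index]
    if missing:
        raise KeyError(f"window result with no matching window: {missing[0]}")
    res = window_results.copy()
    res["parent_peak"] = [wmap.loc[w, "parent_peak"] for w in res.index]
    res["_start"] = [wmap.loc[w, "start"] for w in res.index]
    rows = []
    for peak, grp in res.groupby("parent_peak", sort=True):
        grp = grp.sort_values(["p", "_start"], kind="mergesort")
        rep = grp.iloc[0]
        rows.append(
            {
                "peak": peak,
                "baseMean": rep["baseMean"],
                "log2FC": rep["log2FC"],
                "SE": rep["SE"],
                "p": rep["p"],
                "padj": rep["padj"],
                "significant": bool(grp["significant"].any()),
                "n_windows": len(grp),
                "representative_window": rep.name,
            }
        )
    return pd.DataFrame(rows).set_index("peak")
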