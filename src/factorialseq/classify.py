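"""Directional significance groups and downstream feature classification.

Each of the four pairwise contrasts (CV/GF, CV+HFM/GF+HFM, GF+HFM/GF,
CV+HFM/CV) splits its significant features by log2FC sign into an up and a
down group — 8 directional groups in total.  Features significant in at
least one +microbes (+CV) and one +meal (+HFM) contrast are
"dual-responsive"; among those, regions up with the meal in the colonized
state and up with microbes in the fed state are "red", regions up with the
meal germ-free and down with microbes in the fed state are "blue".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import has_overlap

PAIRWISE_CONTRASTS = ("CV/GF", "CV+HFM/GF+HFM", "GF+HFM/GF", "CV+HFM/CV")
PLUS_CV = ("CV/GF", "CV+HFM/GF+HFM")
PLUS_HFM = ("GF+HFM/GF", "CV+HFM/CV")
GROUPS = tuple(f"{c}|{d}" for c in PAIRWISE_CONTRASTS for d in ("up", "down"))


def assign_directional_groups(
    results: dict[str, pd.DataFrame], flag: str = "significant"
) -> pd.DataFrame:
    """Boolean membership of every feature in the 8 directional groups.

    ``results`` maps contrast name -> per-feature table with columns
    ``log2FC`` and the boolean significance column named by ``flag``.
    Features flagged significant with log2FC exactly 0 cannot be oriented
    and are excluded (with a warning).
    """
    missing = [c for c in PAIRWISE_CONTRASTS if c not in results]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")
    index = results[PAIRWISE_CONTRASTS[0]].index
    out = pd.DataFrame(False, index=index, columns=list(GROUPS))
    for contrast in PAIRWISE_CONTRASTS:
        r = results[contrast].reindex(index)
        sig = r[flag].fillna(False).astype(bool)
        lfc = r["log2FC"]
        zero = sig & (lfc == 0)
        if zero.any():
            warnings.warn(f"{contrast}: {int(zero.sum())} flagged feature(s) with log2FC = 0 excluded")
        out[f"{contrast}|up"] = sig & (lfc > 0)
        out[f"{contrast}|down"] = sig & (lfc < 0)
    return out


def overlap_matrix(groups: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise coincidence of the 8 groups: raw |g & h| and |g & h| / min(|g|, |h|).

    The normalized value ("maximum overlap") is 0, flagged by convention,
    when either group is empty.
    """
    cols = list(groups.columns)
    m = groups.to_numpy(bool)
    inter = m.T.astype(int) @ m.astype(int)
    sizes = m.sum(axis=0)
    counts = pd.DataFrame(inter, index=cols, columns=cols)
    mins = np.minimum.outer(sizes, sizes)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(mins > 0, inter / np.maximum(mins, 1), 0.0)
    return counts, pd.DataFrame(norm, index=cols, columns=cols)


def classify_integration(groups: pd.DataFrame) -> pd.DataFrame:
    """Red / blue / other-dual / none class per feature.

    red  = CV+HFM/CV-up  and CV+HFM/GF+HFM-up
    blue = GF+HFM/GF-up  and CV+HFM/GF+HFM-down
    dual-responsive = significant in >= 1 +CV contrast and >= 1 +HFM
    contrast; other-dual = dual-responsive but neither red nor blue.
    """
    cv_any = np.zeros(len(groups), bool)
    hfm_any = np.zeros(len(groups), bool)
    for c in PLUS_CV:
        cv_any |= groups[f"{c}|up"].to_numpy() | groups[f"{c}|down"].to_numpy()
    for c in PLUS_HFM:
        hfm_any |= groups[f"{c}|up"].to_numpy() | groups[f"{c}|down"].to_numpy()
    dual = cv_any & hfm_any
    red = groups["CV+HFM/CV|up"].to_numpy() & groups["CV+HFM/GF+HFM|up"].to_numpy()
    blue = groups["GF+HFM/GF|up"].to_numpy() & groups["CV+HFM/GF+HFM|down"].to_numpy()
    cls = np.full(len(groups), "none", dtype=object)
    cls[dual] = "other-dual"
    cls[red] = "red"
    cls[blue] = "blue"
    return pd.DataFrame({"integration_class": cls, "dual_responsive": dual}, index=groups.index)


ACCESSIBILITY_LABELS = (
    "pan-accessible",
    "enterocyte-specific",
    "ISC-specific",
    "enterocyte-restricted",
    "ISC-restricted",
    "other",
)


def classify_accessibility(
    regions: pd.DataFrame, accessibility: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Label each region by the cell types in which it is accessible.

    Overlap of >= 1 bp with a cell type's accessible set marks the region
    accessible in that type.  pan-accessible = all types; X-specific = only
    X; X-restricted = X plus some but not all others (X in {enterocyte,
    ISC}); everything else (including no overlap at all) = other.  Labels
    are assigned in the fixed precedence order above, so each region gets
    exactly one.
    """
    if len(accessibility) < 2 or not {"enterocyte", "ISC"} <= set(accessibility):
        raise ValueError("need >= 2 cell types including 'enterocyte' and 'ISC'")
    flags = pd.DataFrame(
        {ct: has_overlap(regions, acc).to_numpy() for ct, acc in accessibility.items()},
        index=regions["name"].to_numpy(),
    )
    n_types = flags.shape[1]
    n_acc = flags.sum(axis=1)
    labels = pd.Series("other", index=flags.index, dtype=object)
    pan = n_acc == n_types
    ent_spec = flags["enterocyte"] & (n_acc == 1)
    isc_spec = flags["ISC"] & (n_acc == 1)
    ent_restr = flags["enterocyte"] & (n_acc > 1) & ~pan
    isc_restr = flags["ISC"] & (n_acc > 1) & ~pan
    for mask, lab in [
        (isc_restr, "ISC-restricted"),
        (ent_restr, "enterocyte-restricted"),
        (isc_spec, "ISC-specific"),
        (ent_spec, "enterocyte-specific"),
        (pan, "pan-accessible"),
    ]:
        labels[mask] = lab  # later assignments take precedence
    out = flags.copy()
    out["accessibility_class"] = labels
    return out


def moving_mean(values, window: int = 500, step: int = 1) -> np.ndarray:
    """Descending moving mean: mean of up to ``window`` consecutive values
    starting at each position, advancing ``step`` at a time.

    Windows at the tail are truncated; missing values are excluded from each
    window's mean, and an all-missing window yields NaN.
    """
    v = np.asarray(values, float)
    if len(v) == 0:
        raise ValueError("series must have length >= 1")
    out = []
    for i in range(0, len(v), step):
        w = v[i : i + window]
        ok = np.isfinite(w)
        out.append(float(w[ok].mean()) if ok.any() else np.nan)
    return np.array(out)


def associate_distributions(a, b, exact_limit: int = 10_000):
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Exact p value by enumeration when n*m <= ``exact_limit``, asymptotic
    otherwise.  Returns (D, p); p is NaN with a warning when either sample
    has fewer than 3 values.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(a) < 3 or len(b) < 3:
        warnings.warn("fewer than 3 observations in a group; KS p value not reported")
        d = stats.ks_2samp(a, b, method="asymp").statistic
        return float(d), float("nan")
    method = "exact" if len(a) * len(b) <= exact_limit else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def compartment_summary(
    log2fc: pd.Series, compartments: pd.Series, order: list[str] | None = None
) -> pd.DataFrame:
    """Mean log2FC and feature count per compartment (e.g. crypt -> villus tip).

    Features without a compartment label are excluded; empty compartments
    report NaN means and zero counts.  ``order`` fixes the row order
    (default: order of first appearance in ``compartments``).
    """
    labels = compartments.reindex(log2fc.index)
    keep = labels.notna()
    if order is None:
        order = list(dict.fromkeys(labels[keep]))
    rows = []
    for comp in order:
        vals = log2fc[keep & (labels == comp)]
        rows.append({"compartment": comp, "mean_log2FC": float(vals.mean()) if len(vals) else np.nan, "n": len(vals)})
    return pd.DataFrame(rows).set_index("compartment")
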