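"""Negative-binomial GLMs for a 2x2 factorial (microbes x meal) design.

The mean model for feature *i*, sample *j* is

    mu_ij = s_j * q_i * 2 ** (bm * x_j + bf * y_j + bi * x_j * y_j)

with size factor ``s_j``, base mean ``q_i``, and ``x_j, y_j`` in {0, 1}
indicating microbiota colonization (CV) and the high-fat meal (HFM).
``bi`` is the interaction log2 fold change: the log2 ratio of
(CV+HFM/CV) / (GF+HFM/GF).  Counts are NB with variance mu + alpha * mu^2.

Coefficients are fitted on the natural-log scale by iteratively reweighted
least squares at a fixed per-feature dispersion and reported on the log2
scale.  The interaction is tested with a likelihood-ratio test against the
additive (no-interaction) model; pairwise condition contrasts use Wald tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

LN2 = np.log(2.0)

#: The four pairwise condition contrasts plus the interaction, expressed as
#: linear combinations of (intercept, microbes, meal, interaction) on log2 scale.
CONTRASTS = {
    "CV/GF": np.array([0.0, 1.0, 0.0, 0.0]),
    "CV+HFM/GF+HFM": np.array([0.0, 1.0, 0.0, 1.0]),
    "GF+HFM/GF": np.array([0.0, 0.0, 1.0, 0.0]),
    "CV+HFM/CV": np.array([0.0, 0.0, 1.0, 1.0]),
    "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
}

CONDITIONS = ("GF", "GF+HFM", "CV", "CV+HFM")


def condition_of(microbes: str, meal: str) -> str:
    base = {"GF": "GF", "CV": "CV"}[microbes]
    return base + ("+HFM" if meal == "HFM" else "")


def validate_design(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Check the sample sheet against the count matrix and return it indexed by sample."""
    d = design.copy()
    if "sample" in d.columns:
        d = d.set_index("sample")
    missing = [s for s in counts.columns if s not in d.index]
    if missing:
        raise ValueError(f"samples missing from the sample sheet: {missing}")
    dup = d.index[d.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicated sample in sheet: {list(dup)}")
    d = d.loc[list(counts.columns)]
    bad_m = set(d["microbes"]) - {"GF", "CV"}
    bad_f = set(d["meal"]) - {"none", "HFM"}
    if bad_m or bad_f:
        raise ValueError(f"unrecognized factor levels: {bad_m | bad_f}")
    d["condition"] = [condition_of(m, f) for m, f in zip(d["microbes"], d["meal"])]
    return d


def design_matrix(design: pd.DataFrame) -> np.ndarray:
    """Full-model matrix (intercept, microbes, meal, interaction) in sample order."""
    x = (design["microbes"] == "CV").to_numpy(float)
    y = (design["meal"] == "HFM").to_numpy(float)
    return np.column_stack([np.ones_like(x), x, y, x * y])


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean across samples, computed
    over features with positive counts in every sample; when no such feature
    exists the geometric mean falls back to positive entries only.
    """
    mat = counts.to_numpy(float)
    if not mat.size or (mat.sum(axis=0) == 0).any() and (mat == 0).all():
        raise ValueError("count matrix is empty or all zero")
    if (mat == 0).all():
        raise ValueError("count matrix is all zero")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_pos = np.isfinite(logs).all(axis=1)
    if all_pos.any():
        loggeo = logs[all_pos].mean(axis=1)
        use = logs[all_pos]
    else:
        warnings.warn("no feature positive in all samples; using positive-only geometric means")
        pos = np.isfinite(logs)
        keep = pos.any(axis=1)
        loggeo = np.where(pos[keep], logs[keep], np.nan)
        loggeo = np.nanmean(loggeo, axis=1)
        use = logs[keep]
    ratios = use - loggeo[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log_sf = np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan), axis=0)
    if not np.isfinite(log_sf).all():
        raise ValueError("could not estimate a size factor for every sample")
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def base_means(counts: pd.DataFrame, size_factors: pd.Series) -> pd.Series:
    norm = counts.to_numpy(float) / size_factors.to_numpy()[None, :]
    return pd.Series(norm.mean(axis=1), index=counts.index, name="baseMean")


ALPHA_FLOOR = 1e-8


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.DataFrame,
    trend_weight: float = 0.9,
) -> pd.DataFrame:
    """Per-feature NB dispersions: method-of-moments, a 1/mu trend, and their blend.

    The per-feature estimate pools within-condition residuals of normalized
    counts: for each condition cell with >= 2 replicates,
    alpha_c = (var_c - mu_c) / mu_c^2, combined across cells weighted by
    degrees of freedom and floored at 1e-8.  A trend alpha(mu) = a0 + a1/mu
    is fitted to per-bin means of the raw (unfloored) feature estimates
    across ~20 base-mean quantile bins — averaging before flooring keeps the
    trend nearly unbiased despite the heavy skew of individual estimates.
    The final estimate is the geometric interpolation
    alpha = mom^(1-w) * trend^w with ``trend_weight`` w.
    """
    norm = counts.to_numpy(float) / size_factors.to_numpy()[None, :]
    bm = norm.mean(axis=1)
    cells = design["condition"].to_numpy()
    alpha_mom = np.full(len(counts), np.nan)
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    any_rep = False
    for cond in np.unique(cells):
        cols = np.where(cells == cond)[0]
        if len(cols) < 2:
            continue
        any_rep = True
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu**2
        ok = np.isfinite(a)
        w = len(cols) - 1
        num[ok] += w * a[ok]
        den[ok] += w
    if not any_rep:
        warnings.warn("no condition has replicates; dispersion estimates are trend-only")
        alpha_mom = np.full(len(counts), np.nan)
    else:
        with np.errstate(invalid="ignore"):
            alpha_mom = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    alpha_mom_fl = np.where(np.isfinite(alpha_mom), np.maximum(alpha_mom, ALPHA_FLOOR), np.nan)

    # trend fit alpha = a0 + a1/mu on binned means of the raw estimates
    fit_mask = np.isfinite(alpha_mom) & (bm > 0)
    if fit_mask.sum() >= 10:
        mu_fit, a_fit = bm[fit_mask], alpha_mom[fit_mask]
        n_bins = min(20, max(fit_mask.sum() // 5, 2))
        edges = np.quantile(mu_fit, np.linspace(0, 1, n_bins + 1))
        which = np.clip(np.searchsorted(edges, mu_fit, side="right") - 1, 0, n_bins - 1)
        mu_b, a_b = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() >= 2:
                mu_b.append(np.median(mu_fit[sel]))
                a_b.append(a_fit[sel].mean())
        mu_b, a_b = np.array(mu_b), np.array(a_b)
        X = np.column_stack([np.ones(len(mu_b)), 1.0 / mu_b])
        coef = np.linalg.lstsq(X, a_b, rcond=None)[0]
        a0, a1 = max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)
    else:
        a0 = float(np.nanmedian(alpha_mom_fl)) if np.isfinite(alpha_mom_fl).any() else 0.01
        a0, a1 = max(a0, ALPHA_FLOOR), 0.0
    with np.errstate(divide="ignore"):
        alpha_trend = np.maximum(a0 + a1 / np.maximum(bm, 1e-12), ALPHA_FLOOR)

    w = float(trend_weight)
    final = np.where(
        np.isfinite(alpha_mom_fl),
        np.exp((1 - w) * np.log(alpha_mom_fl) + w * np.log(alpha_trend)),
        alpha_trend,
    )
    return pd.DataFrame(
        {"baseMean": bm, "alpha_mom": alpha_mom, "alpha_trend": alpha_trend, "alpha": final},
        index=counts.index,
    )


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood with variance mu + alpha mu^2 (size r = 1/alpha)."""
    mu = np.maximum(mu, 1e-12)
    if alpha < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


MAX_ETA = 50.0


def _irls(y, X, offset, alpha, tol=1e-8, maxiter=100):
    """IRLS for an NB GLM with log link and fixed dispersion.

    Returns (beta on natural-log scale, covariance, loglik, converged, n_iter).
    """
    n, p = X.shape
    beta = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        eta = np.clip(X @ beta + offset, -MAX_ETA, MAX_ETA)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-12)
        XtW = X.T * w
        A = XtW @ X
        A_reg = A + np.eye(p) * 1e-12
        new = np.linalg.solve(A_reg, XtW @ z)
        step = new - beta
        beta = new
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -MAX_ETA, MAX_ETA)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    A = (X.T * w) @ X
    try:
        cov = np.linalg.inv(A + np.eye(p) * 1e-12)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    ll = nb_loglik(y, mu, alpha)
    return beta, cov, ll, converged, it


@dataclass
class FitResult:
    """Per-feature full and reduced NB fits for the factorial model.

    ``table`` columns: intercept/beta_microbes/beta_meal/beta_interaction and
    their SEs (log2 scale), ll_full, ll_reduced, converged, baseMean.
    ``cov`` holds the 4x4 log2-scale coefficient covariance per feature.
    """

    table: pd.DataFrame
    cov: np.ndarray
    design: pd.DataFrame = field(repr=False, default=None)

    @property
    def features(self):
        return self.table.index


COEF_NAMES = ["intercept", "beta_microbes", "beta_meal", "beta_interaction"]


def fit_nb_glm(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    trend_weight: float = 0.9,
) -> FitResult:
    """Fit full (with interaction) and reduced (additive) NB GLMs per feature.

    Features with zero counts in every sample are dropped.  A single
    dispersion per feature is shared between the two fits so the LRT compares
    nested mean models only.
    """
    design = validate_design(counts, design)
    keep = counts.sum(axis=1) > 0
    counts = counts.loc[keep]
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, size_factors, design, trend_weight)["alpha"]
    else:
        dispersions = dispersions.loc[counts.index]
    X = design_matrix(design)
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("design is not full rank: all four conditions must be occupied")
    Xr = X[:, :3]
    offset = np.log(size_factors.to_numpy())
    bm = base_means(counts, size_factors)
    Y = counts.to_numpy(float)
    n = len(counts)
    coefs = np.empty((n, 4))
    ses = np.empty((n, 4))
    covs = np.empty((n, 4, 4))
    ll_full = np.empty(n)
    ll_red = np.empty(n)
    conv = np.empty(n, bool)
    for i in range(n):
        alpha = max(float(dispersions.iloc[i]), ALPHA_FLOOR)
        b, cov, llf, cf, _ = _irls(Y[i], X, offset, alpha)
        br, _, llr, cr, _ = _irls(Y[i], Xr, offset, alpha)
        coefs[i] = b / LN2
        covs[i] = cov / LN2**2
        ses[i] = np.sqrt(np.maximum(np.diag(cov), 0.0)) / LN2
        ll_full[i] = llf
        ll_red[i] = llr
        conv[i] = cf and cr
    table = pd.DataFrame(coefs, index=counts.index, columns=COEF_NAMES)
    for j, c in enumerate(COEF_NAMES):
        table[f"SE_{c}"] = ses[:, j]
    table["ll_full"] = ll_full
    table["ll_reduced"] = ll_red
    table["converged"] = conv
    table["baseMean"] = bm
    table["alpha"] = dispersions.to_numpy()
    return FitResult(table=table, cov=covs, design=design)


def wald_contrast(fit: FitResult, contrast: str) -> pd.DataFrame:
    """Wald test of one pairwise contrast (or the interaction coefficient).

    The log2 fold change is the linear combination of coefficients for the
    contrast; p values are two-sided normal on log2FC / SE.  Non-converged
    features get missing p values.
    """
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    c = CONTRASTS[contrast]
    beta = fit.table[COEF_NAMES].to_numpy()
    lfc = beta @ c
    var = np.einsum("i,nij,j->n", c, fit.cov, c)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(fit.table["converged"].to_numpy(), p, np.nan)
    return pd.DataFrame(
        {
            "baseMean": fit.table["baseMean"],
            "log2FC": lfc,
            "SE": se,
            "p": p,
            "contrast": contrast,
        },
        index=fit.features,
    )


def lrt_interaction(fit: FitResult) -> pd.DataFrame:
    """Likelihood-ratio test of the interaction term (chi-square, 1 df).

    The statistic 2*(ll_full - ll_reduced) is floored at 0; small negative
    excursions beyond tolerance mark the feature for refitting.
    """
    raw = 2.0 * (fit.table["ll_full"] - fit.table["ll_reduced"]).to_numpy()
    needs_refit = raw < -1e-4
    stat = np.maximum(raw, 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(fit.table["converged"].to_numpy(), p, np.nan)
    return pd.DataFrame(
        {
            "baseMean": fit.table["baseMean"],
            "log2FC": fit.table["beta_interaction"],
            "SE": fit.table["SE_beta_interaction"],
            "stat": stat,
            "p": p,
            "needs_refit": needs_refit,
            "contrast": "interaction",
        },
        index=fit.features,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values; NaNs are passed through."""
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests

        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class Thresholds:
    """Significance cutoffs used throughout the pipeline.

    standard: BH-adjusted p < padj (genes and joined peaks).
    lenient gene: raw p < lenient_gene_p and baseMean > lenient_gene_basemean
    (putative interaction genes).
    lenient window: raw p < lenient_window_p and baseMean >
    lenient_window_basemean (putative interaction chromatin windows).
    """

    padj: float = 0.05
    lenient_gene_p: float = 0.05
    lenient_gene_basemean: float = 10.0
    lenient_window_p: float = 0.01
    lenient_window_basemean: float = 15.0


def adjust_and_call(result: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """BH-adjust one contrast's p values and attach the three significance flags."""
    out = result.copy()
    if not len(out):
        for col in ("padj", "sig_standard", "sig_lenient_gene", "sig_lenient_window"):
            out[col] = pd.Series(dtype=float if col == "padj" else bool)
        return out
    out["padj"] = bh_adjust(out["p"].to_numpy())
    p = out["p"].to_numpy()
    bm = out["baseMean"].to_numpy()
    out["sig_standard"] = np.where(np.isfinite(out["padj"]), out["padj"] < thresholds.padj, False)
    out["sig_lenient_gene"] = np.where(
        np.isfinite(p), (p < thresholds.lenient_gene_p) & (bm > thresholds.lenient_gene_basemean), False
    )
    out["sig_lenient_window"] = np.where(
        np.isfinite(p), (p < thresholds.lenient_window_p) & (bm > thresholds.lenient_window_basemean), False
    )
    return out


def run_differential(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    trend_weight: float = 0.9,
) -> dict[str, pd.DataFrame]:
    """Full factorial analysis: the four Wald contrasts plus the interaction LRT.

    Returns one BH-adjusted, flagged result table per contrast name.  BH is
    applied within each contrast separately.
    """
    fit = fit_nb_glm(counts, design, trend_weight=trend_weight)
    results = {}
    for name in ("CV/GF", "CV+HFM/GF+HFM", "GF+HFM/GF", "CV+HFM/CV"):
        results[name] = adjust_and_call(wald_contrast(fit, name), thresholds)
    results["interaction"] = adjust_and_call(lrt_interaction(fit), thresholds)
    return results
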