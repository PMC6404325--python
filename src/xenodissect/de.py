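"""Composition-adjusted differential expression for per-species counts.

Mixed-species samples vary widely in how much of their RNA belongs to the
focal organism, and residual composition-dependent expression survives even
within-species normalization.  The model here therefore regresses each
gene's counts on the sample's species percentage alongside the condition of
interest: a negative-binomial log-link GLM with design

    log mu = log(size_factor) + b0 + b1 * percent + sum_c b_c * [condition = c]

("mouse percent when modelling mouse expression, human percent when
modelling human expression").  Per-condition contrasts are tested with a
Wald test and corrected by Benjamini-Hochberg; genes excluded from the
correction (low counts or a single-sample-driven fold change) carry an
absent (NA) adjusted p-value.

Deliberate simplifications relative to shrinkage-based DE packages: the
per-gene dispersion is a plain method-of-moments estimate with a floor —
there is no empirical-Bayes moderation — and fold changes are not shrunk.
Calibration is asserted by simulation (type-I error, power, covariate
efficacy) rather than by matching any particular tool's output gene for
gene.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._exceptions import InvalidInputError, InvalidParameterError
from .containers import CountMatrix

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def size_factors(counts) -> pd.Series:
    """Median-of-ratios sample normalization factors.

    Each sample's factor is the median over genes (with positive geometric
    mean) of count / geometric-mean; factors are rescaled to geometric mean
    one.  If no gene is nonzero in all samples, falls back to library-size
    ratios with a warning.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(arr).mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        warnings.warn(
            "no gene nonzero in every sample; using library-size ratios",
            stacklevel=2,
        )
        lib = arr.sum(axis=0)
        if (lib == 0).any():
            raise InvalidInputError("sample with zero total counts")
        sf = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(sf, index=df.columns)
    geo = np.exp(loggeo[usable])
    sf = np.median(arr[usable] / geo[:, None], axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=df.columns)


def estimate_dispersion(
    counts, sf: pd.Series, condition: list[str] | None = None
) -> pd.Series:
    """Per-gene method-of-moments dispersion on normalized counts.

    alpha_g = max((s^2 - mean) / mean^2, floor), with Var = mu + alpha mu^2.
    When ``condition`` labels are given, the variance is the residual
    variance around the per-condition group means (df-corrected) and the
    mean terms are the fitted group means — the moment estimator applied
    where the mean model actually holds, so planted condition effects do
    not masquerade as biological dispersion.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    norm = df.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    if condition is None:
        m = norm.mean(axis=1)
        m2 = m**2
        v = norm.var(axis=1, ddof=1)
    else:
        cond = np.asarray(condition)
        n = norm.shape[1]
        groups = [np.flatnonzero(cond == c) for c in dict.fromkeys(condition)]
        n_groups = sum(1 for g in groups if len(g))
        fitted = np.empty_like(norm)
        for g in groups:
            fitted[:, g] = norm[:, g].mean(axis=1, keepdims=True)
        dof = max(n - n_groups, 1)
        v = ((norm - fitted) ** 2).sum(axis=1) / dof
        m = fitted.mean(axis=1)
        m2 = (fitted**2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return pd.Series(np.maximum(alpha, DISPERSION_FLOOR), index=df.index)


@dataclass
class GeneFit:
    """One gene's NB GLM fit; coefficients and SEs are on the log2 scale."""

    coef: pd.Series
    se: pd.Series
    converged: bool
    mu: np.ndarray | None = None


def build_design(
    percent: np.ndarray, condition: list[str], reference: str
) -> tuple[np.ndarray, list[str]]:
    """Intercept + centered percent + treatment-coded condition dummies."""
    levels = [c for c in dict.fromkeys(condition) if c != reference]
    if reference not in condition:
        raise InvalidInputError(f"reference condition {reference!r} absent")
    cols = [np.ones(len(condition))]
    names = ["intercept"]
    for lev in levels:
        cols.append(np.array([1.0 if c == lev else 0.0 for c in condition]))
        names.append(f"condition[{lev}]")
    # percent enters last so that, when it is exactly collinear with the
    # condition coding (e.g. normal organs at 100% of one species), the
    # adjustment column is dropped rather than the tested term
    cols.append(percent - percent.mean())
    names.append("percent")
    X = np.column_stack(cols)
    keep = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear design column {names[j]!r}", stacklevel=2)
    return X[:, keep], [names[j] for j in keep]


def fit_gene_glm(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    sf: np.ndarray,
    dispersion: float,
) -> GeneFit:
    """NB log-link GLM with log(size factor) offset, via IRLS."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                y,
                X,
                family=sm.families.NegativeBinomial(alpha=max(dispersion, DISPERSION_FLOOR)),
                offset=np.log(sf),
            )
            res = model.fit(maxiter=100, tol=1e-8)
        coef = pd.Series(res.params / LN2, index=names)
        se = pd.Series(res.bse / LN2, index=names)
        converged = bool(getattr(res, "converged", True)) and np.isfinite(
            se.to_numpy()
        ).all()
        return GeneFit(coef, se, converged, mu=np.asarray(res.mu))
    except Exception:
        nan = pd.Series(np.nan, index=names)
        return GeneFit(nan, nan, False)


def wald_test(
    fit: GeneFit, term: str, df: float | None = None
) -> tuple[float, float, float]:
    """(log2FC, z, two-sided p) for one design term.

    With ``df`` the statistic is referred to a t distribution with that many
    degrees of freedom — the small-sample reference for a Wald statistic
    whose dispersion was itself estimated on the residual degrees of
    freedom; ``df=None`` gives the asymptotic normal reference.
    """
    beta = fit.coef.get(term, np.nan)
    se = fit.se.get(term, np.nan)
    if not fit.converged or not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        return beta, np.nan, np.nan
    z = beta / se
    if df is None or not np.isfinite(df):
        return beta, z, 2.0 * stats.norm.sf(abs(z))
    return beta, z, 2.0 * stats.t.sf(abs(z), df=df)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


def _loo_outliers(
    norm: np.ndarray, cond: np.ndarray, lfc: np.ndarray, min_abs_lfc: float
) -> np.ndarray:
    """Genes whose fold change sign depends on a single sample.

    Only genes with a substantial full-data fold change (|log2FC| above
    ``min_abs_lfc``) are eligible: a near-zero effect has no meaningful sign
    to cross.
    """
    eps = 0.5
    groups = [np.flatnonzero(cond == 0), np.flatnonzero(cond == 1)]
    sums = [norm[:, g].sum(axis=1) for g in groups]
    ns = [len(g) for g in groups]
    flagged = np.zeros(norm.shape[0], dtype=bool)
    eligible = np.abs(lfc) > min_abs_lfc
    full_sign = np.sign(lfc)
    for gi, g in enumerate(groups):
        if ns[gi] <= 1:
            continue
        for s in g:
            mean_loo = (sums[gi] - norm[:, s]) / (ns[gi] - 1)
            mean_other = sums[1 - gi] / ns[1 - gi]
            if gi == 0:
                l = np.log2((mean_other + eps) / (mean_loo + eps))
            else:
                l = np.log2((mean_loo + eps) / (sums[0] / ns[0] + eps))
            flagged |= eligible & (np.sign(l) != full_sign) & (full_sign != 0)
    return flagged


def run_de(
    counts,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    percent_col: str | None = None,
    condition_col: str = "tissue",
    alpha: float = 0.05,
    use_percent: bool = True,
    independent_filtering: bool = True,
    outlier_filtering: bool = True,
    min_outlier_lfc: float = np.log2(1.5),
) -> pd.DataFrame:
    """Full composition-adjusted DE stage for one contrast.

    ``contrast = (condition_B, condition_A)`` tests B vs A; all conditions
    present in the metadata are fit jointly with indicator coding relative
    to A.  Returns the conventional per-gene table (baseMean, log2FoldChange, lfcSE,
    stat, pvalue, padj) where padj is NaN for genes removed by independent
    filtering or the single-sample-outlier rule.
    """
    cm = counts if isinstance(counts, CountMatrix) else None
    df = cm.counts if cm is not None else counts
    organism = cm.organism if cm is not None else "human"
    if percent_col is None:
        percent_col = "human_pct" if organism == "human" else "mouse_pct"
    cond_b, cond_a = contrast
    meta = metadata.loc[[s for s in df.columns if s in metadata.index]]
    df = df[meta.index]
    for c in (cond_a, cond_b):
        if (meta[condition_col] == c).sum() < 2:
            raise InvalidInputError(
                f"condition {c!r} has fewer than 2 samples; cannot test"
            )
    sf = size_factors(df)
    percent = meta[percent_col].to_numpy(dtype=float)
    condition = list(meta[condition_col])
    disp = estimate_dispersion(df, sf, condition=condition)
    if not use_percent:
        percent = np.zeros(len(condition))
    X, names = build_design(percent, condition, reference=cond_a)
    term = f"condition[{cond_b}]"
    sfv = sf.to_numpy()
    arr = df.to_numpy(dtype=float)
    norm = arr / sfv[None, :]
    in_contrast = meta[condition_col].isin([cond_a, cond_b]).to_numpy()
    base_mean = norm[:, in_contrast].mean(axis=1)
    resid_df = max(arr.shape[1] - X.shape[1], 1)
    rows = np.empty((arr.shape[0], 4))
    for g in range(arr.shape[0]):
        fit = fit_gene_glm(arr[g], X, names, sfv, float(disp.iloc[g]))
        lfc, z, p = wald_test(fit, term, df=resid_df)
        rows[g] = (lfc, fit.se.get(term, np.nan), z, p)
    result = pd.DataFrame(
        rows,
        index=df.index,
        columns=["log2FoldChange", "lfcSE", "stat", "pvalue"],
    )
    result.insert(0, "baseMean", base_mean)
    # genes excluded from multiple testing: independent filtering + outliers
    excluded = ~np.isfinite(result["pvalue"].to_numpy())
    if outlier_filtering:
        cvec = np.where(np.array(condition) == cond_b, 1, 0)
        sub = np.flatnonzero(in_contrast)
        out = _loo_outliers(
            norm[:, sub],
            cvec[sub],
            result["log2FoldChange"].to_numpy(),
            min_outlier_lfc,
        )
        excluded |= out
    if independent_filtering:
        excluded |= _independent_filter(
            base_mean, result["pvalue"].to_numpy(), excluded, alpha
        )
    padj = np.full(len(result), np.nan)
    keep = ~excluded
    padj[keep] = bh_adjust(result["pvalue"].to_numpy()[keep])
    result["padj"] = padj
    return result


def _independent_filter(
    base_mean: np.ndarray, p: np.ndarray, excluded: np.ndarray, alpha: float
) -> np.ndarray:
    """baseMean threshold scan on a 20-point quantile grid.

    Among cutoffs whose BH rejection count comes within one residual
    standard deviation (about a lowess fit of rejections vs. cutoff) of the
    maximum, the smallest is chosen — maximizing rejections outright
    overshoots into well-powered genes when discoveries concentrate at high
    counts.
    """
    usable = np.isfinite(p) & ~excluded
    if usable.sum() == 0:
        return np.zeros(p.shape, dtype=bool)
    quantiles = np.linspace(0.0, 0.95, 20)
    cutoffs = np.quantile(base_mean[usable], quantiles)
    rejections = np.full(len(cutoffs), -1)
    for i, cut in enumerate(cutoffs):
        mask = usable & (base_mean >= cut)
        if mask.sum() == 0:
            continue
        rejections[i] = int((bh_adjust(p[mask]) <= alpha).sum())
    valid = rejections >= 0
    rej = rejections[valid].astype(float)
    fit = sm.nonparametric.lowess(rej, quantiles[valid], frac=0.5, return_sorted=False)
    resid_sd = float(np.std(rej - fit))
    good = rej >= rej.max() - resid_sd
    best_cut = cutoffs[valid][np.flatnonzero(good)[0]]
    return base_mean < best_cut


def recurrent_genes(
    de_tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
    fold_threshold: float = 2.0,
    min_lines: int = 5,
    direction: str = "up",
    require_fdr: bool = False,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes recurrently regulated across per-line DE tables.

    A gene is kept when its linear fold change passes ``fold_threshold`` in
    the stated direction in at least ``min_lines`` tables and, when
    ``require_fdr``, padj < ``fdr_threshold`` in those same tables.  Output
    is sorted by number of supporting lines, then mean fold change.
    """
    if isinstance(de_tables, dict):
        tables = list(de_tables.values())
    else:
        tables = list(de_tables)
    if not tables:
        raise InvalidParameterError("at least one DE table required")
    if direction not in ("up", "down"):
        raise InvalidParameterError("direction must be 'up' or 'down'")
    genes = tables[0].index
    for t in tables[1:]:
        genes = genes.union(t.index)
    support = pd.DataFrame(False, index=genes, columns=range(len(tables)))
    folds = pd.DataFrame(np.nan, index=genes, columns=range(len(tables)))
    for i, t in enumerate(tables):
        fold = np.exp2(t["log2FoldChange"])
        ok = fold >= fold_threshold if direction == "up" else fold <= 1.0 / fold_threshold
        if require_fdr:
            ok &= t["padj"].notna() & (t["padj"] < fdr_threshold)
        support.loc[t.index, i] = ok.to_numpy()
        folds.loc[t.index, i] = fold.to_numpy()
    n_support = support.sum(axis=1)
    kept = n_support[n_support >= min_lines].index
    mean_fold = folds.loc[kept].mean(axis=1)
    out = pd.DataFrame(
        {"n_lines": n_support.loc[kept], "mean_fold": mean_fold}, index=kept
    )
    return out.sort_values(
        by=["n_lines", "mean_fold"], ascending=[False, False]
    ).rename_axis("gene_id")
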