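"""Per-species expression representations and cohort-level QC.

Because TPM is computed within each species separately, it is invariant to
how much of a sample's RNA came from the other organism: scaling every human
gene's counts by the human read fraction cancels in the within-species
normalization.  That property is what makes mixed-species samples comparable
at very different human/mouse ratios, and it is asserted by this module's
tests rather than assumed.

The remaining operations are the standard expression toolkit around that
representation: log2(TPM+1), all-zero-gene removal, the differential-
expression prefilter, upper-quantile normalization and row-median centering
for cross-cohort clustering, variable-gene selection, PCA, Ward clustering
on correlation distance, the correlation-based label-swap QC, cohort
merging, and a generic nearest-centroid subtyper for user-supplied centroid
models.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from ._exceptions import InvalidInputError, InvalidParameterError
from .containers import CountMatrix, ExpressionMatrix


def tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Transcripts-per-million within one species.

    TPM[g, s] = 1e6 * (c[g, s] / l_g) / sum_h (c[h, s] / l_h).  Columns with
    no counts at all stay all-zero and are flagged with a warning.
    """
    rate = counts.counts.div(counts.lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom.index[denom == 0]
    if len(zero_cols):
        warnings.warn(
            f"all-zero sample column(s): {list(zero_cols)}", stacklevel=2
        )
    denom = denom.replace(0, np.nan)
    values = rate.div(denom, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(values, counts.organism, ("TPM",))


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1); keeps zeros at zero."""
    if expr.last_transform != "TPM":
        raise InvalidInputError("log_transform expects a TPM matrix")
    if (expr.values.to_numpy() < 0).any():
        raise InvalidInputError("negative expression values")
    return expr.with_values(np.log2(expr.values + 1.0), "log2")


def drop_all_zero_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes that are zero in every sample, preserving order."""
    keep = (expr.values != 0).any(axis=1)
    return ExpressionMatrix(expr.values.loc[keep], expr.organism, expr.transforms)


@dataclass
class PrefilterResult:
    kept: pd.Index
    dropped: pd.Index


def de_prefilter(
    matrix,
    min_expr: float = 0.5,
    min_frac: float = 0.10,
    ratio_threshold: float = 0.5,
):
    """Gene prefilter applied before differential expression.

    A gene is kept iff its expression exceeds ``min_expr`` in at least
    ``ceil(min_frac * n_samples)`` samples AND max / (min + 1) exceeds
    ``ratio_threshold`` (the +1 guards zero minima).  Note the ratio clause
    as printed is satisfied by almost every expressed gene; the threshold is
    a parameter rather than a reinterpretation.  Accepts a ``CountMatrix``,
    ``ExpressionMatrix`` or plain DataFrame; returns the same type plus a
    :class:`PrefilterResult` log.
    """
    if min_expr <= 0 or min_frac <= 0 or ratio_threshold <= 0:
        raise InvalidParameterError("prefilter thresholds must be positive")
    if isinstance(matrix, CountMatrix):
        values = matrix.counts
    elif isinstance(matrix, ExpressionMatrix):
        values = matrix.values
    else:
        values = matrix
    arr = values.to_numpy(dtype=float)
    n = arr.shape[1]
    need = int(np.ceil(min_frac * n))
    clause1 = (arr > min_expr).sum(axis=1) >= need
    clause2 = arr.max(axis=1) / (arr.min(axis=1) + 1.0) > ratio_threshold
    nonzero = arr.any(axis=1)
    keep = clause1 & clause2 & nonzero
    log = PrefilterResult(values.index[keep], values.index[~keep])
    if isinstance(matrix, CountMatrix):
        return (
            CountMatrix(matrix.counts.loc[keep], matrix.lengths, matrix.organism),
            log,
        )
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(values.loc[keep], matrix.organism, matrix.transforms), log
    return values.loc[keep], log


def upper_quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Equalize each column's 75th percentile (log-scale additive shift).

    The percentile is computed over genes nonzero in that column, and only
    nonzero entries are shifted, so absent genes stay at zero.  Columns with
    no nonzero gene are skipped with a warning.
    """
    if "log2" not in expr.transforms:
        raise InvalidInputError("upper-quantile normalization expects log-scale input")
    values = expr.values.copy()
    uq = {}
    for col in values.columns:
        v = values[col].to_numpy()
        nz = v[v != 0]
        if nz.size == 0:
            warnings.warn(f"column {col} all zero; skipped", stacklevel=2)
            continue
        uq[col] = np.percentile(nz, 75)
    if uq:
        target = float(np.mean(list(uq.values())))
        for col, q in uq.items():
            v = values[col].to_numpy()
            mask = v != 0
            v[mask] += target - q
            values[col] = v
    return expr.with_values(values, "uq_normalized")


def median_center_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples."""
    values = expr.values.sub(expr.values.median(axis=1), axis=0)
    return expr.with_values(values, "median_centered")


def top_variable_genes(expr: ExpressionMatrix, n: int = 2000) -> list[str]:
    """The ``n`` genes with the largest sample variance (ties by gene_id)."""
    if n > expr.values.shape[0]:
        raise InvalidParameterError("n exceeds the number of genes")
    var = expr.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


def correlation_qc(
    expr: ExpressionMatrix, metadata: pd.DataFrame
) -> tuple[list[str], list[tuple[str, str]]]:
    """Flag samples whose nearest expression neighbor belongs to another line.

    For each sample, the PDX line of its highest-Pearson-correlated *other*
    sample is compared with its own label; mismatches are flagged.  Two
    flagged samples form a suspected swap when their labels cross: each
    one's nearest-neighbor line equals the other's label (a swapped sample
    clusters with its true line, not with the other swapped sample).
    """
    samples = [s for s in expr.sample_ids if s in metadata.index]
    if len(samples) < 2:
        return [], []
    sub = expr.values[samples]
    corr = np.corrcoef(sub.to_numpy().T)
    np.fill_diagonal(corr, -np.inf)
    flagged = []
    nearest_line = {}
    for i, s in enumerate(samples):
        best = samples[int(np.argmax(corr[i]))]
        nearest_line[s] = metadata.loc[best, "line_id"]
        if nearest_line[s] != metadata.loc[s, "line_id"]:
            flagged.append(s)
    pairs = []
    for a in flagged:
        for b in flagged:
            if a >= b:
                continue
            la, lb = metadata.loc[a, "line_id"], metadata.loc[b, "line_id"]
            if la != lb and nearest_line[a] == lb and nearest_line[b] == la:
                pairs.append((a, b))
    return flagged, pairs


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]


def hcluster(
    expr: ExpressionMatrix, distance: str = "pearson", method: str = "ward"
) -> ClusterResult:
    """Hierarchical clustering of samples on 1 - Pearson correlation.

    Ward linkage applied to the correlation dissimilarity via the
    Lance-Williams recurrence matches R's hclust ``ward.D2`` on the same
    distances.
    """
    labels = list(expr.sample_ids)
    if distance != "pearson":
        raise InvalidParameterError("only pearson distance is supported")
    corr = np.corrcoef(expr.values.to_numpy().T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    z = linkage(squareform(d, checks=False), method=method)
    order = [labels[i] for i in leaves_list(z)]
    return ClusterResult(z, labels, order)


def pca_scores(expr: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """PCA sample scores on gene-centered, gene-scaled expression.

    Each gene (row) is centered and scaled to unit variance before the
    decomposition; zero-variance genes are dropped.  Component signs are
    fixed by making each component's largest-magnitude gene loading
    positive.  The returned frame carries explained variance ratios in
    ``df.attrs["explained_variance_ratio"]``.
    """
    values = expr.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    x = values.loc[keep]
    z = x.sub(x.mean(axis=1), axis=0).div(sd[keep], axis=0)
    mat = z.to_numpy().T  # samples x genes
    n_components = min(n_components, min(mat.shape))
    u, s, vt = np.linalg.svd(mat - mat.mean(axis=0), full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for c in range(n_components):
        imax = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, imax] < 0:
            loadings[c] = -loadings[c]
            scores[:, c] = -scores[:, c]
    df = pd.DataFrame(
        scores,
        index=values.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    total_var = (s**2).sum()
    df.attrs["explained_variance_ratio"] = (s[:n_components] ** 2) / total_var
    return df


def merge_cohorts(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    gene_subset: list[str] | None = None,
) -> tuple[ExpressionMatrix, pd.Series, dict[str, list[str]]]:
    """Column-wise merge of two cohorts on a shared gene namespace.

    Restricted to ``gene_subset`` (if given) intersected with both indices;
    returns the merged matrix, a per-sample origin Series ('a'/'b'), and the
    requested genes missing from each cohort.
    """
    subset = pd.Index(gene_subset) if gene_subset is not None else expr_a.gene_ids
    common = subset.intersection(expr_a.gene_ids).intersection(expr_b.gene_ids)
    missing = {
        "a": list(subset.difference(expr_a.gene_ids)),
        "b": list(subset.difference(expr_b.gene_ids)),
    }
    merged = pd.concat(
        [expr_a.values.loc[common], expr_b.values.loc[common]], axis=1
    )
    if merged.columns.has_duplicates:
        raise InvalidInputError("sample_ids collide between cohorts")
    origin = pd.Series(
        ["a"] * expr_a.values.shape[1] + ["b"] * expr_b.values.shape[1],
        index=merged.columns,
    )
    out = ExpressionMatrix(merged, expr_a.organism, expr_a.transforms + ("merged",))
    return out, origin, missing


def filter_by_mapped_reads(
    metadata: pd.DataFrame, min_reads: float = 1e7
) -> list[str]:
    """Samples with strictly more than ``min_reads`` mapped human reads."""
    col = metadata["mapped_human_reads"].astype(float)
    return list(metadata.index[col > min_reads])


def nearest_centroid(
    expr: ExpressionMatrix | pd.DataFrame,
    centroids: pd.DataFrame,
    distance: str = "spearman",
) -> pd.DataFrame:
    """Classify samples by maximal correlation with user-supplied centroids.

    Returns a frame with the winning class label and its correlation; exact
    ties yield the label ``"unclassified"``.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    common = values.index.intersection(centroids.index)
    if len(common) == 0:
        raise InvalidInputError("no genes shared with the centroid matrix")
    x = values.loc[common].to_numpy(dtype=float)
    c = centroids.loc[common].to_numpy(dtype=float)
    if distance == "spearman":
        x = np.apply_along_axis(rankdata, 0, x)
        c = np.apply_along_axis(rankdata, 0, c)
    elif distance != "pearson":
        raise InvalidParameterError("distance must be 'spearman' or 'pearson'")
    xz = (x - x.mean(axis=0)) / x.std(axis=0)
    cz = (c - c.mean(axis=0)) / c.std(axis=0)
    corr = xz.T @ cz / x.shape[0]
    rows = []
    for i, sample in enumerate(values.columns):
        r = corr[i]
        best = float(r.max())
        winners = [centroids.columns[j] for j in np.flatnonzero(r == best)]
        label = winners[0] if len(winners) == 1 else "unclassified"
        rows.append((sample, label, best))
    return pd.DataFrame(rows, columns=["sample_id", "label", "score"]).set_index(
        "sample_id"
    )


class NearestCentroidSubtyper:
    """Sklearn-style wrapper: fit stores centroids, predict labels samples."""

    def __init__(self, distance: str = "spearman"):
        self.distance = distance

    def get_params(self, deep: bool = True) -> dict:
        return {"distance": self.distance}

    def set_params(self, **params) -> "NearestCentroidSubtyper":
        for key, value in params.items():
            if key != "distance":
                raise ValueError(f"unknown parameter {key!r}")
            self.distance = value
        return self

    def fit(self, centroids: pd.DataFrame, y=None) -> "NearestCentroidSubtyper":
        self.centroids_ = centroids
        self.classes_ = list(centroids.columns)
        return self

    def predict(self, expr) -> list[str]:
        if not hasattr(self, "centroids_"):
            raise InvalidInputError("subtyper is not fitted")
        return list(nearest_centroid(expr, self.centroids_, self.distance)["label"])
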