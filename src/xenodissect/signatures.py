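"""Gene-set scoring and cross-line signature analyses.

Implements the single-sample GSEA enrichment score: within one sample,
genes are ranked by expression (descending, ties broken by gene id); with
rank weights w_i = (N - position_i) raised to ``alpha``, the score is the
summed gap between the weighted in-set cumulative distribution and the
uniform out-of-set step,

    ES(S) = sum_i [ P_in(i) - P_out(i) ],
    P_in(i) = sum_{j<=i, j in S} w_j^alpha / sum_{j in S} w_j^alpha,
    P_out(i) = #{j<=i, j not in S} / (N - |S|).

Because the score depends on a sample's expression only through ranks, it is
invariant to any strictly monotone per-sample transform — in particular to
the overall scaling induced by a sample's species mixture.

Cross-line ranking: per PDX line, the difference of mean enrichment score in
metastases minus mammary tumors; summed over lines and sorted descending,
so gene sets consistently activated in metastases across lines rise to the
top.  Also here: mean-signature scoring, the >50%-reads sample filter, and
the ANOVA that attributes candidate metastasis-signature genes to the host
organ compartment when their mouse orthologs are upregulated in
metastasis-bearing versus normal organ.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedScoreError,
)
from .containers import ExpressionMatrix


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InvalidInputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def parse_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file: name, description, members...

    Duplicate members within a set are collapsed (first occurrence kept);
    a line with fewer than three fields is an error naming the line.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(
                    f"malformed GMT line {lineno}: fewer than 3 fields"
                )
            name = fields[0]
            if name in sets:
                raise InvalidInputError(f"duplicate gene set name {name!r} (line {lineno})")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise InvalidInputError(f"gene set {name!r} is empty (line {lineno})")
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def _ranked_order(values: np.ndarray, gene_rank: np.ndarray) -> np.ndarray:
    """Indices sorting genes by descending value, ties by gene id."""
    return np.lexsort((gene_rank, -values))


def ssgsea_score(
    expression: pd.Series, gene_set: list[str], alpha: float = 0.25
) -> float:
    """Single-sample enrichment score of one gene set in one sample."""
    genes = expression.index
    members = set(gene_set) & set(genes)
    if not members:
        raise UndefinedScoreError("no gene-set member present in the expression vector")
    n = len(genes)
    if len(members) == n:
        return 0.0
    gene_rank = np.argsort(np.argsort(genes.to_numpy()))
    order = _ranked_order(expression.to_numpy(dtype=float), gene_rank)
    mask = np.asarray(genes.isin(members))[order]
    w = (n - np.arange(n)).astype(float) ** alpha
    w_in = np.where(mask, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~mask) / (n - len(members))
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: ExpressionMatrix | pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Enrichment-score matrix, gene sets x samples.

    When ``normalize``, all scores are divided by (max - min) over the whole
    matrix.  Callers are expected to have applied the >50%-reads sample
    filter (:func:`sample_fraction_filter`) beforehand.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if len(collection) == 0:
        raise InvalidParameterError("empty gene-set collection")
    genes = values.index
    n = len(genes)
    gene_rank = np.argsort(np.argsort(genes.to_numpy()))
    masks = {}
    for name, members in collection:
        present = np.asarray(genes.isin(members))
        if not present.any():
            raise UndefinedScoreError(f"gene set {name!r} has no member in the matrix")
        masks[name] = present
    w_full = (n - np.arange(n)).astype(float) ** alpha
    out = np.empty((len(masks), values.shape[1]))
    arr = values.to_numpy(dtype=float)
    for j in range(arr.shape[1]):
        order = _ranked_order(arr[:, j], gene_rank)
        for i, (name, present) in enumerate(masks.items()):
            mask = present[order]
            n_in = int(mask.sum())
            if n_in == n:
                out[i, j] = 0.0
                continue
            w_in = np.where(mask, w_full, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~mask) / (n - n_in)
            out[i, j] = np.sum(p_in - p_out)
    es = pd.DataFrame(out, index=list(masks), columns=values.columns)
    if normalize:
        spread = float(out.max() - out.min())
        if spread > 0:
            es = es / spread
    return es


METASTASIS_TISSUES = ("met_liver", "met_lung", "met_brain")


def es_group_difference(
    es: pd.DataFrame,
    metadata: pd.DataFrame,
    group_met=METASTASIS_TISSUES,
    group_tumor=("MGT",),
    condition_col: str = "tissue",
) -> pd.DataFrame:
    """Per-line (mean ES in metastases - mean ES in mammary tumors).

    Returns sets x lines; lines missing either group are omitted.
    """
    group_met = [group_met] if isinstance(group_met, str) else list(group_met)
    group_tumor = [group_tumor] if isinstance(group_tumor, str) else list(group_tumor)
    meta = metadata.loc[[s for s in es.columns if s in metadata.index]]
    out = {}
    for line, sub in meta.groupby("line_id"):
        met = sub.index[sub[condition_col].isin(group_met)]
        tum = sub.index[sub[condition_col].isin(group_tumor)]
        if len(met) == 0 or len(tum) == 0:
            continue
        out[line] = es[met].mean(axis=1) - es[tum].mean(axis=1)
    return pd.DataFrame(out)


def sum_es_ranking(differences: pd.DataFrame) -> pd.DataFrame:
    """Sum per-set differences across lines; rank descending (ties by name)."""
    total = differences.sum(axis=1)
    out = differences.copy()
    out["sum_es"] = total
    out = out.sort_values(by="sum_es", ascending=False, kind="stable")
    out = out.loc[sorted(out.index, key=lambda s: (-out.loc[s, "sum_es"], s))]
    out["rank"] = np.arange(1, len(out) + 1)
    out["n_lines"] = differences.notna().sum(axis=1)
    return out


def mean_signature_score(
    expr: ExpressionMatrix | pd.DataFrame, gene_list: list[str]
) -> tuple[pd.Series, list[str]]:
    """Unweighted mean of the listed genes per sample; missing genes reported."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    present = [g for g in gene_list if g in values.index]
    missing = [g for g in gene_list if g not in values.index]
    if not present:
        raise InvalidInputError("no signature gene present in the matrix")
    return values.loc[present].mean(axis=0), missing


def map_to_host_genes(
    candidate_genes: list[str],
    host_genes: pd.Index,
    mapping: dict[str, str] | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Map candidate (human) symbols into the host (mouse) namespace.

    Case-insensitive symbol equality is the default ortholog proxy — human
    and mouse symbols usually differ only in capitalization; an explicit
    mapping overrides it.  Returns (mapped, unmapped).
    """
    if mapping is not None:
        mapped = {g: mapping[g] for g in candidate_genes if g in mapping}
    else:
        lower_host = {}
        for h in host_genes:
            lower_host.setdefault(str(h).lower(), h)
        mapped = {
            g: lower_host[g.lower()]
            for g in candidate_genes
            if g.lower() in lower_host
        }
    unmapped = [g for g in candidate_genes if g not in mapped]
    return mapped, unmapped


def anova_origin_filter(
    candidate_genes: list[str],
    host_expr: ExpressionMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    p_threshold: float = 0.05,
    direction: str = "up_in_a",
    mapping: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Attribute candidate signature genes to the host compartment.

    One-way ANOVA per mapped gene across the two host sample groups
    (e.g. metastasis-bearing liver vs normal liver); retained genes have
    p < ``p_threshold`` and group-A mean above group-B mean
    (``direction='up_in_a'``).  Genes absent from the host matrix are
    returned separately.
    """
    if direction not in ("up_in_a", "up_in_b"):
        raise InvalidParameterError("direction must be 'up_in_a' or 'up_in_b'")
    values = host_expr.values if isinstance(host_expr, ExpressionMatrix) else host_expr
    if len(group_a) < 2 or len(group_b) < 2:
        raise InvalidInputError("each group needs at least 2 samples")
    mapped, unmapped = map_to_host_genes(candidate_genes, values.index, mapping)
    rows = []
    for cand, host_gene in mapped.items():
        a = values.loc[host_gene, group_a].to_numpy(dtype=float)
        b = values.loc[host_gene, group_b].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
            f = np.inf if p == 0.0 else 0.0
        else:
            f, p = stats.f_oneway(a, b)
        rows.append((cand, host_gene, a.mean(), b.mean(), float(f), float(p)))
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "host_gene", "mean_a", "mean_b", "F", "pvalue"],
    ).set_index("gene_id")
    up = table["mean_a"] > table["mean_b"]
    if direction == "up_in_b":
        up = table["mean_b"] > table["mean_a"]
    retained = table[(table["pvalue"] < p_threshold) & up]
    return retained, unmapped


def sample_fraction_filter(
    metadata: pd.DataFrame, organism: str, min_pct: float = 50.0
) -> list[str]:
    """Samples with strictly more than ``min_pct`` percent of the organism's reads."""
    col = f"{organism}_pct"
    if col not in metadata.columns:
        raise InvalidInputError(f"metadata lacks column {col!r}")
    return list(metadata.index[metadata[col].astype(float) > min_pct])


class SSGSEATransformer:
    """Sklearn-style transformer: fit stores the collection, transform scores."""

    def __init__(self, alpha: float = 0.25, normalize: bool = True):
        self.alpha = alpha
        self.normalize = normalize

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "normalize": self.normalize}

    def set_params(self, **params) -> "SSGSEATransformer":
        for key, value in params.items():
            if key not in ("alpha", "normalize"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, collection: GeneSetCollection, y=None) -> "SSGSEATransformer":
        self.collection_ = collection
        return self

    def transform(self, expr) -> pd.DataFrame:
        if not hasattr(self, "collection_"):
            raise InvalidInputError("transformer is not fitted")
        return ssgsea_matrix(expr, self.collection_, self.alpha, self.normalize)
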