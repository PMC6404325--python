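"""Microenvironment-induced vs. metastasis-selected gene classification.

A triad is a matched sample triple from one PDX line: the parental mammary
gland tumor (MGT), a metastasis derived from it, and an MGT regrown from
cells of that metastasis.  Comparing the three separates two kinds of
expression change in the cancer cells: *transient* (microenvironment-
induced) genes rise in the metastasis but fall back to parental levels on
regrowth, while *selected* genes rise and stay up — evidence of clonal
selection rather than plastic response.

With fold changes FC1 = met/MGT and FC2 = regrown/MGT (group means on
linear TPM, pseudocount-guarded) and a cutoff t (default twofold):

    transient      FC1 >= t and FC2 < t
    selected       FC1 >= t and FC2 >= t
    down_transient FC1 <= 1/t and FC2 > 1/t
    down_selected  FC1 <= 1/t and FC2 <= 1/t
    unchanged      otherwise

The five classes partition the gene universe.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import InvalidParameterError, InvalidTriadError
from .containers import ExpressionMatrix

CLASSES = ("transient", "selected", "down_transient", "down_selected", "unchanged")

ROLES = ("parental_MGT", "metastasis", "MGT_from_met")


@dataclass
class Triad:
    """Sample groups for the three passage roles of one PDX line."""

    line_id: str
    parental_MGT: list[str]
    metastasis: list[str]
    MGT_from_met: list[str]

    def __post_init__(self) -> None:
        for role in ROLES:
            if not getattr(self, role):
                raise InvalidTriadError(f"triad {self.line_id}: no {role} samples")


def triads_from_metadata(metadata: pd.DataFrame) -> list[Triad]:
    """Assemble triads from a metadata frame carrying ``passage_role``."""
    out = []
    for line, sub in metadata.groupby("line_id"):
        groups = {
            role: list(sub.index[sub["passage_role"] == role]) for role in ROLES
        }
        if all(groups.values()):
            out.append(Triad(line, **groups))
    return out


def triad_fold_changes(
    expr: ExpressionMatrix | pd.DataFrame, triad: Triad, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene (fc_met, fc_regrown) relative to the parental MGT.

    Group means over replicate samples on linear-scale expression (TPM);
    the pseudocount guards division for unexpressed genes.
    """
    if pseudocount <= 0:
        raise InvalidParameterError("pseudocount must be positive")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if isinstance(expr, ExpressionMatrix) and "log2" in expr.transforms:
        raise InvalidParameterError("triad fold changes expect linear-scale expression")
    missing = [
        s
        for role in ROLES
        for s in getattr(triad, role)
        if s not in values.columns
    ]
    if missing:
        raise InvalidTriadError(f"triad samples absent from matrix: {missing}")
    mgt = values[triad.parental_MGT].mean(axis=1)
    met = values[triad.metastasis].mean(axis=1)
    regrown = values[triad.MGT_from_met].mean(axis=1)
    return pd.DataFrame(
        {
            "fc_met": (met + pseudocount) / (mgt + pseudocount),
            "fc_regrown": (regrown + pseudocount) / (mgt + pseudocount),
        }
    )


def classify_genes(fc_pairs: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Assign each gene exactly one of the five triad classes."""
    if threshold <= 1:
        raise InvalidParameterError("threshold must exceed 1")
    fc1 = fc_pairs["fc_met"].to_numpy(dtype=float)
    fc2 = fc_pairs["fc_regrown"].to_numpy(dtype=float)
    cls = np.full(len(fc_pairs), "unchanged", dtype=object)
    up = fc1 >= threshold
    down = fc1 <= 1.0 / threshold
    cls[up & (fc2 < threshold)] = "transient"
    cls[up & (fc2 >= threshold)] = "selected"
    cls[down & (fc2 > 1.0 / threshold)] = "down_transient"
    cls[down & (fc2 <= 1.0 / threshold)] = "down_selected"
    out = fc_pairs.copy()
    out["class"] = cls
    return out


def summarize_triads(
    classifications: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line class counts and the cross-line overlap of non-null calls.

    Returns ``(counts, overlap)`` where ``counts`` is lines x classes and
    ``overlap`` lists genes sharing the same non-``unchanged`` class in at
    least two lines.
    """
    counts = pd.DataFrame(
        0, index=sorted(classifications), columns=list(CLASSES), dtype=int
    )
    membership: dict[tuple[str, str], list[str]] = {}
    for line, table in classifications.items():
        vc = table["class"].value_counts()
        for cls in CLASSES:
            counts.loc[line, cls] = int(vc.get(cls, 0))
        for gene, cls in table["class"].items():
            if cls != "unchanged":
                membership.setdefault((gene, cls), []).append(line)
    rows = [
        (gene, cls, len(lines), sorted(lines))
        for (gene, cls), lines in membership.items()
        if len(lines) >= 2
    ]
    overlap = pd.DataFrame(
        rows, columns=["gene_id", "class", "n_lines", "lines"]
    ).sort_values(["n_lines", "gene_id"], ascending=[False, True], ignore_index=True)
    return counts, overlap
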