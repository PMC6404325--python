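"""In-memory containers for per-species expression data.

A xenograft sample is a mixture of two transcriptomes.  After species
separation, each organism gets its own genes x samples matrix; the two
matrices share sample columns.  ``CountMatrix`` holds raw per-gene read
counts plus effective gene lengths (needed for TPM); ``ExpressionMatrix``
holds real-valued expression with an append-only record of the transforms
applied to it, so downstream operations can assert they are receiving the
representation they expect (e.g. ssGSEA wants log2 TPM, triad fold changes
want linear TPM).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InvalidInputError

#: controlled vocabulary for the ``tissue`` metadata column
TISSUES = (
    "MGT",
    "met_liver",
    "met_lung",
    "met_brain",
    "normal_liver",
    "normal_lung",
    "normal_brain",
    "human_control",
)

#: controlled vocabulary for the ``passage_role`` metadata column
PASSAGE_ROLES = ("parental_MGT", "metastasis", "MGT_from_met", "none")

METADATA_COLUMNS = (
    "line_id",
    "tissue",
    "passage_role",
    "human_pct",
    "mouse_pct",
    "mapped_human_reads",
)


@dataclass
class CountMatrix:
    """Non-negative integer read counts for one organism.

    Parameters
    ----------
    counts
        genes x samples DataFrame of non-negative integers.
    lengths
        Per-gene effective length in bases, indexed like ``counts``.
    organism
        Organism label, e.g. ``"human"``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    organism: str

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise InvalidInputError("duplicate gene_ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise InvalidInputError("duplicate sample_ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("negative counts")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise InvalidInputError(
                f"no effective length for gene(s): {list(missing[:5])}"
            )
        self.lengths = self.lengths.loc[self.counts.index].astype(float)
        if (self.lengths <= 0).any():
            raise InvalidInputError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.lengths, self.organism)


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples expression with transform provenance."""

    values: pd.DataFrame
    organism: str
    transforms: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise InvalidInputError("duplicate gene_ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise InvalidInputError("duplicate sample_ids in expression matrix")
        self.transforms = tuple(self.transforms)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def last_transform(self) -> str | None:
        return self.transforms[-1] if self.transforms else None

    def with_values(self, values: pd.DataFrame, tag: str) -> "ExpressionMatrix":
        """Return a copy holding ``values`` with ``tag`` appended."""
        return ExpressionMatrix(values, self.organism, self.transforms + (tag,))


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata frame against the controlled vocabulary."""
    for col in METADATA_COLUMNS:
        if col not in metadata.columns:
            raise InvalidInputError(f"metadata missing column {col!r}")
    bad = set(metadata["tissue"]) - set(TISSUES)
    if bad:
        raise InvalidInputError(f"unknown tissue label(s): {sorted(bad)}")
    bad = set(metadata["passage_role"]) - set(PASSAGE_ROLES)
    if bad:
        raise InvalidInputError(f"unknown passage_role label(s): {sorted(bad)}")
    for col in ("human_pct", "mouse_pct"):
        vals = metadata[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 100)).any():
            raise InvalidInputError(f"{col} outside [0, 100]")
    return metadata


def as_float_array(df: pd.DataFrame) -> np.ndarray:
    return df.to_numpy(dtype=float)
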