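"""Species separation of mixed-organism reads via organism-unique k-mers.

The alignment step of a xenograft pipeline maps reads to a concatenated
human+mouse(+viral) reference whose sequence names carry organism prefixes,
keeping only uniquely-mapping reads; a read with a valid placement in more
than one organism is discarded.  This module reproduces those semantics at
desk scale with a canonical k-mer index: a read is assigned to an organism
only if it carries at least ``min_informative`` k-mers unique to that
organism and no informative k-mer of any other organism.  Reads with
evidence for two organisms are ``ambiguous``; reads with no informative
k-mer are ``unmapped``.

Per-sample species composition is the percentage of classified reads per
organism, computed over organism-assigned reads only — ambiguous and
unmapped reads (and any excluded organism, e.g. viral) never enter the
denominator.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._exceptions import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedCompositionError,
)
from .simulate import ReadSet, SpeciesReference, revcomp

AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"

#: sentinel organism for k-mers present in more than one organism
_SHARED = None


@dataclass
class KmerIndex:
    """Canonical k-mer -> (organism, gene) occupancy table.

    ``table[kmer]`` is ``(organism, gene_id)`` for organism-unique k-mers
    (``gene_id`` is None when the k-mer occurs in several genes of that
    organism) and ``(None, None)`` for k-mers shared between organisms.
    """

    k: int
    organisms: tuple[str, ...]
    table: dict[str, tuple[str | None, str | None]]

    @property
    def n_informative(self) -> int:
        return sum(1 for org, _ in self.table.values() if org is not None)


def canonical(kmer: str) -> str:
    """Strand-collapsed form: lexicographic min of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_kmer_index(references: list[SpeciesReference], k: int = 31) -> KmerIndex:
    """Index every canonical k-mer of every transcript.

    K-mers found in more than one organism are marked shared and carry no
    assignment information; organism-unique k-mers retain the gene they
    occur in (or None if several genes of the same organism share them).
    """
    if k % 2 == 0 or not 3 <= k <= 63:
        raise InvalidParameterError("k must be odd and within [3, 63]")
    table: dict[str, tuple[str | None, str | None]] = {}
    for ref in references:
        for t in ref.transcripts:
            if t.length < k:
                raise InvalidInputError(
                    f"transcript {t.transcript_id} shorter than k={k}"
                )
            seq = t.sequence
            rc = revcomp(seq)
            n = len(seq)
            for i in range(n - k + 1):
                fwd = seq[i : i + k]
                rev = rc[n - k - i : n - i]
                kmer = fwd if fwd <= rev else rev
                prev = table.get(kmer)
                if prev is None:
                    table[kmer] = (ref.organism, t.gene_id)
                else:
                    org, gene = prev
                    if org != ref.organism:
                        table[kmer] = (_SHARED, None)
                    elif gene != t.gene_id:
                        table[kmer] = (org, None)
    return KmerIndex(k, tuple(r.organism for r in references), table)


def _informative_hits(
    read: str, index: KmerIndex
) -> tuple[Counter, Counter]:
    """Count informative k-mer hits per organism and per gene."""
    k = index.k
    n = len(read)
    org_hits: Counter = Counter()
    gene_hits: Counter = Counter()
    if n < k:
        return org_hits, gene_hits
    table = index.table
    rc = revcomp(read)
    for i in range(n - k + 1):
        fwd = read[i : i + k]
        rev = rc[n - k - i : n - i]
        rec = table.get(fwd if fwd <= rev else rev)
        if rec is None:
            continue
        org, gene = rec
        if org is None:
            continue
        org_hits[org] += 1
        if gene is not None:
            gene_hits[(org, gene)] += 1
    return org_hits, gene_hits


def classify_read(read: str, index: KmerIndex, min_informative: int = 2) -> str:
    """Assign a read to an organism, ``ambiguous`` or ``unmapped``.

    A read belongs to an organism only when that organism alone has
    informative hits and it has at least ``min_informative`` of them;
    informative evidence for two or more organisms discards the read as
    ambiguous (unique-mapping semantics).
    """
    if min_informative < 1:
        raise InvalidParameterError("min_informative must be >= 1")
    org_hits, _ = _informative_hits(read, index)
    return _label_from_hits(org_hits, min_informative)


def _label_from_hits(org_hits: Counter, min_informative: int) -> str:
    if not org_hits:
        return UNMAPPED
    if len(org_hits) > 1:
        return AMBIGUOUS
    org, n = next(iter(org_hits.items()))
    return org if n >= min_informative else UNMAPPED


@dataclass
class PartitionResult:
    """Per-read labels plus per-class and per-gene read counts."""

    labels: list[str]
    class_counts: dict[str, int]
    gene_counts: dict[str, Counter] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return sum(self.class_counts.values())

    def merge(self, other: "PartitionResult") -> "PartitionResult":
        """Additive merge of two runs of the same sample (re-sequencing)."""
        counts = Counter(self.class_counts)
        counts.update(other.class_counts)
        genes = {org: Counter(c) for org, c in self.gene_counts.items()}
        for org, c in other.gene_counts.items():
            genes.setdefault(org, Counter()).update(c)
        return PartitionResult(self.labels + other.labels, dict(counts), genes)


def partition_readset(
    reads: ReadSet | list[str], index: KmerIndex, min_informative: int = 2
) -> PartitionResult:
    """Classify every read; attribute assigned reads to genes by plurality.

    An assigned read's gene-level count goes to the gene owning the
    plurality of its informative k-mer hits; ties leave the read counted at
    organism level only.
    """
    if len(index.organisms) < 2:
        raise InvalidInputError("index must cover at least two organisms")
    if min_informative < 1:
        raise InvalidParameterError("min_informative must be >= 1")
    seqs = reads.sequences if isinstance(reads, ReadSet) else reads
    mates = reads.mates if isinstance(reads, ReadSet) else None
    labels = []
    class_counts: Counter = Counter({org: 0 for org in index.organisms})
    class_counts[AMBIGUOUS] = 0
    class_counts[UNMAPPED] = 0
    gene_counts: dict[str, Counter] = {org: Counter() for org in index.organisms}
    for i, seq in enumerate(seqs):
        org_hits, gene_hits = _informative_hits(seq, index)
        label = _label_from_hits(org_hits, min_informative)
        if mates is not None:
            m_org, m_gene = _informative_hits(mates[i], index)
            m_label = _label_from_hits(m_org, min_informative)
            # mates classified independently; fragment label = agreement
            if label != m_label:
                label = AMBIGUOUS if UNMAPPED not in (label, m_label) else (
                    m_label if label == UNMAPPED else label
                )
            for key, v in m_gene.items():
                gene_hits[key] += v
        labels.append(label)
        class_counts[label] += 1
        if label in gene_counts:
            votes = [(v, g) for (org, g), v in gene_hits.items() if org == label]
            if votes:
                best = max(v for v, _ in votes)
                winners = [g for v, g in votes if v == best]
                if len(winners) == 1:
                    gene_counts[label][winners[0]] += 1
    return PartitionResult(labels, dict(class_counts), gene_counts)


@dataclass
class SampleComposition:
    """Per-organism percentage of classified reads."""

    percentages: dict[str, float]
    counts_used: dict[str, int]

    def pct(self, organism: str) -> float:
        return self.percentages[organism]


def composition_stats(
    partition: PartitionResult, exclude: set[str] | None = None
) -> SampleComposition:
    """Species percentages over retained organism-assigned reads.

    ``exclude`` removes organisms (e.g. a viral reference) from the
    denominator; ambiguous and unmapped reads never enter it.
    """
    exclude = set(exclude or ())
    organisms = [
        org
        for org in partition.class_counts
        if org not in (AMBIGUOUS, UNMAPPED) and org not in exclude
    ]
    unknown = exclude - set(partition.class_counts)
    if unknown:
        raise InvalidParameterError(f"excluded label(s) not present: {sorted(unknown)}")
    counts = {org: partition.class_counts[org] for org in organisms}
    total = sum(counts.values())
    if total == 0:
        raise UndefinedCompositionError("no classified reads; composition undefined")
    return SampleComposition(
        {org: 100.0 * c / total for org, c in counts.items()}, counts
    )


def composition_table(
    partitions: dict[str, PartitionResult], exclude: set[str] | None = None
) -> pd.DataFrame:
    """Per-sample composition table (columns ``<organism>_pct``)."""
    rows = {}
    for sample, part in partitions.items():
        comp = composition_stats(part, exclude)
        rows[sample] = {f"{org}_pct": p for org, p in comp.percentages.items()}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


class KmerSpeciesClassifier:
    """Scikit-learn style wrapper around the k-mer partitioner.

    Parameters
    ----------
    k : odd int, default 31
        K-mer length.
    min_informative : int, default 2
        Minimum organism-unique k-mer hits required for assignment.
    """

    def __init__(self, k: int = 31, min_informative: int = 2):
        self.k = k
        self.min_informative = min_informative

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "min_informative": self.min_informative}

    def set_params(self, **params) -> "KmerSpeciesClassifier":
        for key, value in params.items():
            if key not in ("k", "min_informative"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, references: list[SpeciesReference], y=None) -> "KmerSpeciesClassifier":
        self.index_ = build_kmer_index(references, self.k)
        self.classes_ = list(self.index_.organisms) + [AMBIGUOUS, UNMAPPED]
        return self

    def predict(self, reads: ReadSet | list[str]) -> list[str]:
        if not hasattr(self, "index_"):
            raise InvalidInputError("classifier is not fitted")
        return partition_readset(reads, self.index_, self.min_informative).labels
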