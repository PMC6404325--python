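"""File-format plumbing: FASTA/FASTQ via Biopython, TSV via pandas.

Conventions: count and expression matrices are TSV with gene_id rows and a
sample_id header row; metadata is one TSV row per sample with the
controlled-vocabulary ``tissue`` column; reference FASTA sequence names are
``<prefix>|<transcript_id>`` with a ``gene=<gene_id>`` tag in the
description.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._exceptions import InvalidInputError
from .containers import CountMatrix, ExpressionMatrix, validate_metadata
from .simulate import ReadSet, SpeciesReference, Transcript


def write_fasta(reference: SpeciesReference, path) -> None:
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=reference.sequence_name(t),
            description=f"gene={t.gene_id}",
        )
        for t in reference.transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_reference(path, organism: str, prefix: str | None = None) -> SpeciesReference:
    """Load a reference written by :func:`write_fasta`.

    The organism prefix is taken from sequence names (``prefix|transcript``);
    the gene id from the ``gene=`` description tag, defaulting to the
    transcript id.
    """
    transcripts = []
    seen_prefix = prefix
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            pfx, tid = rec.id.split("|", 1)
        else:
            pfx, tid = prefix or "", rec.id
        if seen_prefix is None:
            seen_prefix = pfx
        elif pfx and pfx != seen_prefix:
            raise InvalidInputError(
                f"mixed organism prefixes in {path}: {seen_prefix!r} vs {pfx!r}"
            )
        gene = tid
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        transcripts.append(Transcript(tid, gene, str(rec.seq).upper()))
    if not transcripts:
        raise InvalidInputError(f"no sequences in {path}")
    return SpeciesReference(organism, seen_prefix or "", transcripts)


def write_fastq(readset: ReadSet, path, mate_path=None) -> None:
    Path(path).write_text(readset.to_fastq())
    if readset.mates is not None and mate_path is not None:
        mates = ReadSet(readset.sample_id, readset.ids, readset.mates)
        Path(mate_path).write_text(mates.to_fastq())


def read_fastq(path, sample_id: str | None = None) -> ReadSet:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return ReadSet(sample_id or Path(path).stem, ids, seqs)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts(path, lengths_path=None, organism: str = "human") -> CountMatrix:
    """Counts TSV (gene_id x sample_id); lengths from a 2-column TSV or a
    ``length`` column inside the counts file."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    elif "length" in df.columns:
        lengths = df.pop("length")
    else:
        raise InvalidInputError("gene lengths required (length column or TSV)")
    return CountMatrix(df.astype(int), lengths.astype(float), organism)


def read_expression(path, organism: str = "human", transforms=("TPM",)) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float), organism, tuple(transforms))


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(meta)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t")


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na"] + list(members)) + "\n")
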