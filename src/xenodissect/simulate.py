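"""Synthetic xenograft cohorts with known ground truth.

Bulk RNA-seq of a patient-derived xenograft (PDX) is a two-species mixture:
human reads from the engrafted cancer cells and mouse reads from the organ
microenvironment.  This module generates the pieces such a study produces —
a pair of species references, mixed-species read sets, per-species count
matrices, and sample metadata — together with a truth table recording every
planted quantity, so that every downstream stage (species partitioning,
per-species TPM, composition-adjusted differential expression, signature
ranking, triad classification) can be tested against known answers.

The default cohort shapes mirror a PDX metastasis study: mammary gland
tumors (MGT) that are mostly human (72-91%), metastases whose human content
spans almost the full range because of adjacent normal organ tissue, normal
mouse organs, and pure-human controls.  Counts follow a gamma-Poisson
(negative binomial) model: the expected count of gene g in sample s is

    mu[g, s] = base_g * effect_{g, cond(s)} * 2**(slope_g * (pct_s - mean_pct))
               * fraction_s(organism) * library_size_s

where ``base_g`` are per-gene relative abundances, ``effect`` holds planted
condition fold changes, ``slope_g`` an optional per-gene dependence on the
sample's species percentage (the composition confound the "percent"
covariate of the DE stage exists to absorb), and ``fraction_s`` the
organism's share of the sample.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._exceptions import InvalidParameterError
from .containers import PASSAGE_ROLES, TISSUES, CountMatrix

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype="S1")

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SpeciesReference:
    """One organism's transcriptome with organism-prefixed sequence names."""

    organism: str
    prefix: str
    transcripts: list[Transcript]
    ortholog_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tids = [t.transcript_id for t in self.transcripts]
        if len(set(tids)) != len(tids):
            raise InvalidParameterError("duplicate transcript_id within reference")
        targets = list(self.ortholog_map.values())
        if len(set(targets)) != len(targets):
            raise InvalidParameterError("ortholog_map is not one-to-one")

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.transcripts]

    def sequence_name(self, transcript: Transcript) -> str:
        return f"{self.prefix}|{transcript.transcript_id}"

    def to_fasta(self) -> str:
        out = io.StringIO()
        for t in self.transcripts:
            out.write(f">{self.sequence_name(t)} gene={t.gene_id}\n")
            for i in range(0, len(t.sequence), 70):
                out.write(t.sequence[i : i + 70] + "\n")
        return out.getvalue()


def _gene_ids(organism: str, n_genes: int, n_orthologs: int) -> list[str]:
    """Gene identifiers; ortholog pairs share a symbol up to case.

    Human/mouse gene symbols differ by capitalization convention (S100A9 vs
    S100a9); shared symbols are emulated the same way so that the default
    case-insensitive ortholog mapping of the signature stage works on
    simulated data.
    """
    shared = [f"G{i:05d}" for i in range(n_orthologs)]
    if organism == "mouse":
        shared = [g.lower() for g in shared]
        own = [f"mg{i:05d}" for i in range(n_genes - n_orthologs)]
    else:
        own = [f"{organism[:1].upper()}G{i:05d}" for i in range(n_genes - n_orthologs)]
    return shared + own


def generate_reference(
    n_genes: int,
    n_orthologs: int,
    divergence: float,
    transcript_length: int,
    seed: int,
    organisms: tuple[str, str] = ("human", "mouse"),
    prefixes: tuple[str, str] = ("hsa", "mmu"),
) -> tuple[SpeciesReference, SpeciesReference]:
    """Generate a pair of single-transcript-per-gene references.

    The first ``n_orthologs`` genes form ortholog pairs: the second
    organism's copy differs from the first at a Binomial(length, divergence)
    number of positions.  All other sequences are independent uniform-random
    nucleotides.  Deterministic for a fixed ``seed``.
    """
    if not 0 < divergence < 1:
        raise InvalidParameterError("divergence must lie in (0, 1)")
    if n_orthologs > n_genes:
        raise InvalidParameterError("n_orthologs cannot exceed n_genes")
    if transcript_length < 22:
        raise InvalidParameterError(
            "transcript_length too short for any informative k-mer"
        )
    rng = np.random.default_rng(seed)
    refs = []
    gene_lists = [_gene_ids(org, n_genes, n_orthologs) for org in organisms]
    seqs_a = None
    for which, (org, prefix, genes) in enumerate(zip(organisms, prefixes, gene_lists)):
        seqs = []
        for i, gene in enumerate(genes):
            if which == 1 and i < n_orthologs:
                base = np.frombuffer(seqs_a[i].encode(), dtype="S1").copy()
                n_mut = rng.binomial(transcript_length, divergence)
                pos = rng.choice(transcript_length, size=n_mut, replace=False)
                for p in pos:
                    choices = NUCLEOTIDES[NUCLEOTIDES != base[p]]
                    base[p] = rng.choice(choices)
                seq = base.tobytes().decode()
            else:
                seq = (
                    NUCLEOTIDES[rng.integers(0, 4, transcript_length)]
                    .tobytes()
                    .decode()
                )
            seqs.append(seq)
        if which == 0:
            seqs_a = seqs
        transcripts = [
            Transcript(f"{g}_t1", g, s) for g, s in zip(genes, seqs)
        ]
        refs.append(SpeciesReference(org, prefix, transcripts))
    # record the pairing on both references
    a, b = refs
    a.ortholog_map = {
        ga: gb for ga, gb in zip(gene_lists[0][:n_orthologs], gene_lists[1][:n_orthologs])
    }
    b.ortholog_map = {v: k for k, v in a.ortholog_map.items()}
    return a, b


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


@dataclass
class SampleSpec:
    sample_id: str
    line_id: str
    tissue: str
    passage_role: str = "none"
    human_fraction: float = 0.8
    library_size: int = 300_000


@dataclass
class SimDesign:
    """Full specification of a simulated cohort.

    ``effects`` maps organism -> DataFrame (genes x condition labels) of
    linear fold multipliers; missing genes/conditions default to 1.
    ``percent_slopes`` maps organism -> per-gene log2 change per percentage
    point of that organism's read share, centered at the cohort mean.
    """

    n_genes: dict[str, int]
    samples: list[SampleSpec]
    effects: dict[str, pd.DataFrame] = field(default_factory=dict)
    percent_slopes: dict[str, pd.Series] = field(default_factory=dict)
    dispersion: float = 0.1
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    n_orthologs: int = 0
    seed: int = 0
    organisms: tuple[str, str] = ("human", "mouse")

    def validate(self) -> None:
        if not self.samples:
            raise InvalidParameterError("empty sample plan")
        if self.dispersion <= 0:
            raise InvalidParameterError("dispersion must be positive")
        for s in self.samples:
            if not 0.0 <= s.human_fraction <= 1.0:
                raise InvalidParameterError(
                    f"human_fraction of {s.sample_id} outside [0, 1]"
                )
            if s.tissue not in TISSUES:
                raise InvalidParameterError(f"unknown tissue {s.tissue!r}")
            if s.passage_role not in PASSAGE_ROLES:
                raise InvalidParameterError(f"unknown passage_role {s.passage_role!r}")
        universe = set()
        for org in self.organisms:
            universe |= set(self.gene_ids(org))
        for name, members in self.gene_sets.items():
            if not set(members) <= universe:
                raise InvalidParameterError(f"gene set {name!r} outside gene universe")

    def gene_ids(self, organism: str) -> list[str]:
        return _gene_ids(organism, self.n_genes[organism], self.n_orthologs)

    def fraction(self, sample: SampleSpec, organism: str) -> float:
        return sample.human_fraction if organism == "human" else 1.0 - sample.human_fraction

    def condition(self, sample: SampleSpec, organism: str) -> str:
        """Condition label driving planted effects.

        On the cancer (human) side the passage role dominates when set, so
        triads can plant transient/selected programs; on the host (mouse)
        side the tissue is the condition.
        """
        if organism == "human" and sample.passage_role != "none":
            return sample.passage_role
        return sample.tissue


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort."""

    sample_fractions: pd.Series
    effects: dict[str, pd.DataFrame]
    percent_slopes: dict[str, pd.Series]
    gene_sets: dict[str, list[str]]
    read_origins: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class ReadSet:
    sample_id: str
    ids: list[str]
    sequences: list[str]
    mates: list[str] | None = None

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fastq(self) -> str:
        out = io.StringIO()
        qual = None
        for rid, seq in zip(self.ids, self.sequences):
            if qual is None or len(qual) != len(seq):
                qual = "I" * len(seq)
            out.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        return out.getvalue()


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _base_abundance(rng: np.random.Generator, n: int) -> np.ndarray:
    prop = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    return prop / prop.sum()


def _expected_means(
    design: SimDesign, organism: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Expected count matrix (genes x samples) and gene lengths."""
    genes = design.gene_ids(organism)
    base = _base_abundance(rng, len(genes))
    lengths = pd.Series(rng.integers(500, 3001, len(genes)), index=genes, dtype=float)
    eff = design.effects.get(organism)
    slopes = design.percent_slopes.get(organism)
    pcts = np.array([100.0 * design.fraction(s, organism) for s in design.samples])
    mean_pct = pcts.mean()
    cols = {}
    for s, pct in zip(design.samples, pcts):
        mu = base * design.fraction(s, organism) * s.library_size
        cond = design.condition(s, organism)
        if eff is not None and cond in eff.columns:
            fold = eff[cond].reindex(genes).fillna(1.0).to_numpy()
            mu = mu * fold
        if slopes is not None:
            sl = slopes.reindex(genes).fillna(0.0).to_numpy()
            mu = mu * np.exp2(sl * (pct - mean_pct))
        cols[s.sample_id] = mu
    return pd.DataFrame(cols, index=genes), lengths


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu**2."""
    if dispersion < 1e-8:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    design: SimDesign,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, SimTruth]:
    """Draw per-species count matrices and metadata from a design."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    matrices = {}
    for organism in design.organisms:
        means, lengths = _expected_means(design, organism, rng)
        counts = pd.DataFrame(
            _nb_draw(rng, means.to_numpy(), design.dispersion),
            index=means.index,
            columns=means.columns,
        )
        matrices[organism] = CountMatrix(counts, lengths, organism)
    human, mouse = (matrices[o] for o in design.organisms)
    metadata = pd.DataFrame(
        {
            "line_id": [s.line_id for s in design.samples],
            "tissue": [s.tissue for s in design.samples],
            "passage_role": [s.passage_role for s in design.samples],
            "human_pct": [100.0 * s.human_fraction for s in design.samples],
            "mouse_pct": [100.0 * (1 - s.human_fraction) for s in design.samples],
            "mapped_human_reads": human.counts.sum(axis=0).to_numpy(),
            "library_size": [s.library_size for s in design.samples],
        },
        index=pd.Index([s.sample_id for s in design.samples], name="sample_id"),
    )
    truth = SimTruth(
        sample_fractions=pd.Series(
            {s.sample_id: s.human_fraction for s in design.samples}
        ),
        effects=design.effects,
        percent_slopes=design.percent_slopes,
        gene_sets=design.gene_sets,
    )
    return human, mouse, metadata, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def simulate_reads(
    design: SimDesign,
    references: tuple[SpeciesReference, SpeciesReference],
    read_length: int = 100,
    paired: bool = False,
    error_rate: float = 0.0,
) -> tuple[dict[str, ReadSet], SimTruth]:
    """Draw reads as uniform substrings of expression-weighted transcripts.

    Each read's organism is chosen with the sample's species fraction, the
    transcript proportional to that organism's per-gene expected expression,
    the start uniformly, and the strand at random.  Per-read origin labels
    are recorded in the truth table.  ``library_size`` of each sample is the
    number of fragments drawn.
    """
    design.validate()
    min_len = min(t.length for ref in references for t in ref.transcripts)
    if read_length > min_len:
        raise InvalidParameterError(
            f"read_length {read_length} exceeds shortest transcript ({min_len})"
        )
    rng = np.random.default_rng(design.seed)
    org_names = [r.organism for r in references]
    weights = {}
    seqs = {}
    tlens = {}
    for ref in references:
        means, _ = _expected_means(design, ref.organism, rng)
        weights[ref.organism] = means
        seqs[ref.organism] = [t.sequence for t in ref.transcripts]
        tlens[ref.organism] = np.array([t.length for t in ref.transcripts])
    readsets: dict[str, ReadSet] = {}
    origins: dict[str, pd.DataFrame] = {}
    for s in design.samples:
        n = s.library_size
        frac_a = design.fraction(s, org_names[0])
        n_a = rng.binomial(n, frac_a)
        per_org = {org_names[0]: n_a, org_names[1]: n - n_a}
        ids, reads, mates, org_lab, gene_lab = [], [], [], [], []
        for ref in references:
            organism = ref.organism
            n_o = per_org[organism]
            if n_o == 0:
                continue
            w = weights[organism][s.sample_id].to_numpy()
            total = w.sum()
            if total <= 0:
                per_org[org_names[0] if organism == org_names[1] else org_names[1]] += n_o
                continue
            idx = rng.choice(len(w), size=n_o, p=w / total)
            genes = weights[organism].index.to_numpy()
            tl = tlens[organism][idx]
            frag_lens = (
                np.minimum(2 * read_length, tl)
                if paired
                else np.full(n_o, read_length)
            )
            starts = (rng.random(n_o) * (tl - frag_lens + 1)).astype(np.int64)
            flips = rng.random(n_o) < 0.5
            org_seqs = seqs[organism]
            for j in range(n_o):
                frag = org_seqs[idx[j]][starts[j] : starts[j] + frag_lens[j]]
                if paired:
                    r1, r2 = frag[:read_length], revcomp(frag[-read_length:])
                else:
                    r1 = frag if flips[j] else revcomp(frag)
                    r2 = None
                if error_rate > 0:
                    r1 = _add_errors(rng, r1, error_rate)
                    if r2 is not None:
                        r2 = _add_errors(rng, r2, error_rate)
                ids.append(f"{s.sample_id}_r{len(ids)}")
                reads.append(r1)
                if paired:
                    mates.append(r2)
                org_lab.append(organism)
                gene_lab.append(genes[idx[j]])
        readsets[s.sample_id] = ReadSet(
            s.sample_id, ids, reads, mates if paired else None
        )
        origins[s.sample_id] = pd.DataFrame(
            {"read_id": ids, "organism": org_lab, "gene_id": gene_lab}
        )
    truth = SimTruth(
        sample_fractions=pd.Series(
            {s.sample_id: s.human_fraction for s in design.samples}
        ),
        effects=design.effects,
        percent_slopes=design.percent_slopes,
        gene_sets=design.gene_sets,
        read_origins=origins,
    )
    return readsets, truth


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for p in hits:
        choices = NUCLEOTIDES[NUCLEOTIDES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------


@dataclass
class CohortFixture:
    preset: str
    design: SimDesign
    truth: SimTruth
    metadata: pd.DataFrame
    references: tuple[SpeciesReference, SpeciesReference] | None = None
    readsets: dict[str, ReadSet] | None = None
    counts_human: CountMatrix | None = None
    counts_mouse: CountMatrix | None = None


PRESET_SEEDS = {
    "partition_demo": 11,
    "de_demo": 12,
    "triad_demo": 13,
    "signature_demo": 14,
}


def _effect_frame(genes, planted: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Build a fold-change table from {condition: {gene: fold}}."""
    eff = pd.DataFrame(1.0, index=pd.Index(genes), columns=sorted(planted))
    for cond, d in planted.items():
        for g, f in d.items():
            eff.loc[g, cond] = f
    return eff


def build_cohort_fixture(
    preset_name: str, seed: int | None = None, **overrides
) -> CohortFixture:
    """Deterministic small cohorts for each downstream stage.

    Presets
    -------
    partition_demo
        Two divergence-0.10 references and four mixed-species read sets with
        per-read truth labels.
    de_demo
        Counts-level single-line cohort: 6 MGT vs 6 liver metastases with the
        human fraction systematically lower in metastases, 50 genes planted
        at 4-fold up in metastases, and 300 null genes whose expression
        depends on the human percentage (the composition confound).
    triad_demo
        Three PDX lines, each with parental MGT / metastasis / regrown-MGT
        sample groups (3 replicates each); 30 planted transient and 30
        planted selected genes, disjoint.
    signature_demo
        Six lines with MGT and metastasis samples, one planted pan-line
        metastasis gene set and 100 decoy sets.
    """
    if preset_name not in PRESET_SEEDS:
        raise InvalidParameterError(f"unknown preset {preset_name!r}")
    if seed is None:
        seed = PRESET_SEEDS[preset_name]
    builder = {
        "partition_demo": _partition_demo,
        "de_demo": _de_demo,
        "triad_demo": _triad_demo,
        "signature_demo": _signature_demo,
    }[preset_name]
    return builder(seed, **overrides)


def _partition_demo(
    seed: int,
    n_reads: int = 5000,
    n_genes: int = 60,
    n_orthologs: int = 20,
    divergence: float = 0.10,
    transcript_length: int = 300,
    read_length: int = 100,
    error_rate: float = 0.0,
    paired: bool = False,
) -> CohortFixture:
    refs = generate_reference(
        n_genes, n_orthologs, divergence, transcript_length, seed=seed
    )
    fracs = [0.8, 0.5, 0.2, 0.99]
    tissues = ["MGT", "met_liver", "met_brain", "human_control"]
    samples = [
        SampleSpec(f"S{i+1}", "HCI10", t, human_fraction=f, library_size=n_reads)
        for i, (t, f) in enumerate(zip(tissues, fracs))
    ]
    design = SimDesign(
        n_genes={"human": n_genes, "mouse": n_genes},
        samples=samples,
        n_orthologs=n_orthologs,
        dispersion=0.1,
        seed=seed,
    )
    readsets, truth = simulate_reads(
        design, refs, read_length=read_length, paired=paired, error_rate=error_rate
    )
    _, _, metadata, _ = simulate_counts(design)
    return CohortFixture(
        "partition_demo", design, truth, metadata, references=refs, readsets=readsets
    )


def _de_demo(
    seed: int,
    n_genes: int = 2000,
    n_per_group: int = 6,
    n_planted: int = 50,
    planted_fold: float = 4.0,
    slope_sd: float = 0.02,
    library_size: int = 1_000_000,
    dispersion: float = 0.05,
    confounded: bool = True,
) -> CohortFixture:
    rng = np.random.default_rng(seed)
    genes = _gene_ids("human", n_genes, 0)
    planted = list(rng.choice(genes, size=n_planted, replace=False))
    rest = [g for g in genes if g not in set(planted)]
    effects = {
        "human": _effect_frame(genes, {"met_liver": {g: planted_fold for g in planted}})
    }
    # composition-dependent expression bleed: every non-planted gene's
    # human-side abundance drifts weakly with the sample's human percentage
    slopes = pd.Series(0.0, index=pd.Index(genes))
    if confounded:
        slopes.loc[rest] = rng.normal(0.0, slope_sd, size=len(rest))
    # MGT human fractions span the 72-91% range typical of mammary tumors;
    # liver metastases span a much wider range with a systematically lower
    # mean, so percent and condition are correlated but not separable.  The
    # spreads are realized deterministically (evenly spaced) because the
    # composition spread is a fixed property of the cohort being emulated;
    # i.i.d. draws would occasionally produce a nearly separating design in
    # which the composition-adjusted model is unidentifiable.
    mgt_fracs = np.linspace(0.72, 0.91, n_per_group)
    met_fracs = (
        np.linspace(0.2, 0.9, n_per_group)
        if confounded
        else np.linspace(0.72, 0.91, n_per_group)
    )
    samples = [
        SampleSpec(f"MGT{i+1}", "HCI10", "MGT", human_fraction=f, library_size=library_size)
        for i, f in enumerate(mgt_fracs)
    ] + [
        SampleSpec(
            f"MET{i+1}", "HCI10", "met_liver", human_fraction=f, library_size=library_size
        )
        for i, f in enumerate(met_fracs)
    ]
    design = SimDesign(
        n_genes={"human": n_genes, "mouse": 200},
        samples=samples,
        effects=effects,
        percent_slopes={"human": slopes},
        dispersion=dispersion,
        gene_sets={"planted_up_met": planted},
        seed=seed,
    )
    ch, cm, metadata, truth = simulate_counts(design)
    return CohortFixture(
        "de_demo", design, truth, metadata, counts_human=ch, counts_mouse=cm
    )


def _triad_demo(
    seed: int,
    n_genes: int = 1000,
    n_lines: int = 3,
    n_replicates: int = 3,
    n_transient: int = 30,
    n_selected: int = 30,
    planted_fold: float = 4.0,
    dispersion: float = 1e-9,
    library_size: int = 3_000_000,
) -> CohortFixture:
    rng = np.random.default_rng(seed)
    genes = _gene_ids("human", n_genes, 0)
    chosen = rng.choice(genes, size=n_transient + n_selected, replace=False)
    transient = list(chosen[:n_transient])
    selected = list(chosen[n_transient:])
    effects = {
        "human": _effect_frame(
            genes,
            {
                "metastasis": {g: planted_fold for g in transient + selected},
                "MGT_from_met": {g: planted_fold for g in selected},
            },
        )
    }
    samples = []
    roles = [
        ("parental_MGT", "MGT", 0.82),
        ("metastasis", "met_liver", 0.4),
        ("MGT_from_met", "MGT", 0.82),
    ]
    for li in range(n_lines):
        line = f"LINE{li+1}"
        for role, tissue, frac in roles:
            for r in range(n_replicates):
                samples.append(
                    SampleSpec(
                        f"{line}_{role}_{r+1}",
                        line,
                        tissue,
                        passage_role=role,
                        human_fraction=frac,
                        library_size=library_size,
                    )
                )
    design = SimDesign(
        n_genes={"human": n_genes, "mouse": 200},
        samples=samples,
        effects=effects,
        dispersion=dispersion,
        gene_sets={"planted_transient": transient, "planted_selected": selected},
        seed=seed,
    )
    ch, cm, metadata, truth = simulate_counts(design)
    return CohortFixture(
        "triad_demo", design, truth, metadata, counts_human=ch, counts_mouse=cm
    )


def _signature_demo(
    seed: int,
    n_genes: int = 800,
    n_lines: int = 6,
    n_per_group: int = 2,
    set_size: int = 30,
    n_decoys: int = 100,
    planted_fold: float = 3.0,
    dispersion: float = 0.1,
) -> CohortFixture:
    rng = np.random.default_rng(seed)
    genes = _gene_ids("human", n_genes, 0)
    planted = list(rng.choice(genes, size=set_size, replace=False))
    gene_sets = {"PLANTED_METASTASIS_PROGRAM": planted}
    rest = [g for g in genes if g not in set(planted)]
    for d in range(n_decoys):
        gene_sets[f"DECOY_{d:03d}"] = list(
            rng.choice(rest, size=set_size, replace=False)
        )
    effects = {
        "human": _effect_frame(genes, {"met_liver": {g: planted_fold for g in planted}})
    }
    samples = []
    for li in range(n_lines):
        line = f"PDX{li+1}"
        for r in range(n_per_group):
            samples.append(
                SampleSpec(
                    f"{line}_MGT_{r+1}", line, "MGT", human_fraction=0.8,
                    library_size=300_000,
                )
            )
            samples.append(
                SampleSpec(
                    f"{line}_MET_{r+1}", line, "met_liver", human_fraction=0.55,
                    library_size=300_000,
                )
            )
    design = SimDesign(
        n_genes={"human": n_genes, "mouse": 200},
        samples=samples,
        effects=effects,
        dispersion=dispersion,
        gene_sets=gene_sets,
        seed=seed,
    )
    ch, cm, metadata, truth = simulate_counts(design)
    return CohortFixture(
        "signature_demo", design, truth, metadata, counts_human=ch, counts_mouse=cm
    )


def build_origin_attribution_fixture(
    seed: int = 15,
    n_candidates_cancer: int = 150,
    n_candidates_host: int = 21,
    n_met: int = 19,
    n_normal: int = 3,
    host_fold: float = 4.0,
    dispersion: float = 0.1,
) -> tuple[CountMatrix, pd.DataFrame, list[str], list[str]]:
    """Host-organ attribution fixture for the signature-origin ANOVA.

    Emulates testing a human metastasis signature against the mouse liver
    transcriptome: a candidate list mixes cancer-origin genes (orthologs
    present in the mouse matrix but flat across liver groups) with planted
    host-origin genes upregulated in metastasis-bearing liver.  Returns the
    mouse count matrix, its metadata, and the two candidate sublists (human
    symbol spelling).
    """
    n_shared = n_candidates_cancer + n_candidates_host
    n_mouse = n_shared + 200
    rng = np.random.default_rng(seed)
    mouse_genes = _gene_ids("mouse", n_mouse, n_shared)
    shared = mouse_genes[:n_shared]
    host = list(rng.choice(shared, size=n_candidates_host, replace=False))
    cancer = [g for g in shared if g not in set(host)]
    effects = {"mouse": _effect_frame(mouse_genes, {"met_liver": {g: host_fold for g in host}})}
    samples = [
        SampleSpec(
            f"LIVMET{i+1}", f"PDX{i % 7 + 1}", "met_liver", human_fraction=0.3,
            library_size=300_000,
        )
        for i in range(n_met)
    ] + [
        SampleSpec(
            f"NLIV{i+1}", "mouse", "normal_liver", human_fraction=0.0,
            library_size=300_000,
        )
        for i in range(n_normal)
    ]
    design = SimDesign(
        n_genes={"human": n_shared, "mouse": n_mouse},
        samples=samples,
        effects=effects,
        dispersion=dispersion,
        n_orthologs=n_shared,
        seed=seed,
    )
    _, counts_mouse, metadata, _ = simulate_counts(design)
    # candidate lists use the human capitalization convention
    return (
        counts_mouse,
        metadata,
        [g.upper() for g in cancer],
        [g.upper() for g in host],
    )
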