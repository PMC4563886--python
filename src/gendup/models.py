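"""Shared data model for the synteny/duplication pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention). Any
half-open arithmetic is private to the functions that need it.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "HitRecord",
    "BestHitSet",
    "SyntenyMap",
    "LineageConfig",
    "SyntenyCall",
    "DuplicateFamily",
    "FixationRate",
    "KaKsResult",
    "EnrichmentRow",
]


@dataclass
class TranscriptModel:
    """One transcript of a gene: exon/CDS structure plus extracted sequences.

    ``exons`` and ``cds`` are lists of 1-based inclusive ``(start, end)``
    intervals in genomic coordinates, sorted in transcription order
    (ascending for + strand, descending for -).
    """

    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    protein: Optional[str] = None
    cds_seq: Optional[str] = None

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def is_complete(self) -> bool:
        """Whether the CDS length is a whole number of codons."""
        return self.cds_length % 3 == 0

    def translate(self) -> str:
        """Translate ``cds_seq`` (truncating any incomplete final codon)."""
        if self.cds_seq is None:
            raise ValueError(f"{self.transcript_id}: no CDS sequence attached")
        n = len(self.cds_seq) - len(self.cds_seq) % 3
        return str(Seq(self.cds_seq[:n]).translate())


@dataclass
class GeneModel:
    """One gene locus with its transcripts and annotation flags."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    is_te_related: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def primary_transcript(self) -> TranscriptModel:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene has no transcripts")
        return self.transcripts[0]

    def te_like(self) -> bool:
        """TE-relatedness from the annotation flag or description text."""
        return self.is_te_related or "transposon" in self.description.lower()


@dataclass
class HitRecord:
    """One pairwise local-alignment hit (BLAST tabular semantics)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_chromosome: Optional[str] = None
    subject_pos: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: identity "
                f"{self.pct_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )

    def query_overlap_pct(self, query_length: int) -> float:
        """Aligned query span as a percentage of the query length."""
        return (abs(self.q_end - self.q_start) + 1) / query_length * 100.0


@dataclass
class BestHitSet:
    """Best hit of one query per target species (``None`` when absent)."""

    query_id: str
    best: dict[str, HitRecord] = field(default_factory=dict)

    def species_with_hits(self) -> list[str]:
        return sorted(k for k, v in self.best.items() if v is not None)


class SyntenyMap:
    """Orthology blocks between chromosomes of species pairs.

    A block says: interval ``(a_start, a_end)`` of ``chrom_a`` in
    ``species_a`` is orthologous to interval ``(b_start, b_end)`` of
    ``chrom_b`` in ``species_b``. Blocks are stored symmetrically.
    Centromere positions are kept per (species, chromosome).
    """

    def __init__(self) -> None:
        self._blocks: dict[tuple[str, str], list[tuple[str, int, int, str, int, int]]] = {}
        self.centromeres: dict[tuple[str, str], int] = {}

    def add_block(
        self,
        species_a: str,
        chrom_a: str,
        a_start: int,
        a_end: int,
        species_b: str,
        chrom_b: str,
        b_start: int,
        b_end: int,
    ) -> None:
        if a_start > a_end or b_start > b_end:
            raise ValueError("synteny block interval reversed")
        self._blocks.setdefault((species_a, species_b), []).append(
            (chrom_a, a_start, a_end, chrom_b, b_start, b_end)
        )
        self._blocks.setdefault((species_b, species_a), []).append(
            (chrom_b, b_start, b_end, chrom_a, a_start, a_end)
        )

    def set_centromere(self, species: str, chromosome: str, pos: int) -> None:
        self.centromeres[(species, chromosome)] = pos

    def counterpart_blocks(
        self, species_a: str, chrom_a: str, species_b: str
    ) -> list[tuple[str, int, int]]:
        """Intervals of ``species_b`` orthologous to ``chrom_a`` of ``species_a``."""
        out = []
        for ca, s, e, cb, bs, be in self._blocks.get((species_a, species_b), []):
            if ca == chrom_a:
                out.append((cb, bs, be))
        return out

    def counterpart_chromosomes(
        self, species_a: str, chrom_a: str, species_b: str
    ) -> set[str]:
        return {c for c, _, _ in self.counterpart_blocks(species_a, chrom_a, species_b)}

    def is_syntenic_location(
        self,
        species_a: str,
        chrom_a: str,
        species_b: str,
        chrom_b: str,
        pos_b: Optional[float] = None,
    ) -> bool:
        """Whether (chrom_b, pos_b) of species_b falls in a block orthologous
        to chrom_a of species_a. With ``pos_b`` None only the chromosome is
        checked."""
        for cb, bs, be in self.counterpart_blocks(species_a, chrom_a, species_b):
            if cb != chrom_b:
                continue
            if pos_b is None or bs <= pos_b <= be:
                return True
        return False

    def species_pairs(self) -> set[tuple[str, str]]:
        return set(self._blocks)


@dataclass
class LineageConfig:
    """Species set, pairwise divergence times (MY) and homeolog groups."""

    species: list[str]
    divergence_my: dict[frozenset, float] = field(default_factory=dict)
    homeolog_groups: list[set[str]] = field(default_factory=list)
    outgroups: set[str] = field(default_factory=set)

    def set_divergence(self, a: str, b: str, my: float) -> None:
        if my <= 0:
            raise ValueError(f"divergence time must be positive, got {my}")
        self.divergence_my[frozenset((a, b))] = my

    def divergence(self, a: str, b: str) -> float:
        return self.divergence_my[frozenset((a, b))]

    def homeologs_of(self, chromosome: str) -> set[str]:
        for group in self.homeolog_groups:
            if chromosome in group:
                return set(group)
        return {chromosome}


@dataclass
class SyntenyCall:
    """Per-gene synteny classification with its evidence trail."""

    gene_id: str
    klass: str  # "syntenic" | "non-syntenic"
    reclassified: bool = False
    origin: str = "n/a"  # "duplication" | "unresolved" | "n/a"
    age_stratum: str = "n/a"  # "recent" | "old" | "n/a"
    evidence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.klass not in ("syntenic", "non-syntenic"):
            raise ValueError(f"bad class {self.klass!r}")


@dataclass
class DuplicateFamily:
    family_id: str
    members: list[str]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(
                f"family {self.family_id}: representative not a member"
            )


@dataclass
class FixationRate:
    """Non-syntenic gene fixation rate: n_nonsyntenic / n_total / T."""

    n_nonsyntenic: int
    n_total: int
    T: float
    rate: float

    @property
    def pct_nonsyntenic(self) -> float:
        return self.n_nonsyntenic / self.n_total * 100.0


@dataclass
class KaKsResult:
    """Nei–Gojobori substitution-rate estimate for one sequence pair."""

    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pd: float
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    flags: list[str] = field(default_factory=list)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    annotated: int
    significant: int
    expected: float
    p_value: float
    adj_p: float


def as_table_rows(records: Iterable) -> tuple[list[str], list[list]]:
    """Flatten homogeneous dataclass records into (header, rows) for TSV."""
    records = list(records)
    if not records:
        return [], []
    first = records[0]
    cols = [f.name for f in fields(first)]
    rows = []
    for r in records:
        if type(r) is not type(first):
            raise TypeError("records are not homogeneous")
        rows.append([getattr(r, c) for c in cols])
    return cols, rows
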