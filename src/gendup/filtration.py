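"""Four-stage filtration to a comparable "core" gene set.

Stages, applied sequentially so each count is conditioned on the
previous one: (1) collapse alternative splice variants to the longest-CDS
representative; (2) remove transposable-element-related genes; (3) keep
only genes with a significant protein hit in at least one other species
(e-value <= 1e-5, >= 35 % identity, >= 35 % query overlap); (4) remove
pseudogenes (internal stop, frameshift, or truncation below 70 % of the
best homolog's length).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .models import GeneModel, HitRecord

logger = logging.getLogger(__name__)

STAGES = ("raw", "no_asv_te", "homology_supported", "non_pseudogene")


@dataclass
class FilterThresholds:
    max_evalue: float = 1e-5
    min_identity_pct: float = 35.0
    min_overlap_pct: float = 35.0
    pseudogene_min_fraction: float = 0.70
    #: "query" (aligned span / query length) or "symmetric_min"
    overlap_denominator: str = "query"


@dataclass
class FiltrationReport:
    species: str
    counts: dict[str, int] = field(default_factory=dict)
    removal_reason: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        vals = [self.counts[s] for s in STAGES if s in self.counts]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise AssertionError("stage counts increased between filters")


def collapse_isoforms(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Keep exactly one transcript per gene: longest CDS, ties broken by
    longest genomic span, then lexicographic transcript id."""
    out = []
    for g in genes:
        if not g.transcripts:
            raise ValueError(f"{g.gene_id}: gene has no transcripts")
        def key(tr):
            span = 0
            if tr.exons:
                span = max(e for _, e in tr.exons) - min(s for s, _ in tr.exons) + 1
            return (-tr.cds_length, -span, tr.transcript_id)
        best = sorted(g.transcripts, key=key)[0]
        g2 = GeneModel(
            gene_id=g.gene_id, species=g.species, chromosome=g.chromosome,
            start=g.start, end=g.end, strand=g.strand, transcripts=[best],
            is_te_related=g.is_te_related, description=g.description,
        )
        out.append(g2)
    return out


def remove_te_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Drop genes flagged TE-related or with 'transposon' in the
    description (case-insensitive substring, mirroring annotation-class
    and description-text sources)."""
    return [g for g in genes if not g.te_like()]


def _protein_len(g: GeneModel) -> int:
    tr = g.primary_transcript()
    if tr.protein:
        return len(tr.protein.rstrip("*"))
    return tr.cds_length // 3


def qualifying_hit(
    hit: HitRecord,
    query_len_aa: int,
    thresholds: FilterThresholds,
    subject_len_aa: Optional[int] = None,
) -> bool:
    if hit.evalue > thresholds.max_evalue:
        return False
    if hit.pct_identity < thresholds.min_identity_pct:
        return False
    denom = query_len_aa
    if thresholds.overlap_denominator == "symmetric_min" and subject_len_aa:
        denom = min(query_len_aa, subject_len_aa)
    overlap = (abs(hit.q_end - hit.q_start) + 1) / denom * 100.0
    return overlap >= thresholds.min_overlap_pct


def homology_support_filter(
    genes: Iterable[GeneModel],
    hits: Iterable[HitRecord],
    species_of: dict[str, str],
    self_species: str,
    thresholds: Optional[FilterThresholds] = None,
    subject_lengths: Optional[dict[str, int]] = None,
) -> list[GeneModel]:
    """Keep genes with >= 1 qualifying hit in >= 1 *other* species.

    Genes absent from the hit table have zero hits and are removed
    (logged). ``species_of`` maps subject gene ids to their species.
    """
    thresholds = thresholds or FilterThresholds()
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = []
    for g in genes:
        qlen = _protein_len(g)
        supported = False
        for h in by_query.get(g.gene_id, ()):
            sp = species_of.get(h.subject_id)
            if sp is None or sp == self_species:
                continue
            slen = subject_lengths.get(h.subject_id) if subject_lengths else None
            if qualifying_hit(h, qlen, thresholds, slen):
                supported = True
                break
        if supported:
            out.append(g)
        else:
            logger.info("%s: no cross-species homology support", g.gene_id)
    return out


def detect_pseudogene(
    gene: GeneModel,
    best_complete_homolog_len: Optional[int],
    thresholds: Optional[FilterThresholds] = None,
) -> tuple[bool, str]:
    """Pseudogene check: internal stop codon, frameshift (CDS length not a
    multiple of 3), or truncation below 70 % of the best homolog's
    protein length. Returns (is_pseudogene, reason); reason is the first
    failing check."""
    thresholds = thresholds or FilterThresholds()
    tr = gene.primary_transcript()
    if tr.cds_seq is None:
        raise ValueError(f"{gene.gene_id}: no CDS sequence; cannot assess")
    protein = tr.translate()
    body = protein[:-1] if protein.endswith("*") else protein
    if "*" in body:
        return True, "internal_stop"
    if tr.cds_length % 3 != 0:
        return True, "frameshift"
    if best_complete_homolog_len:
        if len(body) < thresholds.pseudogene_min_fraction * best_complete_homolog_len:
            return True, "truncation"
    return False, ""


def run_filtration(
    genes: Iterable[GeneModel],
    hits: Iterable[HitRecord],
    species_of: dict[str, str],
    self_species: str,
    thresholds: Optional[FilterThresholds] = None,
    subject_lengths: Optional[dict[str, int]] = None,
) -> tuple[list[GeneModel], FiltrationReport]:
    """Apply the four filters in order and report per-stage counts.

    Each removed gene gets exactly one removal reason: the first filter
    it fails. The homolog length for the truncation rule is taken from
    the gene's best qualifying hit (highest bitscore).
    """
    thresholds = thresholds or FilterThresholds()
    genes = list(genes)
    hits = list(hits)
    report = FiltrationReport(species=self_species)
    report.counts["raw"] = len(genes)

    collapsed = collapse_isoforms(genes)
    no_te = remove_te_genes(collapsed)
    for g in collapsed:
        if g.te_like():
            report.removal_reason[g.gene_id] = "te_related"
    report.counts["no_asv_te"] = len(no_te)

    supported = homology_support_filter(
        no_te, hits, species_of, self_species, thresholds, subject_lengths
    )
    supported_ids = {g.gene_id for g in supported}
    for g in no_te:
        if g.gene_id not in supported_ids:
            report.removal_reason[g.gene_id] = "no_homology_support"
    report.counts["homology_supported"] = len(supported)

    # best qualifying homolog length per gene, for the truncation rule
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    core = []
    for g in supported:
        qlen = _protein_len(g)
        qhits = [
            h for h in by_query.get(g.gene_id, ())
            if species_of.get(h.subject_id) not in (None, self_species)
            and qualifying_hit(
                h, qlen, thresholds,
                subject_lengths.get(h.subject_id) if subject_lengths else None,
            )
        ]
        homolog_len = None
        if qhits:
            best = min(qhits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
            if subject_lengths and best.subject_id in subject_lengths:
                homolog_len = subject_lengths[best.subject_id]
        is_pseudo, reason = detect_pseudogene(g, homolog_len, thresholds)
        if is_pseudo:
            report.removal_reason[g.gene_id] = reason
        else:
            core.append(g)
    report.counts["non_pseudogene"] = len(core)
    report.validate()
    return core, report
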