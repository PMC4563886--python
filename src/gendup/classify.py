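"""Syntenic / non-syntenic classification of core genes.

A gene is **syntenic** when its best protein hit in at least one other
species falls inside an orthology block of the gene's own chromosome,
and **non-syntenic** when every best hit lies on a non-orthologous
chromosome. Initially non-syntenic genes are re-examined by a nucleotide
search of their CDS against the orthologous pseudomolecules (catching
orthologs present in sequence but missing from annotation), then probed
for a retained copy elsewhere in their own genome (duplication origin)
and stratified by age against close-relative gene sets.
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import networkx as nx

from .filtration import FilterThresholds, qualifying_hit
from .homology import NucleotideIndex, ProteinSearch, SearchParams
from .models import BestHitSet, DuplicateFamily, GeneModel, SyntenyCall, SyntenyMap

logger = logging.getLogger(__name__)


def classify_gene(
    gene: GeneModel,
    best: BestHitSet,
    smap: SyntenyMap,
) -> SyntenyCall:
    """Classify one core gene from its per-species best hits.

    "At least one best hit on a syntenic counterpart" wins over any
    number of non-syntenic hits; best hits on chromosomes absent from
    the synteny map count as non-syntenic evidence (logged).
    """
    evidence: dict[str, str] = {}
    syntenic = False
    for sp, hit in sorted(best.best.items()):
        if hit is None:
            continue
        chrom = hit.subject_chromosome
        if chrom is None:
            evidence[sp] = "unplaced"
            logger.info("%s: best hit in %s unplaced", gene.gene_id, sp)
            continue
        known = smap.counterpart_chromosomes(gene.species, gene.chromosome, sp)
        if smap.is_syntenic_location(
            gene.species, gene.chromosome, sp, chrom, hit.subject_pos
        ):
            evidence[sp] = f"{chrom}:syntenic"
            syntenic = True
        else:
            tag = "other" if (chrom in known or known) else "unmapped"
            evidence[sp] = f"{chrom}:{tag}"
    return SyntenyCall(
        gene_id=gene.gene_id,
        klass="syntenic" if syntenic else "non-syntenic",
        evidence=evidence,
    )


def reclassify_by_genomic_search(
    calls: dict[str, SyntenyCall],
    genes: dict[str, GeneModel],
    cds: dict[str, str],
    ortholog_indexes: dict[str, NucleotideIndex],
    counterparts: dict[str, set[str]],
    min_identity_pct: float = 80.0,
    min_overlap_pct: float = 50.0,
) -> dict[str, SyntenyCall]:
    """Flip non-syntenic calls whose CDS is found on an orthologous
    pseudomolecule at >= ``min_identity_pct`` identity and
    >= ``min_overlap_pct`` query overlap.

    ``ortholog_indexes`` maps target species to a nucleotide index over
    its pseudomolecules; ``counterparts`` maps target species to the
    chromosome names there that are orthologous to the query chromosome.
    Genes whose pseudomolecules are unavailable are left unchanged.
    """
    for gid, call in calls.items():
        if call.klass != "non-syntenic":
            continue
        if gid not in cds:
            logger.warning("%s: no CDS for reclassification search", gid)
            continue
        flipped = False
        for sp, index in ortholog_indexes.items():
            allowed = counterparts.get(sp, set())
            for hit in index.search(gid, cds[gid]):
                if hit.subject_id not in allowed:
                    continue
                if (
                    hit.pct_identity >= min_identity_pct
                    and hit.q_overlap_pct >= min_overlap_pct
                ):
                    flipped = True
                    call.evidence[f"reclass_{sp}"] = (
                        f"{hit.subject_id}:{hit.pct_identity:.1f}%/"
                        f"{hit.q_overlap_pct:.1f}%"
                    )
                    break
            if flipped:
                break
        if flipped:
            call.klass = "syntenic"
            call.reclassified = True
    return calls


def detect_duplicate_origin(
    calls: dict[str, SyntenyCall],
    genes: dict[str, GeneModel],
    cds: dict[str, str],
    survey_index: NucleotideIndex,
    homeologs_of_chrom: dict[str, set[str]],
    min_identity_pct: float = 80.0,
    min_overlap_pct: float = 50.0,
) -> dict[str, SyntenyCall]:
    """Mark non-syntenic genes with a copy on a non-homeologous chromosome
    of their own genome as ``origin=duplication`` (else ``unresolved``)."""
    for gid, call in calls.items():
        if call.klass != "non-syntenic":
            continue
        call.origin = "unresolved"
        gene = genes.get(gid)
        if gene is None or gid not in cds:
            continue
        homeo = homeologs_of_chrom.get(gene.chromosome, {gene.chromosome})
        for hit in survey_index.search(gid, cds[gid]):
            if hit.subject_id in homeo:
                continue
            if (
                hit.pct_identity >= min_identity_pct
                and hit.q_overlap_pct >= min_overlap_pct
            ):
                call.origin = "duplication"
                call.evidence["origin_hit"] = (
                    f"{hit.subject_id}:{hit.pct_identity:.1f}%"
                )
                break
    return calls


def stratify_age(
    calls: dict[str, SyntenyCall],
    proteins: dict[str, str],
    relative_sets: dict[str, dict[str, str]],
    thresholds: Optional[FilterThresholds] = None,
    params: Optional[SearchParams] = None,
) -> dict[str, SyntenyCall]:
    """Stratify non-syntenic genes into recent vs old movers.

    ``recent``: no qualifying hit (homology-filter thresholds) in any of
    the close-relative gene sets (e.g. the two homeologous chromosome
    sets and the sister species); ``old`` otherwise.
    """
    thresholds = thresholds or FilterThresholds()
    engines = {
        name: ProteinSearch(prots, params)
        for name, prots in relative_sets.items()
        if prots
    }
    for gid, call in calls.items():
        if call.klass != "non-syntenic":
            continue
        if gid not in proteins:
            call.age_stratum = "n/a"
            continue
        qlen = len(proteins[gid])
        found = False
        for name, engine in engines.items():
            for hit in engine.search_one(gid, proteins[gid]):
                if qualifying_hit(hit, qlen, thresholds):
                    found = True
                    call.evidence[f"age_{name}"] = hit.subject_id
                    break
            if found:
                break
        call.age_stratum = "old" if found else "recent"
    return calls


def build_families_and_pick_representatives(
    gene_ids: Iterable[str],
    intra_hits,
    seed: int,
    gene_lengths: Optional[dict[str, int]] = None,
    thresholds: Optional[FilterThresholds] = None,
) -> list[DuplicateFamily]:
    """Single-linkage duplicate families over same-chromosome hits.

    Edges are hits passing the homology-filter thresholds; families are
    connected components; one representative per family is drawn
    uniformly with the given seed (deterministic per seed). Genes with
    no qualifying hit form singleton families.
    """
    thresholds = thresholds or FilterThresholds()
    gene_ids = sorted(gene_ids)
    graph = nx.Graph()
    graph.add_nodes_from(gene_ids)
    for h in intra_hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in graph or h.subject_id not in graph:
            continue
        qlen = gene_lengths.get(h.query_id) if gene_lengths else None
        if qlen is None:
            qlen = abs(h.q_end - h.q_start) + 1
        if qualifying_hit(h, qlen, thresholds):
            graph.add_edge(h.query_id, h.subject_id)
    rng = np.random.default_rng(seed)
    families = []
    comps = sorted(nx.connected_components(graph), key=min)
    for i, comp in enumerate(comps):
        members = sorted(comp)
        rep = members[int(rng.integers(0, len(members)))]
        families.append(
            DuplicateFamily(family_id=f"fam{i:04d}", members=members, representative=rep)
        )
    return families
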