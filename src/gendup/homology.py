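"""All-vs-all protein homology search and best-hit selection.

The built-in search is a k-mer–seeded Smith–Waterman: candidate subjects
are ranked by the number of shared words (default word size 3) and the
top candidates are aligned locally under BLOSUM62 with affine gaps
(open 11 / extend 1) using Biopython's C aligner. E-values come from the
Karlin–Altschul formula with fixed gapped BLOSUM62 constants and are
approximate by design — the identity/overlap thresholds downstream do
the real filtering. Precomputed BLAST tabular files can be supplied
instead for real-data fidelity.
"""
from __future__ import annotations

import math
import numpy as np
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .models import BestHitSet, GeneModel, HitRecord

# Gapped Karlin-Altschul parameters for BLOSUM62, open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX*")
VALID_NT = set("ACGTN")


@dataclass
class SearchParams:
    word_size: int = 3
    gap_open: float = 11.0
    gap_extend: float = 1.0
    max_candidates: int = 8
    max_evalue: float = 10.0
    min_shared_words: int = 1
    #: align only the top-N candidates by shared-word count;
    #: None = align every candidate.
    max_full_alignments: Optional[int] = None


def _protein_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "local"
    return aligner


def _words(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def bitscore_from_raw(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)


def evalue_from_bitscore(bit: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bit)


def _validate(seqs: dict[str, str], alphabet: set, kind: str) -> None:
    for name, s in seqs.items():
        bad = set(s.upper()) - alphabet
        if bad:
            raise ValueError(
                f"{kind} sequence {name!r} contains invalid characters {sorted(bad)}"
            )


def _hit_from_alignment(aln, query_id: str, subject_id: str,
                        db_size: int) -> HitRecord:
    counts = aln.counts()
    ident = counts.identities
    mism = counts.mismatches
    # gap opens: count runs of gaps in either row
    gap_opens = 0
    ncols = 0
    qgap = sgap = False
    qs = aln[0]
    ss = aln[1]
    for cq, cs in zip(qs, ss):
        ncols += 1
        if cq == "-":
            if not qgap:
                gap_opens += 1
            qgap = True
        else:
            qgap = False
        if cs == "-":
            if not sgap:
                gap_opens += 1
            sgap = True
        else:
            sgap = False
    coords = aln.coordinates
    q_start = int(coords[0, 0]) + 1
    q_end = int(coords[0, -1])
    s_start = int(coords[1, 0]) + 1
    s_end = int(coords[1, -1])
    bit = bitscore_from_raw(aln.score)
    ev = evalue_from_bitscore(bit, len(aln.target), db_size)
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=100.0 * ident / ncols if ncols else 0.0,
        aln_length=ncols,
        mismatches=mism,
        gap_opens=gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=ev,
        bitscore=round(bit, 1),
    )


class ProteinSearch:
    """Reusable seeded protein search against a fixed subject set."""

    def __init__(self, subjects: dict[str, str], params: Optional[SearchParams] = None):
        self.params = params or SearchParams()
        _validate(subjects, VALID_AA, "protein")
        self.subjects = {k: v.upper() for k, v in subjects.items()}
        self.db_size = sum(len(s) for s in self.subjects.values())
        # word -> array of subject indices (subjects in sorted-id order so
        # numeric index order is lexicographic: deterministic tie-breaks)
        self._names = sorted(self.subjects)
        k = self.params.word_size
        tmp: dict[str, list[int]] = defaultdict(list)
        for i, sid in enumerate(self._names):
            for w in _words(self.subjects[sid], k):
                tmp[w].append(i)
        self._index = {w: np.asarray(v, dtype=np.int32) for w, v in tmp.items()}
        self._aligner = _protein_aligner(self.params)

    def candidates(self, query_seq: str) -> list[str]:
        arrays = [
            self._index[w]
            for w in _words(query_seq, self.params.word_size)
            if w in self._index
        ]
        if not arrays:
            return []
        counts = np.bincount(np.concatenate(arrays), minlength=len(self._names))
        eligible = np.nonzero(counts >= self.params.min_shared_words)[0]
        order = eligible[np.lexsort((eligible, -counts[eligible]))]
        return [self._names[i] for i in order[: self.params.max_candidates]]

    def search_one(self, query_id: str, query_seq: str,
                   exclude_self: bool = True) -> list[HitRecord]:
        query_seq = query_seq.upper()
        cands = [
            sid for sid in self.candidates(query_seq)
            if not (exclude_self and sid == query_id)
        ]
        top_n = self.params.max_full_alignments
        if top_n is not None:
            cands = cands[:top_n]
        hits = []
        for sid in cands:
            alns = self._aligner.align(query_seq, self.subjects[sid])
            try:
                aln = alns[0]
            except IndexError:
                continue
            hit = _hit_from_alignment(aln, query_id, sid, self.db_size)
            if hit.evalue <= self.params.max_evalue:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id))
        return hits


def search_proteins(
    queries: dict[str, str],
    subjects: dict[str, str],
    params: Optional[SearchParams] = None,
) -> list[HitRecord]:
    """Search every query against the subject set; see module docstring.

    Self-hits (identical IDs) are excluded. Queries without any shared
    word of length ``word_size`` produce no hits.
    """
    _validate(queries, VALID_AA, "protein")
    engine = ProteinSearch(subjects, params)
    out: list[HitRecord] = []
    for qid in sorted(queries):
        out.extend(engine.search_one(qid, queries[qid]))
    return out


def annotate_subject_locations(
    hits: Iterable[HitRecord], gene_index: dict[str, GeneModel]
) -> None:
    """Fill subject_chromosome / subject_pos from the gene annotation."""
    for h in hits:
        g = gene_index.get(h.subject_id)
        if g is not None:
            h.subject_chromosome = g.chromosome
            h.subject_pos = g.midpoint


def best_hits(
    hits: Iterable[HitRecord],
    species_of: dict[str, str],
    max_evalue: float = 1e-5,
) -> dict[str, BestHitSet]:
    """Best hit per (query, target species) under the e-value cutoff.

    Ties on bitscore go to the lower e-value, then higher identity, then
    the lexicographically smaller subject id, so the result is
    deterministic regardless of input order.
    """
    per_query: dict[str, BestHitSet] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        sp = species_of.get(h.subject_id)
        if sp is None:
            continue
        bhs = per_query.setdefault(h.query_id, BestHitSet(query_id=h.query_id))
        cur = bhs.best.get(sp)
        if cur is None or _hit_key(h) < _hit_key(cur):
            bhs.best[sp] = h
    return per_query


def _hit_key(h: HitRecord):
    return (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id)


def protein_global_alignment(a: str, b: str) -> tuple[str, str]:
    """Global (Needleman–Wunsch) protein alignment under BLOSUM62.

    Used to build the protein alignment that gets back-translated for
    Ka/Ks. End gaps are free so terminal length differences are not
    over-penalized.
    """
    aligner = Align.PairwiseAligner()
    matrix = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    aligner.mode = "global"
    a = a.replace("*", "").upper()
    b = b.replace("*", "").upper()
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


@dataclass
class NucleotideHit:
    query_id: str
    subject_id: str
    pct_identity: float
    q_overlap_pct: float
    s_start: int
    s_end: int
    score: float
    strand: str = "+"


class NucleotideIndex:
    """Seeded nucleotide local search against large sequences.

    Exact k-mer seeds (default 13) locate candidate regions; each region
    (plus query-length flanks) is aligned locally (match 2, mismatch -3,
    open 5 / extend 2) and reported with identity and query overlap.
    Intended for CDS-vs-pseudomolecule searches.
    """

    def __init__(self, subjects: dict[str, str], k: int = 13):
        _validate(subjects, VALID_NT, "nucleotide")
        self.k = k
        self.subjects = {n: s.upper() for n, s in subjects.items()}
        self._index: dict[str, dict[str, list[int]]] = {}
        for name, seq in self.subjects.items():
            idx: dict[str, list[int]] = defaultdict(list)
            for i in range(len(seq) - k + 1):
                idx[seq[i : i + k]].append(i)
            self._index[name] = idx
        aligner = Align.PairwiseAligner()
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
        aligner.mode = "local"
        self._aligner = aligner

    def search(self, query_id: str, query: str) -> list[NucleotideHit]:
        """Search both strands (the query and its reverse complement)."""
        query = query.upper()
        rc = query.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        hits = self._search_strand(query_id, query, "+")
        hits += self._search_strand(query_id, rc, "-")
        hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start, h.strand))
        return hits

    def _search_strand(self, query_id: str, query: str, strand: str) -> list[NucleotideHit]:
        k = self.k
        qwords = [(i, query[i : i + k]) for i in range(0, len(query) - k + 1, k)]
        hits = []
        for name, idx in self._index.items():
            positions = []
            for qi, w in qwords:
                for si in idx.get(w, ()):
                    positions.append(si - qi)  # diagonal anchor
            if not positions:
                continue
            # group anchors into candidate regions
            positions.sort()
            regions: list[list[int]] = [[positions[0]]]
            for p in positions[1:]:
                if p - regions[-1][-1] <= len(query):
                    regions[-1].append(p)
                else:
                    regions.append([p])
            subj = self.subjects[name]
            for reg in regions:
                lo = max(0, reg[0] - len(query) // 2)
                hi = min(len(subj), reg[-1] + len(query) + len(query) // 2)
                window = subj[lo:hi]
                alns = self._aligner.align(query, window)
                try:
                    aln = alns[0]
                except IndexError:
                    continue
                counts = aln.counts()
                ncols = len(aln[0])
                q_span = aln.coordinates[0, -1] - aln.coordinates[0, 0]
                hits.append(
                    NucleotideHit(
                        query_id=query_id,
                        subject_id=name,
                        pct_identity=100.0 * counts.identities / ncols if ncols else 0.0,
                        q_overlap_pct=100.0 * q_span / len(query),
                        s_start=lo + int(aln.coordinates[1, 0]) + 1,
                        s_end=lo + int(aln.coordinates[1, -1]),
                        score=aln.score,
                        strand=strand,
                    )
                )
        return hits
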