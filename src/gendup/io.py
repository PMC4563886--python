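"""Reading and writing of GFF3, FASTA and tabular hit/result files.

GFF3 parsing is delegated to :mod:`gffutils` (in-memory database), FASTA
to Biopython. Coordinates stay 1-based inclusive end to end so that a
GFF3 -> GeneModel -> GFF3 round trip is loss-free.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, HitRecord, TranscriptModel, as_table_rows


class GFF3ParseError(ValueError):
    """Structured GFF3 parse failure (carries the offending feature id)."""


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: Union[str, Path], width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _extract_cds_seq(cds: list[tuple[int, int]], strand: str, chrom_seq: str) -> str:
    parts = [chrom_seq[s - 1 : e] for s, e in sorted(cds)]
    seq = "".join(parts)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def read_gff3(path: Union[str, Path], fasta: Union[str, Path, dict, None] = None,
              species: str = "") -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels, attaching CDS and protein sequences.

    Parameters
    ----------
    path
        GFF3 with gene / mRNA / exon / CDS features linked by ID/Parent.
    fasta
        Chromosome sequences (path or preloaded dict). When given, each
        transcript gets a strand-aware spliced ``cds_seq`` and its
        translation in ``protein``.
    species
        Species label stamped on every gene.

    Raises
    ------
    GFF3ParseError
        On duplicate gene IDs, mRNA/exon/CDS features whose Parent is
        missing, or CDS referencing a sequence absent from the FASTA.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    chrom_seqs: Optional[dict[str, str]] = None
    if fasta is not None:
        chrom_seqs = fasta if isinstance(fasta, dict) else read_fasta(fasta)

    gene_ids: set[str] = set()
    # Parent links: gffutils silently tolerates orphans, so check explicitly.
    all_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent in feat.attributes.get("Parent", []):
            if parent not in all_ids:
                raise GFF3ParseError(
                    f"feature {feat.id or feat.featuretype} at "
                    f"{feat.seqid}:{feat.start} references missing Parent "
                    f"{parent!r}"
                )

    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        if gf.id in gene_ids:
            raise GFF3ParseError(f"duplicate gene id {gf.id!r}")
        gene_ids.add(gf.id)
        transcripts = []
        for mrna in db.children(gf, featuretype="mRNA", order_by="start"):
            exons = [(c.start, c.end) for c in db.children(mrna, featuretype="exon")]
            cds = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            exons.sort(reverse=(gf.strand == "-"))
            cds_sorted = sorted(cds, reverse=(gf.strand == "-"))
            cds_seq = protein = None
            if chrom_seqs is not None and cds:
                if gf.seqid not in chrom_seqs:
                    raise GFF3ParseError(
                        f"{mrna.id}: CDS references sequence {gf.seqid!r} "
                        "absent from FASTA"
                    )
                cds_seq = _extract_cds_seq(cds, gf.strand, chrom_seqs[gf.seqid])
            tr = TranscriptModel(
                transcript_id=mrna.id,
                exons=exons,
                cds=cds_sorted,
                cds_seq=cds_seq,
            )
            if cds_seq is not None:
                tr.protein = tr.translate()
            transcripts.append(tr)
        attrs = gf.attributes
        desc = (attrs.get("Note") or attrs.get("description") or [""])[0]
        te_flag = (attrs.get("te_related") or ["0"])[0] in ("1", "true", "True")
        genes.append(
            GeneModel(
                gene_id=gf.id,
                species=species,
                chromosome=gf.seqid,
                start=gf.start,
                end=gf.end,
                strand=gf.strand,
                transcripts=transcripts,
                is_te_related=te_flag,
                description=desc,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: Union[str, Path],
               source: str = "gendup") -> None:
    """Write GeneModels back out as GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.is_te_related:
                attrs.append("te_related=1")
            if g.description:
                attrs.append(f"Note={g.description}")
            fh.write(
                "\t".join(
                    [g.chromosome, source, "gene", str(g.start), str(g.end),
                     ".", g.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )
            for tr in g.transcripts:
                fh.write(
                    "\t".join(
                        [g.chromosome, source, "mRNA", str(g.start), str(g.end),
                         ".", g.strand, ".",
                         f"ID={tr.transcript_id};Parent={g.gene_id}"]
                    )
                    + "\n"
                )
                for s, e in sorted(tr.exons):
                    fh.write(
                        "\t".join(
                            [g.chromosome, source, "exon", str(s), str(e), ".",
                             g.strand, ".", f"Parent={tr.transcript_id}"]
                        )
                        + "\n"
                    )
                for s, e in sorted(tr.cds):
                    fh.write(
                        "\t".join(
                            [g.chromosome, source, "CDS", str(s), str(e), ".",
                             g.strand, "0", f"Parent={tr.transcript_id}"]
                        )
                        + "\n"
                    )


def read_hit_table(path: Union[str, Path],
                   gene_index: Optional[dict[str, GeneModel]] = None) -> list[HitRecord]:
    """Parse a 12/13-column BLAST-tabular hit file.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore [subject_chromosome]. When the 13th
    column is absent, the subject chromosome and position are resolved
    through ``gene_index`` (subject gene annotation) if provided.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                hit = HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if len(parts) >= 13:
                hit.subject_chromosome = parts[12]
            elif gene_index is not None and hit.subject_id in gene_index:
                subj = gene_index[hit.subject_id]
                hit.subject_chromosome = subj.chromosome
                hit.subject_pos = subj.midpoint
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: Union[str, Path]) -> None:
    """Write hits in the 13-column tabular dialect (no header)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        h.query_id, h.subject_id, h.pct_identity, h.aln_length,
                        h.mismatches, h.gap_opens, h.q_start, h.q_end,
                        h.s_start, h.s_end, h.evalue, h.bitscore,
                        h.subject_chromosome if h.subject_chromosome else ".",
                    ]
                )
                + "\n"
            )


def write_table(records, path: Union[str, Path]) -> None:
    """Write homogeneous records (dataclasses or a DataFrame) as headered TSV."""
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep="\t", index=False)
        return
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        cols, rows = as_table_rows(records)
        df = pd.DataFrame(rows, columns=cols)
    elif records and isinstance(records[0], dict):
        df = pd.DataFrame(records)
    else:
        df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
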