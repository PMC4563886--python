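"""Synthetic multi-species genome generator with known ground truth.

The generator emulates the comparative setting of a focal *Triticeae*-like
chromosome against three model-grass relatives: an ancestral gene
complement conserved collinearly on orthologous chromosomes, plus
lineage-specific interchromosomal duplications/translocations that insert
gene copies onto non-orthologous chromosomes, pseudogenization lesions,
TE-gene and splice-variant decoys, and coding-sequence divergence under a
configurable Ka/Ks (``omega``).

Topology is the fixed four-taxon species tree
``(((focal, relative1):15, relative2):6, outgroup)`` with divergence
times 39 / 54 / 60 MY, matching grass phylogeny dating; an optional
"homeolog mode" adds two homeologous gene sets (split 6.5 MY) and a
sister-species set (11.6 MY) for the recent/old age stratification of
duplicated genes.

Every emitted gene has exactly one truth record, so downstream stages
(filtration, classification, rates, landscapes) can be validated exactly.
A single integer seed fixes all randomness; identical seeds give
byte-identical output bundles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .kaks import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, translate_cds
from .models import GeneModel, LineageConfig, SyntenyMap, TranscriptModel
from . import io as gio

BASES = "TCAG"
_ALT = {b: [x for x in BASES if x != b] for b in BASES}
# (codon, pos, alt-index) -> (new codon, kind); kind: "syn" | "nonsyn" | "stop"
_MUT: dict[tuple[str, int, int], tuple[str, str]] = {}
for _c in SENSE_CODONS:
    for _p in range(3):
        for _i, _b in enumerate(_ALT[_c[_p]]):
            _new = _c[:_p] + _b + _c[_p + 1 :]
            if _new in STOP_CODONS:
                _kind = "stop"
            elif GENETIC_CODE[_new] == GENETIC_CODE[_c]:
                _kind = "syn"
            else:
                _kind = "nonsyn"
            _MUT[(_c, _p, _i)] = (_new, _kind)

DEFAULT_SPECIES = ("wheat", "brachypodium", "rice", "sorghum")
#: Tip branch lengths (MY since last divergence) of the fixed topology.
TIP_BRANCH = {"wheat": 39.0, "brachypodium": 39.0, "rice": 54.0, "sorghum": 60.0}


@dataclass
class ExpressionParams:
    """Class-wise expression model (defaults follow the observed contrast
    between syntenic and non-syntenic genes: 83 % vs 74 % expressed, mean
    breadth 12 vs 9.2 of 15 conditions, mean level 261 vs 142)."""

    n_conditions: int = 15
    expressed_prob: dict = field(
        default_factory=lambda: {"syntenic": 0.83, "non-syntenic": 0.74}
    )
    mean_breadth: dict = field(
        default_factory=lambda: {"syntenic": 12.0, "non-syntenic": 9.2}
    )
    mean_level: dict = field(
        default_factory=lambda: {"syntenic": 261.0, "non-syntenic": 142.0}
    )


@dataclass
class SimulationConfig:
    """Knobs of the clade generator; defaults are the study conditions.

    Rates are events per locus per MY on terminal branches. The default
    per-lineage duplication rates are calibrated so the study chromosome
    of each species ends up with approximately the non-syntenic gene
    fractions observed in wheat 3B (~27 %) and the three model grasses
    (~8-14 %).
    """

    species: tuple = DEFAULT_SPECIES
    focal_species: str = "wheat"
    n_chromosomes: int = 3
    study_chromosome: str = "chr1"
    n_ancestral_genes: int = 1000
    min_codons: int = 100
    max_codons: int = 300
    intergenic_bp: int = 150
    intron_bp: int = 60
    multi_exon_fraction: float = 0.0
    duplication_rate: Union[float, dict] = field(
        default_factory=lambda: {
            "wheat": 6.8e-3,
            "brachypodium": 1.6e-3,
            "rice": 1.4e-3,
            "sorghum": 2.0e-3,
        }
    )
    translocation_rate: Union[float, dict] = field(
        default_factory=lambda: {
            "wheat": 2.0e-3,
            "brachypodium": 0.5e-3,
            "rice": 0.4e-3,
            "sorghum": 0.6e-3,
        }
    )
    pseudogenization_prob: float = 0.0
    te_decoy_fraction: float = 0.0
    asv_decoy_fraction: float = 0.0
    ancient_paralog_fraction: float = 0.0
    ancient_paralog_extra_my: float = 30.0
    annotation_dropout_rate: float = 0.0
    omega: float = 0.2
    omega_nonsyntenic: float = 0.35
    syn_subs_per_my: float = 0.006
    distal_retention_bias: float = 0.0
    homeolog_mode: bool = False
    homeolog_split_my: float = 6.5
    sister_split_my: float = 11.6
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    seed: int = 0

    def rate_of(self, table: Union[float, dict], species: str) -> float:
        if isinstance(table, dict):
            return float(table[species])
        return float(table)


@dataclass
class TruthRecord:
    """Ground truth for one emitted gene in one species."""

    species: str
    gene_id: str
    ancestral_locus: str
    chromosome: str
    true_class: str          # "syntenic" | "non-syntenic" | "decoy"
    age_stratum: str = "n/a"  # "recent" | "old" | "n/a"
    event: str = ""           # "duplication" | "translocation" | ""
    event_time_my: float = float("nan")
    ancestral_retained: bool = True
    pseudogene_type: str = ""  # "internal_stop" | "frameshift" | "truncation" | ""
    is_te_decoy: bool = False
    has_asv_decoy: bool = False
    annotation_dropout: bool = False
    has_ancient_paralog: bool = False
    annotated: bool = True


@dataclass
class CladeTruth:
    records: list[TruthRecord] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def by_gene(self, species: str) -> dict[str, TruthRecord]:
        return {r.gene_id: r for r in self.records if r.species == species}

    def study_records(self, species: str, study_chrom: str) -> list[TruthRecord]:
        return [
            r for r in self.records
            if r.species == species and r.chromosome == study_chrom
        ]


@dataclass
class SpeciesBundle:
    species: str
    genes: list[GeneModel]
    chromosomes: dict[str, str]

    def gene_index(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def proteins(self, chromosome: Optional[str] = None) -> dict[str, str]:
        out = {}
        for g in self.genes:
            if chromosome is not None and g.chromosome != chromosome:
                continue
            tr = g.primary_transcript()
            if tr.protein:
                out[g.gene_id] = tr.protein.rstrip("*")
        return out

    def cds(self, chromosome: Optional[str] = None) -> dict[str, str]:
        out = {}
        for g in self.genes:
            if chromosome is not None and g.chromosome != chromosome:
                continue
            tr = g.primary_transcript()
            if tr.cds_seq:
                out[g.gene_id] = tr.cds_seq
        return out


@dataclass
class CladeBundle:
    config: SimulationConfig
    species: dict[str, SpeciesBundle]
    synteny_map: SyntenyMap
    lineage: LineageConfig
    truth: CladeTruth
    close_relatives: dict[str, dict[str, str]] = field(default_factory=dict)


# ---------------------------------------------------------------- sequences

def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG + random sense codons + one stop codon."""
    body = rng.choice(len(SENSE_CODONS), size=max(n_codons - 1, 1))
    stop = ["TAA", "TGA", "TAG"][rng.integers(0, 3)]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def evolve_cds(
    cds: str,
    t_my: float,
    rng: np.random.Generator,
    omega: float,
    syn_rate: float,
) -> str:
    """Evolve a CDS for ``t_my`` MY of codon substitution.

    Mutations are proposed uniformly over positions and alternative
    bases; synonymous proposals are always accepted, non-synonymous ones
    with probability ``omega``, and proposals creating a stop codon are
    rejected, so the realized Ka/Ks tracks ``omega`` and the realized Ks
    tracks ``syn_rate * t_my`` (before multiple-hit correction). A
    terminal stop codon is held fixed.
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    has_stop = codons[-1] in STOP_CODONS
    core = codons[:-1] if has_stop else codons
    L = len(core)
    # Attempts are uniform over the 3L positions x 3 alternative bases, so
    # accepted synonymous changes per synonymous site come out to
    # lam * S/(3L) / S = lam/(3L); lam = 3L * syn_rate * t gives Ks ~ syn_rate*t.
    lam = 3.0 * syn_rate * L * t_my
    n = rng.poisson(lam)
    if n:
        pos = rng.integers(0, 3 * L, size=n)
        alt = rng.integers(0, 3, size=n)
        u = rng.random(n)
        for i in range(n):
            ci, cp = divmod(int(pos[i]), 3)
            key = (core[ci], cp, int(alt[i]))
            entry = _MUT.get(key)
            if entry is None:  # current codon mutated into stop? cannot happen
                continue
            new, kind = entry
            if kind == "stop":
                continue
            if kind == "syn" or u[i] < omega:
                core[ci] = new
    return "".join(core) + (codons[-1] if has_stop else "")


def simulate_divergent_pair(
    n_codons: int,
    omega: float,
    ks_total: float,
    rng: np.random.Generator,
    syn_rate: float = 0.006,
) -> tuple[str, str]:
    """Two CDSs diverged from a common ancestor to total Ks ``ks_total``."""
    anc = random_cds(rng, n_codons)
    t_half = ks_total / syn_rate / 2.0
    a = evolve_cds(anc, t_half, rng, omega, syn_rate)
    b = evolve_cds(anc, t_half, rng, omega, syn_rate)
    return a, b


# ---------------------------------------------------------------- the clade

def _tree_paths() -> dict[str, list[tuple[str, float]]]:
    """Branch segments (label, length MY) from the root to each tip."""
    return {
        "wheat": [("root-n54", 6.0), ("n54-n39", 15.0), ("tip", 39.0)],
        "brachypodium": [("root-n54", 6.0), ("n54-n39", 15.0), ("tip", 39.0)],
        "rice": [("root-n54", 6.0), ("tip", 54.0)],
        "sorghum": [("tip", 60.0)],
    }


def _position_weights(n_slots: int, bias: float) -> np.ndarray:
    """Insertion-slot weights: ``w(x) = 1 + bias * (d(x) - 1/2)`` with
    ``d`` the normalized distance from the chromosome midpoint
    (centromere). ``bias > 0`` favors distal slots, ``bias < 0``
    pericentromeric ones; ``|bias| < 2`` keeps weights positive."""
    x = (np.arange(n_slots) + 0.5) / n_slots
    d = 2.0 * np.abs(x - 0.5)
    w = 1.0 + bias * (d - 0.5)
    w = np.clip(w, 1e-9, None)
    return w / w.sum()


def simulate_clade(config: SimulationConfig) -> CladeBundle:
    """Generate the four-species bundle plus ground truth. See module
    docstring for the model; the returned bundle is fully in-memory and
    :func:`write_bundle` serializes it to GFF3/FASTA/TSV."""
    rng = np.random.default_rng(config.seed)
    species = list(config.species)
    if len(species) != 4:
        raise ValueError("the fixed topology requires exactly 4 species")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    study = config.study_chromosome
    if study not in chroms:
        raise ValueError(f"study chromosome {study} not among {chroms}")

    for sp in species:
        for table in (config.duplication_rate, config.translocation_rate):
            r = config.rate_of(table, sp)
            if r * TIP_BRANCH[sp] > 1.0:
                warnings.warn(
                    f"{sp}: rate {r}/locus/MY implies >1 expected event per "
                    "locus on its terminal branch; multiple events allowed"
                )

    # --- ancestral loci -----------------------------------------------
    n = config.n_ancestral_genes
    per_chrom = [n // len(chroms)] * len(chroms)
    for i in range(n % len(chroms)):
        per_chrom[i] += 1
    loci: list[dict] = []
    for ci, chrom in enumerate(chroms):
        for j in range(per_chrom[ci]):
            loci.append({"locus": f"L{len(loci):04d}", "chrom": chrom})
    locus_by_id = {l["locus"]: l for l in loci}

    codon_counts = rng.integers(config.min_codons, config.max_codons + 1, size=len(loci))
    for l, nc in zip(loci, codon_counts):
        l["root_seq"] = random_cds(rng, int(nc))
        l["paralog_of"] = None

    # ancient paralogs of study-chromosome loci, placed on donor chromosomes
    study_loci = [l for l in loci if l["chrom"] == study]
    donor_chroms = [c for c in chroms if c != study]
    n_par = round(config.ancient_paralog_fraction * len(study_loci))
    paralog_sources = [study_loci[i] for i in
                       sorted(rng.choice(len(study_loci), size=n_par, replace=False))]
    for src in paralog_sources:
        src["has_paralog"] = True
        chrom = donor_chroms[rng.integers(0, len(donor_chroms))]
        par = {
            "locus": f"P{src['locus'][1:]}",
            "chrom": chrom,
            "root_seq": evolve_cds(
                src["root_seq"], config.ancient_paralog_extra_my, rng,
                config.omega, config.syn_subs_per_my,
            ),
            "paralog_of": src["locus"],
        }
        loci.append(par)
        locus_by_id[par["locus"]] = par

    # annotation dropout: study loci (with a paralog when available) whose
    # gene models are omitted from every non-focal annotation while the
    # sequence stays in the chromosome.
    dropout_pool = [l for l in study_loci if l.get("has_paralog")] or study_loci
    n_drop = round(config.annotation_dropout_rate * len(study_loci))
    n_drop = min(n_drop, len(dropout_pool))
    dropout_ids = {
        dropout_pool[i]["locus"]
        for i in sorted(rng.choice(len(dropout_pool), size=n_drop, replace=False))
    }

    # --- sequence evolution along the shared part of the tree ---------
    paths = _tree_paths()
    omega, mu = config.omega, config.syn_subs_per_my
    node_seqs: dict[str, dict[str, str]] = {"root": {l["locus"]: l["root_seq"] for l in loci}}
    # internal nodes
    node_seqs["n54"] = {
        k: evolve_cds(s, 6.0, rng, omega, mu) for k, s in node_seqs["root"].items()
    }
    node_seqs["n39"] = {
        k: evolve_cds(s, 15.0, rng, omega, mu) for k, s in node_seqs["n54"].items()
    }
    parent_node = {"wheat": "n39", "brachypodium": "n39", "rice": "n54", "sorghum": "n54"}

    truth = CladeTruth()
    bundles: dict[str, SpeciesBundle] = {}
    close_relatives: dict[str, dict[str, str]] = {}
    focal = config.focal_species

    for sp in species:
        sp_rng = np.random.default_rng(rng.integers(0, 2**31))
        T = TIP_BRANCH[sp]
        parent = node_seqs[parent_node[sp]]
        dup_r = config.rate_of(config.duplication_rate, sp)
        tra_r = config.rate_of(config.translocation_rate, sp)

        # event draws per locus on the terminal branch
        events: list[dict] = []
        lost: set[str] = set()
        tip_seqs: dict[str, str] = {}
        # homeolog-mode side sets: locus -> protein, filled on the fly
        rel_sets: dict[str, dict[str, str]] = (
            {"homeologA": {}, "homeologD": {}, "sister": {}}
            if (config.homeolog_mode and sp == focal)
            else {}
        )

        def _evolve_segments(seq: str, breaks: list[float], om: float):
            """Evolve from T MY ago to the present, returning the states at
            each requested time-before-present in ``breaks`` (descending)
            plus the tip state."""
            states = []
            cur = seq
            t_prev = T
            for b in breaks:
                cur = evolve_cds(cur, t_prev - b, sp_rng, om, mu)
                states.append((b, cur))
                t_prev = b
            cur = evolve_cds(cur, t_prev, sp_rng, om, mu)
            return states, cur

        sister_t = config.sister_split_my
        homeo_t = config.homeolog_split_my
        breaks = (
            [sister_t, homeo_t] if (config.homeolog_mode and sp == focal) else []
        )

        for l in loci:
            locus = l["locus"]
            seq0 = parent[locus]
            states, tip = _evolve_segments(seq0, breaks, omega)
            tip_seqs[locus] = tip
            state_at = dict(states)
            # close-relative sets mirror the annotated gene content of the
            # homeologous/sister *study* chromosome only
            if rel_sets and l["chrom"] == study:
                rel_sets["sister"][locus] = translate_cds(
                    evolve_cds(state_at[sister_t], sister_t, sp_rng, omega, mu)
                ).rstrip("*")
                for h in ("homeologA", "homeologD"):
                    rel_sets[h][locus] = translate_cds(
                        evolve_cds(state_at[homeo_t], homeo_t, sp_rng, omega, mu)
                    ).rstrip("*")

            for kind, r in (("duplication", dup_r), ("translocation", tra_r)):
                if sp_rng.random() < r * T:
                    t_ev = float(sp_rng.uniform(0.0, T))
                    dest_choices = [c for c in chroms if c != l["chrom"]]
                    dest = dest_choices[sp_rng.integers(0, len(dest_choices))]
                    # the copy shares history until t_ev: approximate the
                    # lineage state at t_ev by re-evolving the relevant span
                    om_copy = (
                        config.omega_nonsyntenic
                        if dest == study
                        else omega
                    )
                    anc_at_ev = evolve_cds(seq0, T - t_ev, sp_rng, omega, mu)
                    copy_tip = evolve_cds(anc_at_ev, t_ev, sp_rng, om_copy, mu)
                    events.append(
                        {
                            "locus": locus,
                            "kind": kind,
                            "time": t_ev,
                            "dest": dest,
                            "seq": copy_tip,
                        }
                    )
                    if kind == "translocation":
                        lost.add(locus)
                    if rel_sets and dest == study:
                        prot = translate_cds(copy_tip).rstrip("*")
                        if t_ev > sister_t:
                            rel_sets["sister"][locus + "_c"] = prot
                        if t_ev > homeo_t:
                            for h in ("homeologA", "homeologD"):
                                rel_sets[h][locus + "_c"] = prot

        # --- assemble per-chromosome gene orders ----------------------
        chrom_orders: dict[str, list[dict]] = {c: [] for c in chroms}
        for l in loci:
            if l["locus"] in lost:
                continue
            annotated = not (l["locus"] in dropout_ids and sp != focal)
            chrom_orders[l["chrom"]].append(
                {
                    "locus": l["locus"],
                    "gene_id": f"{sp}_{l['locus']}",
                    "seq": tip_seqs[l["locus"]],
                    "class": "syntenic",
                    "annotated": annotated,
                    "event": "",
                    "time": float("nan"),
                    "retained": True,
                    "has_paralog": bool(l.get("has_paralog")),
                    "dropout": l["locus"] in dropout_ids,
                }
            )
        for k, ev in enumerate(events):
            order = chrom_orders[ev["dest"]]
            if ev["dest"] == study and config.distal_retention_bias != 0.0:
                w = _position_weights(len(order) + 1, config.distal_retention_bias)
                slot = int(sp_rng.choice(len(order) + 1, p=w))
            else:
                slot = int(sp_rng.integers(0, len(order) + 1))
            order.insert(
                slot,
                {
                    "locus": ev["locus"],
                    "gene_id": f"{sp}_{ev['locus']}_c{k}",
                    "seq": ev["seq"],
                    "class": "non-syntenic",
                    "annotated": True,
                    "event": ev["kind"],
                    "time": ev["time"],
                    "retained": ev["kind"] == "duplication",
                    "has_paralog": False,
                    "dropout": False,
                },
            )

        # TE decoys on the study chromosome
        n_te = round(config.te_decoy_fraction * per_chrom[chroms.index(study)])
        for k in range(n_te):
            order = chrom_orders[study]
            slot = int(sp_rng.integers(0, len(order) + 1))
            nc = int(sp_rng.integers(config.min_codons, config.max_codons + 1))
            order.insert(
                slot,
                {
                    "locus": "TE",
                    "gene_id": f"{sp}_te{k:03d}",
                    "seq": random_cds(sp_rng, nc),
                    "class": "decoy",
                    "annotated": True,
                    "event": "",
                    "time": float("nan"),
                    "retained": True,
                    "has_paralog": False,
                    "dropout": False,
                    "te": True,
                    # half flagged via annotation class, half via description
                    "te_by_desc": k % 2 == 1,
                },
            )

        # pseudogenization of study-chromosome genes
        pseudo_types = ("internal_stop", "frameshift", "truncation")
        for entry in chrom_orders[study]:
            if entry.get("te"):
                continue
            if sp_rng.random() < config.pseudogenization_prob:
                ptype = pseudo_types[sp_rng.integers(0, 3)]
                seq = entry["seq"]
                ncod = len(seq) // 3
                if ptype == "internal_stop":
                    ci = int(sp_rng.integers(int(ncod * 0.5), int(ncod * 0.9)))
                    stop = ["TAA", "TGA", "TAG"][sp_rng.integers(0, 3)]
                    seq = seq[: 3 * ci] + stop + seq[3 * ci + 3 :]
                elif ptype == "frameshift":
                    pos = int(sp_rng.integers(int(len(seq) * 0.5), int(len(seq) * 0.9)))
                    seq = seq[:pos] + seq[pos + 1 :]  # 1-bp deletion
                else:  # truncation below 70 % of the complete homolog
                    frac = float(sp_rng.uniform(0.30, 0.65))
                    keep = max(6, 3 * int(ncod * frac))
                    seq = seq[:keep]
                entry["seq"] = seq
                entry["pseudo"] = ptype

        # ASV decoys: extra (shorter) transcript on a fraction of study genes
        for entry in chrom_orders[study]:
            if entry.get("te") or entry.get("pseudo"):
                continue
            if sp_rng.random() < config.asv_decoy_fraction:
                entry["asv"] = True

        # --- build chromosome sequences and gene models ---------------
        genes: list[GeneModel] = []
        chrom_seqs: dict[str, str] = {}
        for chrom in chroms:
            parts: list[str] = []
            cursor = 0
            for entry in chrom_orders[chrom]:
                spacer = random_nt(sp_rng, config.intergenic_bp)
                parts.append(spacer)
                cursor += len(spacer)
                seq = entry["seq"]
                strand = "+" if sp_rng.random() < 0.5 else "-"
                multi = (
                    config.multi_exon_fraction > 0
                    and len(seq) >= 60
                    and sp_rng.random() < config.multi_exon_fraction
                )
                if multi:
                    cut = 3 * (len(seq) // 6)
                    intron = random_nt(sp_rng, config.intron_bp)
                    genomic = seq[:cut] + intron + seq[cut:]
                    exon_mrna = [(1, cut), (cut + len(intron) + 1, len(genomic))]
                else:
                    genomic = seq
                    exon_mrna = [(1, len(genomic))]
                gstart = cursor + 1
                gend = cursor + len(genomic)
                if strand == "+":
                    intervals = [(gstart + s - 1, gstart + e - 1) for s, e in exon_mrna]
                    placed = genomic
                else:
                    intervals = [
                        (gend - e + 1, gend - s + 1) for s, e in exon_mrna
                    ][::-1]
                    placed = _revcomp(genomic)
                parts.append(placed)
                cursor += len(placed)
                if entry["annotated"]:
                    exons = sorted(intervals, reverse=(strand == "-"))
                    tr = TranscriptModel(
                        transcript_id=f"{entry['gene_id']}.1",
                        exons=exons,
                        cds=list(exons),
                        cds_seq=seq,
                    )
                    tr.protein = tr.translate()
                    transcripts = [tr]
                    if entry.get("asv") and len(intervals) == 1:
                        # shorter isoform: first 60 % of the CDS
                        keep = 3 * (len(seq) // 5)
                        if strand == "+":
                            sub = [(intervals[0][0], intervals[0][0] + keep - 1)]
                        else:
                            sub = [(intervals[-1][1] - keep + 1, intervals[-1][1])]
                        tr2 = TranscriptModel(
                            transcript_id=f"{entry['gene_id']}.2",
                            exons=list(sub),
                            cds=list(sub),
                            cds_seq=seq[:keep],
                        )
                        tr2.protein = tr2.translate()
                        transcripts.append(tr2)
                    desc = ""
                    te_flag = False
                    if entry.get("te"):
                        if entry.get("te_by_desc"):
                            desc = "retrotransposon protein"
                        else:
                            te_flag = True
                    genes.append(
                        GeneModel(
                            gene_id=entry["gene_id"],
                            species=sp,
                            chromosome=chrom,
                            start=gstart,
                            end=gend,
                            strand=strand,
                            transcripts=transcripts,
                            is_te_related=te_flag,
                            description=desc,
                        )
                    )
                # truth for every emitted (placed) gene, annotated or not
                if entry["class"] == "decoy":
                    t_class = "decoy"
                else:
                    t_class = entry["class"]
                stratum = "n/a"
                if (
                    sp == focal
                    and entry["class"] == "non-syntenic"
                    and config.homeolog_mode
                ):
                    stratum = (
                        "recent" if entry["time"] < config.homeolog_split_my else "old"
                    )
                truth.records.append(
                    TruthRecord(
                        species=sp,
                        gene_id=entry["gene_id"],
                        ancestral_locus=entry["locus"],
                        chromosome=chrom,
                        true_class=t_class,
                        age_stratum=stratum,
                        event=entry["event"],
                        event_time_my=entry["time"],
                        ancestral_retained=entry["retained"],
                        pseudogene_type=entry.get("pseudo", ""),
                        is_te_decoy=bool(entry.get("te")),
                        has_asv_decoy=bool(entry.get("asv")),
                        annotation_dropout=entry["dropout"],
                        has_ancient_paralog=entry["has_paralog"],
                        annotated=entry["annotated"],
                    )
                )
            parts.append(random_nt(sp_rng, config.intergenic_bp))
            chrom_seqs[chrom] = "".join(parts)
        bundles[sp] = SpeciesBundle(species=sp, genes=genes, chromosomes=chrom_seqs)
        if rel_sets:
            close_relatives = rel_sets

    # --- synteny map and lineage config -------------------------------
    smap = SyntenyMap()
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            for chrom in chroms:
                smap.add_block(
                    a, chrom, 1, len(bundles[a].chromosomes[chrom]),
                    b, chrom, 1, len(bundles[b].chromosomes[chrom]),
                )
    for sp in species:
        for chrom in chroms:
            smap.set_centromere(sp, chrom, len(bundles[sp].chromosomes[chrom]) // 2)

    lineage = LineageConfig(species=species)
    div = {
        ("wheat", "brachypodium"): 39.0,
        ("wheat", "rice"): 54.0, ("brachypodium", "rice"): 54.0,
        ("wheat", "sorghum"): 60.0, ("brachypodium", "sorghum"): 60.0,
        ("rice", "sorghum"): 60.0,
    }
    for (a, b), t in div.items():
        lineage.set_divergence(a, b, t)
    lineage.outgroups = {"sorghum"}
    lineage.homeolog_groups = [{study}]

    return CladeBundle(
        config=config,
        species=bundles,
        synteny_map=smap,
        lineage=lineage,
        truth=truth,
        close_relatives=close_relatives,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------- outputs

def write_bundle(bundle: CladeBundle, outdir: Union[str, Path]) -> None:
    """Serialize a clade bundle: per-species GFF3 + genome FASTA, the
    truth table as TSV, and the config as flat key=value text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, sb in bundle.species.items():
        gio.write_gff3(sb.genes, outdir / f"{sp}.gff3")
        gio.write_fasta(sb.chromosomes, outdir / f"{sp}.genome.fasta")
    gio.write_table(bundle.truth.to_dataframe(), outdir / "truth.tsv")
    with open(outdir / "config.txt", "w") as fh:
        for key, val in asdict(bundle.config).items():
            fh.write(f"{key}={val}\n")
    for name, prots in bundle.close_relatives.items():
        gio.write_fasta(prots, outdir / f"relative_{name}.proteins.fasta")


def load_bundle_species(outdir: Union[str, Path], species: str) -> SpeciesBundle:
    outdir = Path(outdir)
    chrom = gio.read_fasta(outdir / f"{species}.genome.fasta")
    genes = gio.read_gff3(outdir / f"{species}.gff3", fasta=chrom, species=species)
    return SpeciesBundle(species=species, genes=genes, chromosomes=chrom)


def simulate_expression_table(
    truth: CladeTruth,
    config: SimulationConfig,
    species: Optional[str] = None,
) -> pd.DataFrame:
    """Per-gene expression table (gene, condition, FPKM-like value) for the
    focal species' study chromosome, standing in for an RNA-seq
    quantification stage. Class-wise breadth/level follow
    ``config.expression``; a seed-fixed run is fully deterministic."""
    sp = species or config.focal_species
    prm = config.expression
    rng = np.random.default_rng(config.seed + 101)
    rows = []
    for rec in truth.study_records(sp, config.study_chromosome):
        if rec.true_class == "decoy" or rec.pseudogene_type:
            continue
        klass = rec.true_class
        p_expr = prm.expressed_prob[klass]
        expressed = rng.random() < p_expr
        n_cond = prm.n_conditions
        if expressed:
            b = min(max(prm.mean_breadth[klass] / n_cond, 1.0 / n_cond), 1.0)
            breadth = 0
            while breadth == 0:
                breadth = rng.binomial(n_cond, b)
            which = rng.choice(n_cond, size=breadth, replace=False)
            mean_level = prm.mean_level[klass]
            # lognormal with unit-sigma shape scaled to the class mean
            levels = rng.lognormal(mean=0.0, sigma=1.0, size=breadth)
            levels = levels / np.exp(0.5) * mean_level
        else:
            which = np.array([], dtype=int)
            levels = np.array([])
        value_by_cond = dict(zip(which.tolist(), levels.tolist()))
        for cond in range(n_cond):
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "condition": f"cond{cond:02d}",
                    "fpkm": float(value_by_cond.get(cond, 0.0)),
                }
            )
    return pd.DataFrame(rows)


def simulate_annotation(
    truth: CladeTruth,
    config: SimulationConfig,
    n_terms: int = 12,
    enriched_term: str = "programmed cell death",
    enrichment_factor: float = 3.0,
) -> pd.DataFrame:
    """Flat gene -> GO-like term annotation for the focal study genes,
    with one term over-assigned to non-syntenic genes so the enrichment
    stage has signal to find."""
    rng = np.random.default_rng(config.seed + 202)
    rows = []
    terms = [(f"GO:{7000 + i:07d}", f"process_{i}") for i in range(n_terms)]
    special = ("GO:0012501", enriched_term)
    for rec in truth.study_records(config.focal_species, config.study_chromosome):
        if rec.true_class == "decoy" or rec.pseudogene_type:
            continue
        for tid, tname in terms:
            if rng.random() < 0.08:
                rows.append({"gene_id": rec.gene_id, "term_id": tid, "term_name": tname})
        p = 0.03 * (enrichment_factor if rec.true_class == "non-syntenic" else 1.0)
        if rng.random() < p:
            rows.append(
                {"gene_id": rec.gene_id, "term_id": special[0], "term_name": special[1]}
            )
    return pd.DataFrame(rows)


def simulate_landscape_genes(
    n_genes: int,
    chrom_length: int,
    frac_nonsyntenic: float,
    bias: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene midpoints and classes for chromosomal-landscape studies.

    Syntenic genes are uniform along the chromosome; non-syntenic gene
    positions are drawn with the retention-bias weighting of
    :func:`_position_weights` (positive = distal excess, negative =
    pericentromeric excess, centromere at the midpoint).
    """
    n_ns = int(round(frac_nonsyntenic * n_genes))
    n_s = n_genes - n_ns
    pos_s = rng.uniform(0, chrom_length, size=n_s)
    grid = 1000
    w = _position_weights(grid, bias)
    cells = rng.choice(grid, size=n_ns, p=w)
    pos_ns = (cells + rng.random(n_ns)) / grid * chrom_length
    positions = np.concatenate([pos_s, pos_ns])
    classes = np.array(["syntenic"] * n_s + ["non-syntenic"] * n_ns)
    order = np.argsort(positions)
    return positions[order], classes[order]
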