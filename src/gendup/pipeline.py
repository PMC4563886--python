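"""End-to-end orchestration: filter -> search -> classify -> rates ->
landscape -> Ka/Ks -> enrichment.

:func:`run_analysis` works on an in-memory clade bundle (simulated or
loaded from disk) and returns all per-stage results; :func:`run_all`
wraps it with file I/O for the command line. Every threshold is carried
in :class:`RunConfig` with the published defaults (protein homology
e <= 1e-5, >= 35 % identity / 35 % overlap; nucleotide reclassification
>= 80 % identity / 50 % overlap; pseudogene length fraction 0.70) and is
logged when used.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import io as gio
from .classify import (
    build_families_and_pick_representatives,
    classify_gene,
    detect_duplicate_origin,
    reclassify_by_genomic_search,
    stratify_age,
)
from .enrich import compare_features, enrich, expression_features, structural_features
from .filtration import FilterThresholds, collapse_isoforms, remove_te_genes, run_filtration
from .homology import NucleotideIndex, ProteinSearch, SearchParams, best_hits
from .kaks import fixation_rate, kaks_cohort, round_sig
from .landscape import (
    age_stratified_profiles,
    centromere_distance_correlation,
    sliding_proportion,
)
from .models import SyntenyCall
from .simulate import CladeBundle, SimulationConfig, simulate_clade

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline thresholds and stage toggles (defaults = published values)."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    best_hit_max_evalue: float = 1e-5
    reclass_min_identity: float = 80.0
    reclass_min_overlap: float = 50.0
    search_params: SearchParams = field(
        default_factory=lambda: SearchParams(max_candidates=8, max_full_alignments=2)
    )
    #: landscape window/step as fractions of chromosome length, per species
    window_fraction: float = 0.10
    step_fraction: float = 0.01
    kaks_outgroup: str = "brachypodium"
    run_reclassify: bool = True
    run_origin: bool = True
    run_landscape: bool = True
    run_kaks: bool = True
    run_age: bool = True
    run_expression: bool = False
    run_enrichment: bool = False
    seed: int = 0


@dataclass
class SpeciesResult:
    species: str
    report: object
    calls: dict[str, SyntenyCall]
    core_ids: list[str]
    rate: object
    profile: object = None
    correlation: Optional[float] = None


@dataclass
class AnalysisResult:
    per_species: dict[str, SpeciesResult]
    summary: pd.DataFrame
    kaks: Optional[dict] = None
    age_profiles: Optional[dict] = None
    families: Optional[list] = None
    feature_comparison: Optional[pd.DataFrame] = None
    enrichment: Optional[dict] = None


def _stage(name: str, t0: float, n_in: int, n_out: int) -> None:
    logger.info(
        "stage=%s in=%d out=%d wall=%.2fs", name, n_in, n_out, time.time() - t0
    )


def prepare_search(bundle: CladeBundle, rcfg: Optional[RunConfig] = None) -> dict:
    """Collapse isoforms, drop TE genes, and build one protein-search
    engine per species (shared by all per-species analyses)."""
    rcfg = rcfg or RunConfig()
    species = list(bundle.species)
    prepared = {}
    for sp in species:
        genes_all = remove_te_genes(collapse_isoforms(bundle.species[sp].genes))
        prot = {}
        for g in genes_all:
            p = g.primary_transcript().protein
            if p:
                prot[g.gene_id] = p.rstrip("*")
        prepared[sp] = {
            "genes": genes_all,
            "proteins": prot,
            "index": {g.gene_id: g for g in genes_all},
        }
    return {
        "prepared": prepared,
        "species_of": {gid: sp for sp in species for gid in prepared[sp]["proteins"]},
        "subject_lengths": {
            gid: len(p) for sp in species for gid, p in prepared[sp]["proteins"].items()
        },
        "engines": {
            sp: ProteinSearch(prepared[sp]["proteins"], rcfg.search_params)
            for sp in species
        },
    }


def cross_species_hits(bundle: CladeBundle, sp: str, prep: dict) -> list:
    """Hits of one species' (collapsed, TE-free) study-chromosome genes
    against every other species, with subject locations annotated."""
    study = bundle.config.study_chromosome
    collapsed = [
        g for g in prep["prepared"][sp]["genes"] if g.chromosome == study
    ]
    hits = []
    for other in bundle.species:
        if other == sp:
            continue
        engine = prep["engines"][other]
        gene_idx = prep["prepared"][other]["index"]
        for g in collapsed:
            p = g.primary_transcript().protein
            if not p:
                continue
            for h in engine.search_one(g.gene_id, p.rstrip("*")):
                og = gene_idx.get(h.subject_id)
                if og is not None:
                    h.subject_chromosome = og.chromosome
                    h.subject_pos = og.midpoint
                hits.append(h)
    return hits


def run_analysis(bundle: CladeBundle, rcfg: Optional[RunConfig] = None) -> AnalysisResult:
    """Run the full classification pipeline on a clade bundle."""
    rcfg = rcfg or RunConfig()
    cfg = bundle.config
    study = cfg.study_chromosome
    species = list(bundle.species)
    focal = cfg.focal_species

    prep = prepare_search(bundle, rcfg)
    prepared = prep["prepared"]
    species_of = prep["species_of"]
    subject_lengths = prep["subject_lengths"]
    engines = prep["engines"]
    ortho_index = {}
    if rcfg.run_reclassify:
        ortho_index = {
            sp: NucleotideIndex(
                {study: bundle.species[sp].chromosomes[study]}
            )
            for sp in species
        }

    per_species: dict[str, SpeciesResult] = {}
    summary_rows = []
    for sp in species:
        t0 = time.time()
        sb = bundle.species[sp]
        study_genes = [g for g in sb.genes if g.chromosome == study]
        hits = cross_species_hits(bundle, sp, prep)
        _stage(f"{sp}:search", t0, len(study_genes), len(hits))

        t0 = time.time()
        core, report = run_filtration(
            study_genes, hits, species_of, sp, rcfg.thresholds, subject_lengths
        )
        _stage(f"{sp}:filtration", t0, len(study_genes), len(core))

        t0 = time.time()
        bhs = best_hits(hits, species_of, rcfg.best_hit_max_evalue)
        calls: dict[str, SyntenyCall] = {}
        for g in core:
            best = bhs.get(g.gene_id)
            if best is None:
                continue
            calls[g.gene_id] = classify_gene(g, best, bundle.synteny_map)
        core_ids = sorted(calls)
        _stage(f"{sp}:classify", t0, len(core), len(calls))

        gene_index = {g.gene_id: g for g in core}
        cds = {}
        for g in core:
            c = g.primary_transcript().cds_seq
            if c:
                cds[g.gene_id] = c

        if rcfg.run_reclassify:
            t0 = time.time()
            counterparts = {
                other: bundle.synteny_map.counterpart_chromosomes(sp, study, other)
                for other in species
                if other != sp
            }
            indexes = {o: ortho_index[o] for o in counterparts}
            n_ns0 = sum(c.klass == "non-syntenic" for c in calls.values())
            reclassify_by_genomic_search(
                calls, gene_index, cds, indexes, counterparts,
                rcfg.reclass_min_identity, rcfg.reclass_min_overlap,
            )
            n_ns1 = sum(c.klass == "non-syntenic" for c in calls.values())
            _stage(f"{sp}:reclassify", t0, n_ns0, n_ns1)

        if rcfg.run_origin:
            t0 = time.time()
            survey = {
                c: seq for c, seq in sb.chromosomes.items() if c != study
            }
            homeo = {study: bundle.lineage.homeologs_of(study)}
            detect_duplicate_origin(
                calls, gene_index, cds, NucleotideIndex(survey), homeo,
                rcfg.reclass_min_identity, rcfg.reclass_min_overlap,
            )
            _stage(f"{sp}:origin", t0, len(calls), len(calls))

        n_total = len(calls)
        n_ns = sum(c.klass == "non-syntenic" for c in calls.values())
        T = min(
            bundle.lineage.divergence(sp, other)
            for other in species
            if other != sp
        )
        rate = fixation_rate(n_ns, n_total, T) if n_total else None

        profile = None
        corr = None
        if rcfg.run_landscape and calls:
            chrom_len = len(sb.chromosomes[study])
            window = max(int(chrom_len * rcfg.window_fraction), 1)
            step = max(int(chrom_len * rcfg.step_fraction), 1)
            positions = [gene_index[g].midpoint for g in core_ids]
            klasses = [calls[g].klass for g in core_ids]
            profile = sliding_proportion(
                positions, klasses, window, step, chrom_len,
                centromere=bundle.synteny_map.centromeres.get((sp, study)),
                chromosome=study,
            )
            try:
                corr = centromere_distance_correlation(profile)
            except ValueError:
                corr = None

        per_species[sp] = SpeciesResult(
            species=sp, report=report, calls=calls, core_ids=core_ids,
            rate=rate, profile=profile, correlation=corr,
        )
        row = {
            "species": sp,
            **{f"n_{k}": v for k, v in report.counts.items()},
            "n_core": n_total,
            "n_syntenic": n_total - n_ns,
            "n_nonsyntenic": n_ns,
            "pct_nonsyntenic": round(100.0 * n_ns / n_total, 1) if n_total else 0.0,
            "n_reclassified": sum(c.reclassified for c in calls.values()),
            "divergence_my": T,
            "fixation_rate": round_sig(rate.rate, 2) if rate else 0.0,
            "centromere_r": corr,
        }
        summary_rows.append(row)

    result = AnalysisResult(
        per_species=per_species, summary=pd.DataFrame(summary_rows)
    )

    focal_res = per_species[focal]
    focal_prepared = prepared[focal]

    if rcfg.run_age and bundle.close_relatives:
        t0 = time.time()
        proteins = {
            gid: focal_prepared["proteins"][gid]
            for gid in focal_res.core_ids
            if gid in focal_prepared["proteins"]
        }
        stratify_age(
            focal_res.calls, proteins, bundle.close_relatives, rcfg.thresholds,
            rcfg.search_params,
        )
        # duplicate families among focal study genes, for representatives
        intra_hits = []
        focal_engine = ProteinSearch(proteins, rcfg.search_params)
        for gid in focal_res.core_ids:
            if gid in proteins:
                intra_hits.extend(focal_engine.search_one(gid, proteins[gid]))
        ns_ids = [
            gid for gid, c in focal_res.calls.items() if c.klass == "non-syntenic"
        ]
        families = build_families_and_pick_representatives(
            ns_ids,
            [h for h in intra_hits
             if h.query_id in ns_ids and h.subject_id in ns_ids],
            rcfg.seed,
            gene_lengths={g: len(proteins[g]) for g in ns_ids if g in proteins},
            thresholds=rcfg.thresholds,
        )
        result.families = families
        reps = {f.representative for f in families}
        sbf = bundle.species[focal]
        chrom_len = len(sbf.chromosomes[study])
        gene_index = {g.gene_id: g for g in sbf.genes}
        positions = {
            gid: gene_index[gid].midpoint for gid in focal_res.core_ids
        }
        strata = {
            gid: c.age_stratum
            for gid, c in focal_res.calls.items()
            if c.age_stratum in ("recent", "old")
        }
        result.age_profiles = age_stratified_profiles(
            positions, strata, reps,
            max(int(chrom_len * rcfg.window_fraction), 1),
            max(int(chrom_len * rcfg.step_fraction), 1),
            chrom_len,
            centromere=bundle.synteny_map.centromeres.get((focal, study)),
            chromosome=study,
        )
        _stage("age_stratification", t0, len(focal_res.calls), len(strata))

    if rcfg.run_kaks:
        t0 = time.time()
        outgroup = rcfg.kaks_outgroup
        target_cds = bundle.species[outgroup].cds()
        focal_cds = bundle.species[focal].cds()
        # recompute best hits focal->outgroup from calls' evidence is not
        # stored; redo a quick best-hit pass through the engine
        engine = engines[outgroup]
        pairs: dict[str, list[tuple[str, str]]] = {"syntenic": [], "non-syntenic": []}
        for gid, call in focal_res.calls.items():
            p = focal_prepared["proteins"].get(gid)
            if p is None or gid not in focal_cds:
                continue
            hs = engine.search_one(gid, p)
            if not hs or hs[0].evalue > rcfg.best_hit_max_evalue:
                continue
            sid = hs[0].subject_id
            if sid in target_cds:
                pairs[call.klass].append((focal_cds[gid], target_cds[sid]))
        result.kaks = kaks_cohort(pairs)
        _stage("kaks_cohort", t0, len(focal_res.calls),
               sum(len(v) for v in pairs.values()))

    if rcfg.run_expression or rcfg.run_enrichment:
        from .simulate import simulate_annotation, simulate_expression_table

        truth = bundle.truth
        class_of = {
            gid: c.klass for gid, c in focal_res.calls.items()
        }
        if rcfg.run_expression:
            expr = simulate_expression_table(truth, cfg)
            feats = expression_features(expr)
            struct = structural_features(
                [g for g in prepared[focal]["genes"]
                 if g.gene_id in focal_res.calls]
            )
            features = struct.join(feats, how="left")
            result.feature_comparison = compare_features(class_of, features)
        if rcfg.run_enrichment:
            ann = simulate_annotation(truth, cfg)
            background = set(class_of)
            result.enrichment = {}
            for klass in ("syntenic", "non-syntenic"):
                study_set = {g for g, k in class_of.items() if k == klass}
                if study_set:
                    result.enrichment[klass] = enrich(study_set, background, ann)
    return result


def run_all(
    out_dir: Union[str, Path],
    bundle: Optional[CladeBundle] = None,
    sim_config: Optional[SimulationConfig] = None,
    rcfg: Optional[RunConfig] = None,
) -> AnalysisResult:
    """File-level entry point: simulate (or accept) a bundle, run the
    analysis, and write per-stage TSVs plus a summary table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rcfg = rcfg or RunConfig()
    if bundle is None:
        bundle = simulate_clade(sim_config or SimulationConfig(seed=rcfg.seed))
    result = run_analysis(bundle, rcfg)
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    for sp, res in result.per_species.items():
        rows = [
            {
                "gene_id": gid,
                "class": c.klass,
                "reclassified": c.reclassified,
                "origin": c.origin,
                "age_stratum": c.age_stratum,
                "evidence": ";".join(f"{k}={v}" for k, v in sorted(c.evidence.items())),
            }
            for gid, c in sorted(res.calls.items())
        ]
        gio.write_table(pd.DataFrame(rows), out / f"calls_{sp}.tsv")
        if res.profile is not None:
            res.profile.to_dataframe().to_csv(
                out / f"profile_{sp}.tsv", sep="\t", index=False
            )
    if result.kaks:
        pd.DataFrame(
            [
                {"class": k, **v}
                for k, v in result.kaks["summary"].items()
            ]
        ).to_csv(out / "kaks_summary.tsv", sep="\t", index=False)
    if result.feature_comparison is not None:
        result.feature_comparison.to_csv(
            out / "feature_comparison.tsv", sep="\t", index=False
        )
    if result.enrichment:
        rows = []
        for klass, er in result.enrichment.items():
            for r in er:
                rows.append({"study_class": klass, **r.__dict__})
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return result
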