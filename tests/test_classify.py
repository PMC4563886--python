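"""Synteny classification rules, genomic reclassification, duplication
origin, age strata, and duplicate families."""
import itertools

import numpy as np
import pytest

from gendup.classify import (
    build_families_and_pick_representatives,
    classify_gene,
    detect_duplicate_origin,
    reclassify_by_genomic_search,
    stratify_age,
)
from gendup.homology import NucleotideIndex
from gendup.models import (
    BestHitSet,
    GeneModel,
    HitRecord,
    SyntenyCall,
    SyntenyMap,
    TranscriptModel,
)


def _map3():
    smap = SyntenyMap()
    for other in ("B", "C", "D"):
        for chrom in ("chr1", "chr2", "chr3"):
            smap.add_block("A", chrom, 1, 10_000, other, chrom, 1, 10_000)
    return smap


def _gene(gene_id="q", chrom="chr1", species="A", cds=None):
    cds = cds or ("ATG" + "GCT" * 40 + "TAA")
    tr = TranscriptModel(f"{gene_id}.1", [(1, len(cds))], [(1, len(cds))], cds_seq=cds)
    tr.protein = tr.translate()
    return GeneModel(
        gene_id=gene_id, species=species, chromosome=chrom, start=1,
        end=len(cds), strand="+", transcripts=[tr],
    )


def _hit(subject, chrom, pos=500.0):
    return HitRecord(
        query_id="q", subject_id=subject, pct_identity=90.0, aln_length=100,
        mismatches=0, gap_opens=0, q_start=1, q_end=100, s_start=1, s_end=100,
        evalue=1e-30, bitscore=200.0, subject_chromosome=chrom, subject_pos=pos,
    )


class TestClassifyGene:
    @pytest.mark.parametrize(
        "pattern", list(itertools.product([True, False], repeat=3))
    )
    def test_full_three_species_pattern_space_matches_any_oracle(self, pattern):
        """Enumerate all 2^3 syntenic/non-syntenic best-hit placements over
        three target species; the class must equal the brute-force rule
        'syntenic iff any hit is on a counterpart chromosome'."""
        gene = _gene()
        best = BestHitSet(query_id="q")
        for species_name, on_counterpart in zip(("B", "C", "D"), pattern):
            chrom = "chr1" if on_counterpart else "chr3"
            best.best[species_name] = _hit(f"{species_name.lower()}1", chrom)
        call = classify_gene(gene, best, _map3())
        expected = "syntenic" if any(pattern) else "non-syntenic"
        assert call.klass == expected
        assert len(call.evidence) == 3

    def test_mixed_hits_syntenic_by_at_least_one_rule(self):
        gene = _gene()
        best = BestHitSet(query_id="q")
        best.best["B"] = _hit("b1", "chr1")   # counterpart
        best.best["C"] = _hit("c1", "chr2")   # elsewhere
        assert classify_gene(gene, best, _map3()).klass == "syntenic"

    def test_hit_outside_block_interval_is_not_syntenic(self):
        gene = _gene()
        best = BestHitSet(query_id="q")
        best.best["B"] = _hit("b1", "chr1", pos=50_000)  # beyond block end
        assert classify_gene(gene, best, _map3()).klass == "non-syntenic"

    def test_unmapped_chromosome_counts_as_nonsyntenic_evidence(self):
        gene = _gene()
        best = BestHitSet(query_id="q")
        best.best["B"] = _hit("b1", "scaffold77")
        call = classify_gene(gene, best, _map3())
        assert call.klass == "non-syntenic"

    def test_rate_zero_clade_fully_syntenic(self, clean_bundle):
        from gendup.pipeline import RunConfig, run_analysis

        res = run_analysis(
            clean_bundle,
            RunConfig(run_kaks=False, run_origin=False, run_landscape=False),
        )
        assert (res.summary["n_nonsyntenic"] == 0).all()
        assert (res.summary["pct_nonsyntenic"] == 0.0).all()


class TestReclassify:
    def _setup(self, cds, embed):
        gene = _gene(cds=cds)
        calls = {"q": SyntenyCall(gene_id="q", klass="non-syntenic")}
        rng = np.random.default_rng(0)
        filler = "".join(rng.choice(list("ACGT"), 3000))
        seq = filler[:1500] + (cds if embed else "") + filler[1500:]
        indexes = {"B": NucleotideIndex({"chr1": seq})}
        counterparts = {"B": {"chr1"}}
        return gene, calls, indexes, counterparts

    def test_unannotated_ortholog_sequence_flips_call(self):
        cds = "ATGGCTAGGCATCTTAAAGGCCTTATCGATCGATTTGGCACTGCAAGGACT" * 6
        gene, calls, idx, cp = self._setup(cds, embed=True)
        out = reclassify_by_genomic_search(calls, {"q": gene}, {"q": cds}, idx, cp)
        assert out["q"].klass == "syntenic"
        assert out["q"].reclassified is True

    def test_no_hit_remains_nonsyntenic(self):
        cds = "ATGGCTAGGCATCTTAAAGGCCTTATCGATCGATTTGGCACTGCAAGGACT" * 6
        gene, calls, idx, cp = self._setup(cds, embed=False)
        out = reclassify_by_genomic_search(calls, {"q": gene}, {"q": cds}, idx, cp)
        assert out["q"].klass == "non-syntenic"
        assert out["q"].reclassified is False

    def test_annotation_dropout_genes_flip_exactly(self):
        """Orthologs deleted from annotation but present in sequence are the
        genes (and the only genes) rescued by the genomic search."""
        from gendup.pipeline import RunConfig, run_analysis
        from gendup.simulate import SimulationConfig, simulate_clade

        # events only in the focal lineage so no convergent insertion can
        # place a moved gene's sequence on another species' counterpart
        cfg = SimulationConfig(
            n_ancestral_genes=120, seed=13,
            ancient_paralog_fraction=0.5, annotation_dropout_rate=0.10,
            duplication_rate={"wheat": 6.8e-3, "brachypodium": 0.0,
                              "rice": 0.0, "sorghum": 0.0},
            translocation_rate=0.0,
        )
        bundle = simulate_clade(cfg)
        res = run_analysis(
            bundle, RunConfig(run_kaks=False, run_origin=False, run_landscape=False)
        )
        focal = bundle.config.focal_species
        calls = res.per_species[focal].calls
        dropped = {
            r.gene_id
            for r in bundle.truth.study_records(focal, "chr1")
            if r.annotation_dropout
        }
        flipped = {g for g, c in calls.items() if c.reclassified}
        assert dropped, "dropout condition produced no genes"
        assert flipped == {g for g in dropped if g in calls}


class TestDuplicateOrigin:
    def test_copy_on_nonhomeologous_chromosome_flags_duplication(self):
        cds = "ATGGCTAGGCATCTTAAAGGCCTTATCGATCGATTTGGCACTGCAAGGACT" * 6
        gene = _gene(cds=cds)
        calls = {"q": SyntenyCall(gene_id="q", klass="non-syntenic")}
        rng = np.random.default_rng(1)
        filler = "".join(rng.choice(list("ACGT"), 2000))
        survey = NucleotideIndex({"chr2": filler[:900] + cds + filler[900:]})
        out = detect_duplicate_origin(
            calls, {"q": gene}, {"q": cds}, survey, {"chr1": {"chr1"}}
        )
        assert out["q"].origin == "duplication"

    def test_hit_only_on_homeolog_stays_unresolved(self):
        cds = "ATGGCTAGGCATCTTAAAGGCCTTATCGATCGATTTGGCACTGCAAGGACT" * 6
        gene = _gene(cds=cds)
        calls = {"q": SyntenyCall(gene_id="q", klass="non-syntenic")}
        survey = NucleotideIndex({"chr1B": "A" * 400 + cds + "C" * 400})
        out = detect_duplicate_origin(
            calls, {"q": gene}, {"q": cds}, survey, {"chr1": {"chr1", "chr1B"}}
        )
        assert out["q"].origin == "unresolved"

    def test_origin_flags_match_copy_presence_in_truth(self, decoy_bundle):
        """A non-syntenic gene is flagged 'duplication' exactly when the
        truth places another clean copy of its locus on a non-homeologous
        chromosome of the same genome."""
        from gendup.pipeline import RunConfig, run_analysis

        res = run_analysis(
            decoy_bundle, RunConfig(run_kaks=False, run_landscape=False)
        )
        study = decoy_bundle.config.study_chromosome
        wheat_recs = [r for r in decoy_bundle.truth.records if r.species == "wheat"]
        copies_elsewhere = {}
        for r in wheat_recs:
            if r.chromosome != study and not r.pseudogene_type:
                copies_elsewhere.setdefault(r.ancestral_locus, []).append(r)
        truth = decoy_bundle.truth.by_gene("wheat")
        calls = res.per_species["wheat"].calls
        checked = 0
        for gid, c in calls.items():
            if c.klass != "non-syntenic":
                continue
            t = truth.get(gid)
            if t is None or t.true_class != "non-syntenic":
                continue
            checked += 1
            expected = (
                "duplication" if copies_elsewhere.get(t.ancestral_locus) else "unresolved"
            )
            assert c.origin == expected, gid
        assert checked > 0


class TestStratifyAge:
    PROT = "MKVLATTGHHWWYREQPLSD" * 8

    def _calls(self):
        return {"q": SyntenyCall(gene_id="q", klass="non-syntenic")}

    def test_hit_on_one_homeolog_means_old(self):
        calls = stratify_age(
            self._calls(), {"q": self.PROT},
            {"homeologA": {"hA": self.PROT}, "homeologD": {}, "sister": {}},
        )
        assert calls["q"].age_stratum == "old"

    def test_no_hits_anywhere_means_recent(self):
        calls = stratify_age(
            self._calls(), {"q": self.PROT},
            {"homeologA": {"x": "GGGPPPAAA" * 10}, "homeologD": {}, "sister": {}},
        )
        assert calls["q"].age_stratum == "recent"

    def test_simulated_strata_match_truth(self):
        """Events placed before/after the homeolog split are recovered from
        presence/absence in the close-relative gene sets."""
        from gendup.pipeline import RunConfig, run_analysis
        from gendup.simulate import SimulationConfig, simulate_clade

        cfg = SimulationConfig(n_ancestral_genes=250, seed=21, homeolog_mode=True)
        bundle = simulate_clade(cfg)
        res = run_analysis(
            bundle, RunConfig(run_kaks=False, run_origin=False, run_landscape=False)
        )
        focal = bundle.config.focal_species
        calls = res.per_species[focal].calls
        truth = bundle.truth.by_gene(focal)
        checked = agree = 0
        for gid, call in calls.items():
            if call.age_stratum not in ("recent", "old"):
                continue
            rec = truth.get(gid)
            if rec is None or rec.age_stratum == "n/a":
                continue
            checked += 1
            agree += call.age_stratum == rec.age_stratum
        assert checked >= 10
        assert agree / checked >= 0.95


class TestFamilies:
    def _hit(self, q, s):
        return HitRecord(
            query_id=q, subject_id=s, pct_identity=90.0, aln_length=100,
            mismatches=0, gap_opens=0, q_start=1, q_end=100, s_start=1,
            s_end=100, evalue=1e-30, bitscore=200.0,
        )

    def test_mutually_hitting_genes_form_one_family(self):
        hits = [self._hit(a, b) for a in "abc" for b in "abc" if a != b]
        fams = build_families_and_pick_representatives(
            ["a", "b", "c"], hits, seed=0, gene_lengths={g: 100 for g in "abc"}
        )
        assert len(fams) == 1
        assert set(fams[0].members) == {"a", "b", "c"}
        assert fams[0].representative in fams[0].members

    def test_gene_without_hits_is_singleton_and_own_representative(self):
        fams = build_families_and_pick_representatives(["solo"], [], seed=0)
        assert fams[0].members == ["solo"]
        assert fams[0].representative == "solo"

    def test_same_seed_reproduces_representatives(self):
        hits = [self._hit(a, b) for a in "abcd" for b in "abcd" if a != b]
        lens = {g: 100 for g in "abcd"}
        f1 = build_families_and_pick_representatives(list("abcd"), hits, 5, lens)
        f2 = build_families_and_pick_representatives(list("abcd"), hits, 5, lens)
        assert [f.representative for f in f1] == [f.representative for f in f2]
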