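"""Core-set filtration: isoform collapse, TE removal, homology support,
pseudogene detection, and exact agreement of stage counts with the
synthetic generator's ground truth."""
import pytest

from gendup.filtration import (
    FilterThresholds,
    collapse_isoforms,
    detect_pseudogene,
    homology_support_filter,
    remove_te_genes,
    run_filtration,
)
from gendup.models import GeneModel, HitRecord, TranscriptModel
from gendup.pipeline import cross_species_hits, prepare_search


def _gene(gene_id="g", cds_seq=None, transcripts=None, te=False, desc="",
          species="A", start=1, end=None):
    if transcripts is None:
        cds_seq = cds_seq or ("ATG" + "GCT" * 50 + "TAA")
        end = end or len(cds_seq)
        transcripts = [
            TranscriptModel(
                f"{gene_id}.1", [(start, end)], [(start, end)], cds_seq=cds_seq
            )
        ]
        transcripts[0].protein = transcripts[0].translate()
    end = end or max(e for t in transcripts for _, e in t.exons)
    return GeneModel(
        gene_id=gene_id, species=species, chromosome="chr1", start=start,
        end=end, strand="+", transcripts=transcripts, is_te_related=te,
        description=desc,
    )


def _tr(tid, cds_len, span=None):
    span = span or cds_len
    t = TranscriptModel(tid, [(1, span)], [(1, cds_len)], cds_seq="A" * cds_len)
    return t


class TestCollapseIsoforms:
    def test_longest_cds_kept(self):
        g = _gene(transcripts=[_tr("t.1", 900), _tr("t.2", 1200), _tr("t.3", 600)],
                  end=1200)
        (out,) = collapse_isoforms([g])
        assert out.transcripts[0].transcript_id == "t.2"
        assert len(out.transcripts) == 1

    def test_single_transcript_unchanged(self):
        g = _gene()
        (out,) = collapse_isoforms([g])
        assert out.transcripts[0].transcript_id == "g.1"

    def test_cds_tie_broken_by_genomic_span_then_id(self):
        g = _gene(transcripts=[_tr("t.a", 900, span=2000), _tr("t.b", 900, span=2500)],
                  end=2500)
        (out,) = collapse_isoforms([g])
        assert out.transcripts[0].transcript_id == "t.b"
        g2 = _gene(transcripts=[_tr("t.b", 900, span=2000), _tr("t.a", 900, span=2000)],
                   end=2000)
        (out2,) = collapse_isoforms([g2])
        assert out2.transcripts[0].transcript_id == "t.a"


class TestRemoveTE:
    def test_description_substring_match(self):
        kept = remove_te_genes([
            _gene("g1", desc="retrotransposon protein"),
            _gene("g2", desc="kinase"),
            _gene("g3", te=True),
        ])
        assert [g.gene_id for g in kept] == ["g2"]

    def test_decoy_bundle_te_removal_matches_truth(self, decoy_bundle):
        cfg = decoy_bundle.config
        for sp, sb in decoy_bundle.species.items():
            study = [g for g in sb.genes if g.chromosome == cfg.study_chromosome]
            removed = len(study) - len(remove_te_genes(study))
            truth_te = sum(
                r.is_te_decoy
                for r in decoy_bundle.truth.study_records(sp, cfg.study_chromosome)
            )
            assert removed == truth_te


def _hit(q, s, ident=90.0, ev=1e-20, q_start=1, q_end=100):
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=ident, aln_length=100,
        mismatches=0, gap_opens=0, q_start=q_start, q_end=q_end, s_start=1,
        s_end=100, evalue=ev, bitscore=200.0,
    )


class TestHomologySupport:
    SPECIES = {"b1": "B", "a2": "A"}

    def _gene100(self):
        # 100-aa protein
        return _gene("q", cds_seq="ATG" + "GCT" * 99 + "TAA")

    def test_identity_just_below_threshold_removed(self):
        g = self._gene100()
        out = homology_support_filter(
            [g], [_hit("q", "b1", ident=34.9, q_start=1, q_end=80)],
            self.SPECIES, "A",
        )
        assert out == []

    def test_qualifying_hit_kept(self):
        g = self._gene100()
        out = homology_support_filter(
            [g], [_hit("q", "b1", ident=40.0, ev=1e-6, q_start=1, q_end=36)],
            self.SPECIES, "A",
        )
        assert [x.gene_id for x in out] == ["q"]

    def test_same_species_hit_does_not_count(self):
        g = self._gene100()
        out = homology_support_filter(
            [g], [_hit("q", "a2", ident=99.0)], self.SPECIES, "A"
        )
        assert out == []

    def test_gene_absent_from_hit_table_removed(self):
        g = self._gene100()
        assert homology_support_filter([g], [], self.SPECIES, "A") == []


class TestDetectPseudogene:
    def test_internal_stop(self):
        g = _gene("p", cds_seq="ATGTAA" + "GGG" * 10)
        is_p, reason = detect_pseudogene(g, 12)
        assert is_p and reason == "internal_stop"

    def test_truncation_below_seventy_percent(self):
        g = _gene("p", cds_seq="ATG" + "GCT" * 599)  # 600 aa
        is_p, reason = detect_pseudogene(g, 1000)
        assert is_p and reason == "truncation"

    def test_near_complete_not_pseudogene(self):
        g = _gene("p", cds_seq="ATG" + "GCT" * 949)  # 950 aa
        is_p, reason = detect_pseudogene(g, 1000)
        assert not is_p

    def test_frameshift_by_cds_length(self):
        g = _gene("p", cds_seq="ATG" + "GCT" * 50 + "GC")
        is_p, reason = detect_pseudogene(g, None)
        assert is_p and reason == "frameshift"

    def test_missing_cds_is_an_error(self):
        tr = TranscriptModel("t.1", [(1, 30)], [(1, 30)])
        g = _gene("p", transcripts=[tr], end=30)
        with pytest.raises(ValueError, match="cannot assess"):
            detect_pseudogene(g, 100)


class TestRunFiltration:
    def test_stage_counts_match_truth_predictions_exactly(self, decoy_bundle):
        """Each stage count equals the generator's event log prediction:
        TE decoys out first, then (all genes have orthologs) no homology
        losses, then exactly the pseudogenized genes."""
        cfg = decoy_bundle.config
        prep = prepare_search(decoy_bundle)
        for sp in decoy_bundle.species:
            sb = decoy_bundle.species[sp]
            study_genes = [g for g in sb.genes if g.chromosome == cfg.study_chromosome]
            hits = cross_species_hits(decoy_bundle, sp, prep)
            core, report = run_filtration(
                study_genes, hits, prep["species_of"], sp,
                subject_lengths=prep["subject_lengths"],
            )
            recs = decoy_bundle.truth.study_records(sp, cfg.study_chromosome)
            n_raw = len(recs)
            n_te = sum(r.is_te_decoy for r in recs)
            n_pseudo = sum(bool(r.pseudogene_type) for r in recs if not r.is_te_decoy)
            assert report.counts["raw"] == n_raw
            assert report.counts["no_asv_te"] == n_raw - n_te
            assert report.counts["homology_supported"] == n_raw - n_te
            assert report.counts["non_pseudogene"] == n_raw - n_te - n_pseudo
            assert len(core) == report.counts["non_pseudogene"]
            vals = list(report.counts.values())
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_no_decoys_leaves_all_stages_equal(self, clean_bundle):
        cfg = clean_bundle.config
        prep = prepare_search(clean_bundle)
        sp = "rice"
        sb = clean_bundle.species[sp]
        study_genes = [g for g in sb.genes if g.chromosome == cfg.study_chromosome]
        hits = cross_species_hits(clean_bundle, sp, prep)
        core, report = run_filtration(
            study_genes, hits, prep["species_of"], sp,
            subject_lengths=prep["subject_lengths"],
        )
        assert len(set(report.counts.values())) == 1

    def test_empty_gene_set_all_zero(self):
        core, report = run_filtration([], [], {}, "A")
        assert core == []
        assert set(report.counts.values()) == {0}

    def test_idempotent_on_own_output(self, decoy_bundle):
        cfg = decoy_bundle.config
        prep = prepare_search(decoy_bundle)
        sp = "brachypodium"
        sb = decoy_bundle.species[sp]
        study_genes = [g for g in sb.genes if g.chromosome == cfg.study_chromosome]
        hits = cross_species_hits(decoy_bundle, sp, prep)
        core, _ = run_filtration(
            study_genes, hits, prep["species_of"], sp,
            subject_lengths=prep["subject_lengths"],
        )
        core2, report2 = run_filtration(
            core, hits, prep["species_of"], sp,
            subject_lengths=prep["subject_lengths"],
        )
        assert [g.gene_id for g in core2] == [g.gene_id for g in core]
        assert len(set(report2.counts.values())) == 1
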