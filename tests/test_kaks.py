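"""Nei-Gojobori site/difference counting, JC correction, back-translation
and fixation-rate arithmetic, checked against independent oracles built on
Biopython's codon table (not the package's own code tables)."""
import itertools
import math

import pytest
from Bio.Data.CodonTable import standard_dna_table
from hypothesis import given, settings, strategies as st

from gendup import kaks
from gendup.kaks import (
    back_translate,
    count_differences,
    count_sites,
    fixation_rate,
    jukes_cantor,
    kaks_cohort,
    nei_gojobori,
    round_sig,
)

BASES = "TCAG"
ORACLE_CODE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    ORACLE_CODE[_stop] = "*"
SENSE = sorted(c for c, aa in ORACLE_CODE.items() if aa != "*")


def oracle_sites(codon):
    """Enumerate all 9 single-base mutants; stop-codon changes excluded and
    each position renormalized over its remaining changes."""
    s = 0.0
    for pos in range(3):
        syn, valid = 0, 0
        for b in BASES:
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1 :]
            if ORACLE_CODE[m] == "*":
                continue
            valid += 1
            if ORACLE_CODE[m] == ORACLE_CODE[codon]:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def oracle_differences(a, b):
    """Exhaustive pathway enumeration with stop-pathway exclusion."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, steps, through_stop = a, [], False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if ORACLE_CODE[nxt] == "*" and nxt != b:
                through_stop = True
            cur = nxt
        paths.append((through_stop, steps))
    usable = [s for ts, s in paths if not ts] or [s for _, s in paths]
    sd = nd = 0.0
    for steps in usable:
        for frm, nxt in steps:
            if ORACLE_CODE[frm] == ORACLE_CODE[nxt]:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


class TestCountSites:
    def test_phe_TTT(self):
        assert count_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_gly_GGG_fourfold_third_position(self):
        assert count_sites("GGG") == pytest.approx((1.0, 2.0))

    @pytest.mark.parametrize("codon", SENSE)
    def test_matches_enumeration_oracle(self, codon):
        s, n = count_sites(codon)
        so, no = oracle_sites(codon)
        assert s == pytest.approx(so, abs=1e-12)
        assert n == pytest.approx(no, abs=1e-12)
        assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            count_sites("ANG")


class TestCountDifferences:
    def test_identical_codons(self):
        assert count_differences("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous_step(self):
        assert count_differences("TTT", "TTC") == (1.0, 0.0)

    def test_two_difference_pair_averages_both_pathways(self):
        sd, nd = count_differences("TTG", "AGG")
        assert (sd, nd) == oracle_differences("TTG", "AGG")

    @given(
        st.sampled_from(SENSE), st.sampled_from(SENSE)
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_random_pairs_match_pathway_oracle_and_symmetry(self, a, b):
        sd, nd = count_differences(a, b)
        so, no = oracle_differences(a, b)
        assert sd == pytest.approx(so, abs=1e-12)
        assert nd == pytest.approx(no, abs=1e-12)
        assert count_differences(b, a) == (sd, nd)


class TestJukesCantor:
    @given(st.floats(min_value=0.0, max_value=0.7499))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inversion_recovers_proportion(self, p):
        d = jukes_cantor(p)
        back = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        assert back == pytest.approx(p, abs=1e-12)

    def test_saturated_proportion_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor(0.75)


class TestBackTranslate:
    def test_gap_expands_to_triple_gap(self):
        out = back_translate(("M-K", "MAK"), "ATGAAA", "ATGGCGAAG")
        assert out == ("ATG---AAA", "ATGGCGAAG")

    def test_identical_sequences_no_gaps(self):
        out = back_translate(("MK", "MK"), "ATGAAA", "ATGAAG")
        assert out == ("ATGAAA", "ATGAAG")

    def test_mismatched_residue_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            back_translate(("MK", "MK"), "ATGTGG", "ATGAAA")

    def test_removing_gaps_recovers_inputs(self):
        a, b = back_translate(("MA-G", "MAAG"), "ATGGCTGGA", "ATGGCTGCAGGA")
        assert a.replace("-", "") == "ATGGCTGGA"
        assert b.replace("-", "") == "ATGGCTGCAGGA"


class TestNeiGojobori:
    def test_identical_cds_gives_zero_rates_and_no_ratio(self):
        aln = ("ATGGCTAAA", "ATGGCTAAA")
        res = nei_gojobori(aln)
        assert res.Ka == 0.0 and res.Ks == 0.0
        assert res.ratio is None
        assert "ks_zero" in res.flags

    def test_sites_sum_to_three_per_codon(self):
        aln = ("ATGGCTAAAGGG", "ATGGCAAAAGGA")
        res = nei_gojobori(aln)
        assert res.S + res.N == pytest.approx(3 * res.n_codons, abs=1e-9)

    def test_symmetry(self):
        a = "ATGGCTAAAGGGTTTCCC"
        b = "ATGGCAAAGGGATTCCCA"
        r1 = nei_gojobori((a, b))
        r2 = nei_gojobori((b, a))
        assert (r1.S, r1.N, r1.Sd, r1.Nd) == (r2.S, r2.N, r2.Sd, r2.Nd)

    def test_single_saturated_column_flagged(self):
        # TTT vs TTC: Sd=1 on S=1/3 sites -> ps=3 >= 0.75, not correctable
        res = nei_gojobori(("TTT", "TTC"))
        assert res.Ks is None
        assert "ps_saturated" in res.flags

    def test_gap_and_stop_columns_skipped(self):
        res = nei_gojobori(("ATG---TAAGGG", "ATGGCTTAAGGG"))
        assert res.n_codons == 2  # ATG and GGG only

    def test_cohort_requires_defined_ratios(self):
        with pytest.raises(ValueError):
            kaks_cohort({"syntenic": [("ATGGCT", "ATGGCT")],
                         "non-syntenic": [("ATGGCT", "ATGGCT")]})

    def test_cohort_detects_relaxed_selection_with_power(self):
        """Classes simulated at omega 0.2 vs 0.35 are separated by the rank
        test at alpha = 0.01 in >= 90 % of seeds."""
        import numpy as np

        from gendup.simulate import simulate_divergent_pair

        significant = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            pairs = {
                "syntenic": [
                    simulate_divergent_pair(200, 0.2, 0.45, rng) for _ in range(60)
                ],
                "non-syntenic": [
                    simulate_divergent_pair(200, 0.35, 0.45, rng) for _ in range(25)
                ],
            }
            out = kaks_cohort(pairs)
            significant += out["mannwhitney"]["p"] < 0.01
            assert (
                out["summary"]["non-syntenic"]["median"]
                > out["summary"]["syntenic"]["median"]
            ) or out["mannwhitney"]["p"] >= 0.01
        assert significant >= 0.9 * n_seeds


class TestFixationRate:
    @pytest.mark.parametrize(
        "ns,total,T,expect_rate,expect_pct",
        [
            (1397, 5125, 39, 7.0e-3, 27.3),
            (295, 3804, 39, 2.0e-3, 7.8),
            (325, 3582, 54, 1.7e-3, 9.1),
            (551, 4023, 60, 2.3e-3, 13.7),
        ],
    )
    def test_published_chromosome_rows(self, ns, total, T, expect_rate, expect_pct):
        fr = fixation_rate(ns, total, T)
        assert round_sig(fr.rate, 2) == pytest.approx(expect_rate)
        assert round(fr.pct_nonsyntenic, 1) == expect_pct

    def test_zero_events(self):
        assert fixation_rate(0, 1000, 10).rate == 0.0

    @pytest.mark.parametrize("args", [(1, 100, 0), (1, 0, 10), (-1, 100, 10), (11, 10, 10)])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            fixation_rate(*args)
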