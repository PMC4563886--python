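"""Substitution-rate statistics: Nei–Gojobori Ka/Ks and fixation rates.

The Nei–Gojobori (1986) method is implemented directly on codon
alignments obtained by back-translating protein alignments:

* **Sites.** Each codon position contributes a synonymous-site fraction
  equal to the fraction of its possible single-base changes that are
  synonymous. Changes creating a stop codon are excluded and the
  position renormalized over the remaining changes, so every codon
  contributes exactly ``s + n = 3`` sites.
* **Differences.** For codon pairs differing at 1–3 positions, the
  synonymous/non-synonymous split is averaged with equal weight over all
  minimal substitution pathways; pathways passing through a stop codon
  are excluded (falling back to all pathways when every pathway hits a
  stop).
* **Correction.** The proportions ``ps = Sd/S`` and ``pd = Nd/N`` are
  corrected for multiple hits with the Jukes–Cantor formula
  ``d = -(3/4) ln(1 - 4p/3)``; proportions >= 0.75 are flagged
  uncorrectable. Ka/Ks is reported only when Ks > 0.
"""
from __future__ import annotations

import itertools
import math
from functools import lru_cache
from statistics import median
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .models import FixationRate, KaKsResult

BASES = "TCAG"

#: Standard genetic code, codon -> amino acid ('*' = stop).
GENETIC_CODE = {
    "".join(c): aa
    for c, aa in zip(
        itertools.product(BASES, repeat=3),
        "FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR" "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG",
    )
}
STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}
SENSE_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)


def fixation_rate(n_nonsyntenic: int, n_total: int, T: float) -> FixationRate:
    """Non-syntenic gene fixation rate in events per locus per MY.

    ``rate = n_nonsyntenic / n_total / T`` where ``T`` is the divergence
    time (MY) from the last common ancestor with the compared species.
    """
    if T <= 0:
        raise ValueError(f"divergence time must be positive, got {T}")
    if n_total <= 0:
        raise ValueError("total gene count must be positive")
    if not 0 <= n_nonsyntenic <= n_total:
        raise ValueError("non-syntenic count outside [0, total]")
    return FixationRate(
        n_nonsyntenic=n_nonsyntenic,
        n_total=n_total,
        T=T,
        rate=n_nonsyntenic / n_total / T,
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (summary-output convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """Synonymous/non-synonymous site counts of one codon.

    Returns ``(s, n)`` with ``s + n == 3``. Raises on stop codons or
    codons containing ambiguous bases (callers skip and log those).
    """
    codon = codon.upper().replace("U", "T")
    if any(b not in BASES for b in codon) or len(codon) != 3:
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site count")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue  # stop changes excluded from the denominator
            valid += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _pathway_steps(codon_a: str, codon_b: str) -> list[list[tuple[str, str]]]:
    """All minimal substitution pathways a->b as lists of (from, to) codons."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    pathways = []
    for order in itertools.permutations(diff_pos):
        steps = []
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        pathways.append(steps)
    return pathways


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/non-synonymous differences between codons.

    Pathways through stop codons are excluded; if all pathways pass
    through a stop, all are used (equal-weight fallback).
    """
    codon_a = codon_a.upper().replace("U", "T")
    codon_b = codon_b.upper().replace("U", "T")
    if codon_a == codon_b:
        return 0.0, 0.0
    pathways = _pathway_steps(codon_a, codon_b)
    usable = [
        p for p in pathways
        if not any(nxt in STOP_CODONS for _, nxt in p[:-1])
    ]
    if not usable:
        usable = pathways
    sd_total = nd_total = 0.0
    for p in usable:
        for frm, nxt in p:
            if GENETIC_CODE[frm] == GENETIC_CODE[nxt]:
                sd_total += 1
            else:
                nd_total += 1
    k = len(usable)
    return sd_total / k, nd_total / k


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction ``d = -(3/4) ln(1 - 4p/3)``."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 0.75 is not correctable")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def back_translate(
    protein_aln: tuple[str, str], cds_a: str, cds_b: str
) -> tuple[str, str]:
    """Expand a gapped protein alignment to a codon alignment.

    Each aligned amino-acid column becomes its source codon, each gap a
    ``---`` column, so removing gaps recovers the input CDSs exactly.
    A trailing stop codon on either CDS is tolerated and dropped.
    """
    out = []
    for prot, cds in zip(protein_aln, (cds_a, cds_b)):
        ungapped = prot.replace("-", "")
        cds = cds.upper().replace("U", "T")
        if len(cds) >= 3 and cds[-3:] in STOP_CODONS and len(cds) == 3 * (len(ungapped) + 1):
            cds = cds[:-3]
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"CDS length {len(cds)} does not match protein length "
                f"{len(ungapped)}"
            )
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for i, (codon, aa) in enumerate(zip(codons, ungapped)):
            trans = GENETIC_CODE.get(codon)
            if trans is not None and aa not in ("X", "*") and trans != aa:
                raise ValueError(
                    f"residue {aa!r} at protein position {i + 1} does not "
                    f"match codon {codon!r} ({trans!r})"
                )
        aligned = []
        it = iter(codons)
        for aa in prot:
            aligned.append("---" if aa == "-" else next(it))
        out.append("".join(aligned))
    if len(out[0]) != len(out[1]):
        raise ValueError("aligned codon sequences differ in length")
    return out[0], out[1]


def nei_gojobori(aln: tuple[str, str]) -> KaKsResult:
    """Nei–Gojobori Ka/Ks on a codon alignment.

    Codon columns containing gaps, ambiguity, or a stop codon in either
    sequence are skipped. Site counts are averaged over the two
    sequences. Uncorrectable proportions (p >= 0.75) leave the
    corresponding rate ``None`` and add a flag.
    """
    a, b = aln
    if len(a) != len(b) or len(a) % 3 != 0:
        raise ValueError("codon alignment length mismatch or not codon-sized")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    flags: list[str] = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if any(x not in BASES for x in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = count_differences(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codon columns in alignment")
    ps = Sd / S if S > 0 else 0.0
    pd = Nd / N if N > 0 else 0.0
    Ks = Ka = None
    if ps >= 0.75:
        flags.append("ps_saturated")
    else:
        Ks = jukes_cantor(ps)
    if pd >= 0.75:
        flags.append("pd_saturated")
    else:
        Ka = jukes_cantor(pd)
    ratio = None
    if Ks is not None and Ka is not None:
        if Ks > 0:
            ratio = Ka / Ks
        else:
            flags.append("ks_zero")
    return KaKsResult(
        n_codons=n_codons, S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pd=pd,
        Ks=Ks, Ka=Ka, ratio=ratio, flags=flags,
    )


def kaks_pair(cds_a: str, cds_b: str, aligner=None) -> KaKsResult:
    """Align two CDSs at the protein level, back-translate, and run NG.

    Convenience wrapper used by the cohort analysis; the protein
    alignment is a global Needleman–Wunsch under BLOSUM62.
    """
    from .homology import protein_global_alignment

    cds_a = cds_a.upper()
    cds_b = cds_b.upper()

    def _trim(cds: str) -> str:
        n = len(cds) - len(cds) % 3
        cds = cds[:n]
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        return cds

    cds_a, cds_b = _trim(cds_a), _trim(cds_b)
    prot_a = translate_cds(cds_a)
    prot_b = translate_cds(cds_b)
    pa, pb = protein_global_alignment(prot_a, prot_b)
    codon_aln = back_translate((pa, pb), cds_a, cds_b)
    return nei_gojobori(codon_aln)


def translate_cds(cds: str) -> str:
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    return "".join(GENETIC_CODE.get(c, "X") for c in codons)


def kaks_cohort(
    pairs_by_class: dict[str, Sequence[tuple[str, str]]],
) -> dict:
    """Per-class Ka/Ks distributions and a rank test between two classes.

    ``pairs_by_class`` maps class label ("syntenic"/"non-syntenic") to
    CDS pairs (gene vs its closest outgroup homolog). Pairs with Ks = 0,
    an internal stop, or saturated proportions are excluded from the
    ratio distributions, following the convention of reporting ratios
    only where Ks > 0.
    """
    ratios: dict[str, list[float]] = {}
    results: dict[str, list[KaKsResult]] = {}
    for klass, pairs in pairs_by_class.items():
        ratios[klass] = []
        results[klass] = []
        for cds_a, cds_b in pairs:
            try:
                res = kaks_pair(cds_a, cds_b)
            except ValueError:
                continue
            results[klass].append(res)
            if res.ratio is not None:
                ratios[klass].append(res.ratio)
    for klass, r in ratios.items():
        if not r:
            raise ValueError(
                f"class {klass!r} has no pairs with defined Ka/Ks"
            )
    summary = {
        klass: {
            "n": len(r),
            "mean": float(np.mean(r)),
            "median": float(median(r)),
        }
        for klass, r in ratios.items()
    }
    out = {"summary": summary, "ratios": ratios, "results": results}
    if len(ratios) == 2:
        (ka, ra), (kb, rb) = ratios.items()
        stat, p = mannwhitneyu(ra, rb, alternative="two-sided")
        out["mannwhitney"] = {"classes": (ka, kb), "U": float(stat), "p": float(p)}
    return out
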