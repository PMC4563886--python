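# Methods

## Classification model

A gene's synteny status is decided from the locations of its best
protein hits, one per target species, against a chromosome-level synteny
map (orthology blocks with explicit intervals; e.g. only the distal
segments of a *Brachypodium*-like chromosome may be orthologous to the
focal chromosome). Best hits — not reciprocal best hits — are used
deliberately: in highly duplicated genomes reciprocal filtering discards
many true orthologs. The decision rule is asymmetric by design:

* *syntenic* — at least one best hit inside an orthology block of the
  gene's own chromosome;
* *non-syntenic* — every best hit on a non-orthologous chromosome **and**
  a nucleotide search of the gene's CDS against the orthologous
  pseudomolecules (both strands) finds no hit at ≥80 % identity and
  ≥50 % query overlap. The rescue step exists because an ortholog can be
  present in sequence but absent from an annotation; without it the
  non-syntenic count is inflated.

Known property: when the same ancestral locus moves independently in two
lineages onto corresponding chromosomes, the mover is rescued into the
syntenic class (its sequence genuinely is on the counterpart
chromosome). On simulated clades this depresses the recovered
non-syntenic fraction by roughly 1–3 percentage points below truth —
within two binomial standard errors at the problem sizes used, but a
real bias of the published rule, not of this implementation.

## Filtration

Four sequential filters (each count conditioned on the previous stage):
longest-CDS isoform collapse (ties: longer genomic span, then
lexicographic transcript id); TE removal by annotation flag or a
case-insensitive "transposon" substring in the description; homology
support (≥1 hit in ≥1 *other* species at e ≤ 1e-5, ≥35 % identity,
≥35 % overlap); pseudogene removal (internal stop codon; CDS length not
a multiple of 3 as the frameshift proxy; protein shorter than 70 % of
the best qualifying homolog). The ≥35 % thresholds follow the method
text; a stricter ">" variant appears in one caption and is not used.
The overlap denominator is the query protein length ("symmetric minimum"
is available by configuration); the homolog for the 70 % rule is the
best hit surviving the homology filter, since "best complete homolog" is
not otherwise identifiable without curation.

## Homology search

The built-in protein search is a word-seeded Smith–Waterman: candidate
subjects ranked by shared 3-mers, the top candidates aligned locally
under BLOSUM62 with affine gaps (open 11, extend 1) via Biopython's C
aligner; e-values come from the Karlin–Altschul formula with fixed
gapped BLOSUM62 constants (λ = 0.267, K = 0.041) and are approximate by
construction — the identity/overlap thresholds do the effective
filtering, and precomputed BLAST tabular files can be substituted for
real-data fidelity. In the pipeline the two highest-ranked candidates
per (query, target species) are fully aligned; on simulated data the
true homolog ranks first by shared-word count in essentially all cases.
Ties anywhere (bitscore, e-value, identity) break to the
lexicographically smaller subject id, so outputs are byte-reproducible.
The nucleotide search used for reclassification and duplication-origin
detection is exact-13-mer seeding with local alignment (match 2,
mismatch −3, gap open 5 / extend 2) of the seed region on both strands.

## Fixation rate and age strata

Rate = non-syntenic count / core count / divergence time (MY since the
last common ancestor with the nearest compared species: 39 / 39 / 54 /
60 for the four taxa). Summaries print two significant figures.
Non-syntenic genes are stratified as *recent* (no qualifying hit — same
thresholds as the homology filter — in any of the two homeologous gene
sets and the sister-species set, splits at 6.5 and 11.6 MY) or *old*
(any such hit). Duplicate families among non-syntenic genes are
single-linkage components over same-chromosome hits passing the filter
thresholds; one representative per family is drawn uniformly under the
pipeline seed before plotting landscapes, to avoid tandem-family bias.

## Ka/Ks (Nei–Gojobori)

Implemented from the published algorithm rather than wrapping an
external binary. Per codon position, the synonymous-site fraction is the
fraction of single-base changes that are synonymous, with changes to
stop codons removed from the denominator and the position renormalized
over the remaining changes — this keeps s + n = 3 exactly for every
codon. Differences between codon pairs average over all minimal
substitution pathways with equal weight; pathways through stop codons
are excluded, falling back to all pathways when none survive. Codon
columns containing gaps, ambiguity or stops are skipped; site counts are
averaged over the two sequences. Proportions are Jukes–Cantor corrected
(d = −¾ ln(1 − 4p/3)); p ≥ 0.75 is flagged uncorrectable, and Ka/Ks is
reported only when Ks > 0 (Ks = 0 pairs are excluded from cohort
summaries, mirroring the published exclusion). Protein alignments for
back-translation are global BLOSUM62 alignments with free end gaps; the
back-translation maps each residue column to its source codon, so
removing gaps recovers the input CDSs exactly.

## Enrichment and feature comparisons

Per-term one-sided hypergeometric tail probabilities (exact, via scipy)
with Benjamini–Hochberg adjustment across tested terms. This is classic
per-term Fisher testing; the graph-aware "elim" decorrelation of
topGO-style tools is intentionally not applied, so published
topGO-derived p-values are not reproduction targets. Feature comparisons
use two-sided Mann–Whitney for numeric features and a 2×2 chi-squared
without continuity correction (a flag enables it) for binary ones;
zero-variance features and classes with fewer than two observations are
skipped and logged.

## Synthetic clade generator

The generator emulates the comparative design, not grass genomes per se:

* **Topology.** Fixed four-taxon tree (((focal, relative1):15,
  relative2):6, outgroup) with tip times 39/39/54/60 MY; optional
  homeolog mode adds two homeolog sets (6.5 MY) and a sister set
  (11.6 MY) as protein collections restricted to the study-chromosome
  group, which is what the age stratification actually consumes.
* **Genes.** 1000 ancestral loci by default, uniform 100–300 codons,
  placed collinearly on three chromosomes per species (the study
  chromosome plus two donors); single-exon by default with a
  configurable multi-exon fraction (two exons, 60 bp intron) to
  exercise spliced extraction; intergenic spacers are 150 bp of uniform
  random sequence (TE decoys are annotation-level, no TE sequence
  model).
* **Sequence divergence.** Codon-level proposal/acceptance: mutations
  proposed uniformly over positions and alternative bases, synonymous
  changes always accepted, non-synonymous with probability ω, stops
  rejected. The proposal intensity is calibrated so Ks accumulates at
  `syn_subs_per_my` (default 0.006/site/MY, giving Ks ≈ 0.45 and ≈85 %
  nucleotide identity between the two closest tips — high enough for
  unambiguous homology, low enough to keep the 80 % rescue threshold
  meaningful). Defaults ω = 0.2 background and ω = 0.35 on the
  post-duplication segment of moved copies, so cohort Ka/Ks contrasts
  are a time-weighted mixture, as in real duplicate cohorts.
* **Events.** Duplications (ancestral copy retained) and translocations
  (ancestral removed) are drawn per locus on *terminal branches only*,
  with per-lineage rates; each event copies the locus to a uniformly
  random other chromosome at a uniform event time. Restricting events to
  terminal branches keeps the truth class identical to "resides on a
  non-ancestral chromosome": an internal-branch event would be shared by
  two species and the "at least one best hit" rule would correctly call
  it syntenic, making ground truth ill-defined. Default rates are
  calibrated so the study chromosome converges to the observed
  non-syntenic fractions (~27 % focal, ~8–14 % relatives) given that
  arrivals on the study chromosome are one third of all events.
* **Decoys.** TE decoy genes (half flagged by annotation class, half by
  a "retrotransposon protein" description), extra shorter splice
  isoforms, and pseudogene lesions chosen uniformly among internal stop,
  1-bp frameshift and truncation below 70 % — lesions are placed in the
  50–90 % span of the CDS so the damaged gene still passes the homology
  filter and is caught by the pseudogene filter, which is what makes
  stage counts exactly predictable from the event log.
* **Annotation dropout.** A fraction of study loci lose their gene
  models in all non-focal species while the sequence stays in the
  chromosome; dropout is preferentially assigned to loci that carry an
  ancient (pre-root) paralog on a donor chromosome, because only those
  genes survive the homology filter (via the paralog) and exercise the
  reclassification rescue the way unannotated real orthologs do.
* **Expression and annotation tables.** Class-conditional expression
  (expressed probability 0.83/0.74, mean breadth 12/9.2 of 15
  conditions, mean level 261/142 — the observed contrast) and a flat
  gene→term annotation with one term over-assigned to non-syntenic
  genes stand in for the out-of-scope RNA-seq and GO-assignment stages.

What passing tests on this generator do **not** show: robustness to
fragmented assemblies, tandem arrays, TE sequence homology,
indel-rich alignments, or annotation error modes beyond the ones
modeled; real-genome counts (the published per-chromosome tables) are
reproduced only at the level of their arithmetic, never re-derived from
sequence.

## Problem sizes and determinism

Validation runs use 1000-locus clades (≈450 study genes in the focal
species) for parameter recovery over 20 seeds, 100 seeds for landscape
sign checks, and 50 pairs × 500 codons for dN/dS recovery — sizes at
which binomial error bands are tight enough to be informative while a
full run stays in the minutes range on one core. A single integer seed
fixes the generator, representative draws and every stochastic choice;
identical seeds give byte-identical bundles and tables.

## Known limitations

* E-values from the built-in search are calibrated, not BLAST-identical;
  analyses that depend on absolute e-values near the 1e-5 cutoff should
  supply precomputed hit tables.
* Collinearity (gene order within blocks) is out of scope; the map
  works at the chromosome/interval level only.
* The convergent-movement rescue bias described above is inherent to
  the classification rule.
* The Ks = 0 exclusion makes cohort ratio summaries conditional on
  observable synonymous divergence; at very low divergence this censors
  slow genes first.
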