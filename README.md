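# gendup

Synteny-based detection of lineage-specific interchromosomal gene
duplications in grass genomes.

## The problem

Grass chromosomes are largely syntenic: most genes sit on the same
orthologous chromosome in wheat, *Brachypodium*, rice and sorghum. Genes
that violate this — whose closest homologs in every other species lie on
*non*-orthologous chromosomes — are the footprint of lineage-specific
interchromosomal duplications and translocations. Counting them on a
comparable "core" gene set, and normalizing by divergence time, turns
synteny violations into a **fixation rate** (events · locus⁻¹ · MY⁻¹)
that can be compared across lineages. On wheat chromosome 3B this rate
is about 3.5× the model-grass level (7.0×10⁻³ vs ≈2×10⁻³), the signature
of accelerated small-scale duplication in the *Triticeae*.

`gendup` re-implements that analysis as a reusable, tested pipeline:

1. **Filtration** to a core gene set: collapse splice variants to the
   longest-CDS representative, remove transposon-related genes, require a
   cross-species protein hit (e ≤ 1e-5, ≥35 % identity, ≥35 % overlap),
   and remove pseudogenes (internal stop, frameshift, or <70 % of the
   best homolog's length).
2. **Classification**: a gene with at least one best protein hit on a
   syntenic counterpart chromosome is *syntenic*; with all best hits on
   non-orthologous chromosomes it is *non-syntenic*, after a nucleotide
   rescue search of its CDS against the orthologous pseudomolecules
   (≥80 % identity, ≥50 % overlap) to catch unannotated orthologs.
3. **Rates and landscapes**: per-species fixation rates
   `n_nonsyntenic / n_total / T`; sliding-window proportions along the
   chromosome and their Pearson correlation with centromere distance;
   age stratification of movers (recent vs old relative to the ~6.5 MY
   homeolog split) using close-relative gene sets.
4. **Selection and function**: Nei–Gojobori Ka/Ks on back-translated
   protein alignments (Jukes–Cantor corrected, Ks = 0 pairs excluded),
   class-wise Mann–Whitney / chi-squared feature comparisons, and
   hypergeometric term enrichment with BH-FDR.

Real per-genome inputs (GFF3 + FASTA + BLAST tabular hits) are accepted
throughout; because desk-scale reproduction of the original genomes is
impossible, the package also ships a **synthetic clade generator**
(`gendup.simulate`) that emulates the four-taxon grass phylogeny with
configurable duplication/translocation rates, codon-level divergence at
a chosen dN/dS, pseudogene lesions and annotation decoys — with complete
ground truth, so every stage is validated end to end.

## Worked example

Run the numbered drivers in `analysis/` (each writes TSVs under
`results/`). The full pipeline on the bundled study clade:

```bash
python analysis/01_simulate_clade.py
python analysis/02_run_pipeline.py
```

prints, per species, the filtration stages and the classification
summary (seed 1, 1000 ancestral loci):

```
     species  n_raw  n_no_asv_te  n_homology_supported  n_core  n_syntenic  n_nonsyntenic  pct_nonsyntenic  divergence_my  fixation_rate
       wheat    451          424                   424     408         313             95             23.3           39.0        0.00600
brachypodium    384          357                   357     340         323             17              5.0           39.0        0.00130
        rice    377          350                   350     335         319             16              4.8           54.0        0.00088
     sorghum    404          377                   377     363         315             48             13.2           60.0        0.00220
```

The focal lineage, simulated with a duplication rate calibrated to the
wheat-3B excess, is recovered with ~23 % non-syntenic genes and a
fixation rate several-fold above the three relatives — the same contrast
the method reports on real data. `analysis/03_fixation_rates.py`
recomputes the published-count arithmetic directly:

```
chromosome  n_core  n_nonsyntenic  pct_nonsyntenic  divergence_my  rate_per_locus_per_my
      Ta3B    5125           1397             27.3           39.0                 0.0070
       Bd2    3804            295              7.8           39.0                 0.0020
       Os1    3582            325              9.1           54.0                 0.0017
       Sb3    4023            551             13.7           60.0                 0.0023

fold contrast (focal vs model-grass mean): 3.5x
core-set gene excess on the focal chromosome: 35 %
```

`04_kaks_selection.py` shows the relaxed selection on movers
(median Ka/Ks 0.244 vs 0.213, Mann–Whitney p ≈ 7×10⁻⁷),
`05_landscape_bias.py` the sign of the centromere-distance correlation
under distal vs pericentromeric retention, and `06_function_stats.py`
the expression/feature contrasts and term enrichment.

A `gendup` CLI wraps the same library for file-level use
(`gendup simulate`, `gendup search`, `gendup filter`, `gendup rates`,
`gendup landscape`, `gendup kaks`, `gendup enrich`, `gendup run-all`).

## Layout

```
src/gendup/       library: io, models, simulate, filtration, homology,
                  classify, kaks, landscape, enrich, pipeline, cli
analysis/         numbered narrative drivers (write results/)
tests/            pytest suite with independent oracles
scripts/          acceptance.py
docs/methods.md   model, parameters, design choices, limitations
```
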