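#!/usr/bin/env python
"""Generate the study clade and summarize its ground truth.

Writes the full bundle (GFF3 + genome FASTA per species, truth table)
under scratch/bundle/ and a per-species truth summary under results/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd
from common import RESULTS, SCRATCH, study_config

from gendup.simulate import simulate_clade, write_bundle

cfg = study_config()
bundle = simulate_clade(cfg)
write_bundle(bundle, SCRATCH / "bundle")

rows = []
for sp in bundle.species:
    recs = bundle.truth.study_records(sp, cfg.study_chromosome)
    clean = [r for r in recs if r.true_class != "decoy" and not r.pseudogene_type
             and r.annotated]
    ns = sum(r.true_class == "non-syntenic" for r in clean)
    rows.append(
        {
            "species": sp,
            "study_genes_annotated": sum(r.annotated for r in recs),
            "te_decoys": sum(r.is_te_decoy for r in recs),
            "pseudogenized": sum(bool(r.pseudogene_type) for r in recs),
            "clean_core_truth": len(clean),
            "truth_nonsyntenic": ns,
            "truth_pct_nonsyntenic": round(100 * ns / len(clean), 1),
        }
    )
df = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "01_truth_summary.tsv", sep="\t", index=False)
print(f"bundle written to {SCRATCH / 'bundle'}")
print(df.to_string(index=False))
print(
    "\nThe focal lineage carries the configured excess of interchromosomal "
    "duplicates; the three relatives sit near the model-grass level."
)
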