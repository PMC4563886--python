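#!/usr/bin/env python
"""Feature comparisons and term enrichment between gene classes.

Uses the simulated expression table (class-wise breadth/level following
the observed syntenic vs non-syntenic contrast) plus structural features,
and a simulated annotation with one term over-assigned to non-syntenic
genes, to exercise the Mann-Whitney / chi-squared comparisons and the
hypergeometric enrichment with BH-FDR.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd
from common import RESULTS, study_config

from gendup.pipeline import RunConfig, run_analysis
from gendup.simulate import simulate_clade

bundle = simulate_clade(study_config())
rcfg = RunConfig(
    run_origin=False, run_landscape=False, run_age=False, run_kaks=False,
    run_expression=True, run_enrichment=True,
)
result = run_analysis(bundle, rcfg)

RESULTS.mkdir(exist_ok=True)
fc = result.feature_comparison
fc.to_csv(RESULTS / "06_feature_comparison.tsv", sep="\t", index=False)
print("Class-wise feature comparison (means, medians, tests):")
print(fc.to_string(index=False))

rows = []
for klass, er in result.enrichment.items():
    for r in er[:5]:
        rows.append({"study_class": klass, **r.__dict__})
enr = pd.DataFrame(rows)
enr.to_csv(RESULTS / "06_enrichment_top.tsv", sep="\t", index=False)
print("\nTop enriched terms per class:")
print(enr.to_string(index=False))
print(
    "\nThe planted term surfaces for the non-syntenic class at low adjusted "
    "p; background terms stay near p = 1."
)
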