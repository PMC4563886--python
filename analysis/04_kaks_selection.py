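#!/usr/bin/env python
"""Selection pressure on syntenic vs non-syntenic genes.

Pairs every focal core gene with its closest homolog in the nearest
relative, back-translates the protein alignments, and runs Nei-Gojobori
Ka/Ks. Non-syntenic genes are simulated under relaxed selection, so
their ratio distribution should sit significantly higher.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd
from common import RESULTS, study_config

from gendup.pipeline import RunConfig, run_analysis
from gendup.simulate import simulate_clade

bundle = simulate_clade(study_config())
rcfg = RunConfig(run_origin=False, run_landscape=False, run_age=False,
                 run_kaks=True)
result = run_analysis(bundle, rcfg)

kk = result.kaks
rows = [
    {"class": klass, **stats} for klass, stats in kk["summary"].items()
]
df = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "04_kaks_summary.tsv", sep="\t", index=False)
print(df.to_string(index=False))
mw = kk["mannwhitney"]
print(
    f"\nMann-Whitney ({mw['classes'][0]} vs {mw['classes'][1]}): "
    f"U={mw['U']:.0f}, p={mw['p']:.2e}"
)
print(
    "\nConfigured omegas: 0.2 (background) vs 0.35 on the post-duplication "
    "segment of each moved gene; the pairwise ratio is therefore a "
    "time-weighted mixture, and the elevated non-syntenic median plus the "
    "rank test recover the relaxation."
)
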