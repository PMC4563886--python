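#!/usr/bin/env python
"""Chromosomal landscapes under biased retention of moved genes.

Simulates distally-biased and pericentromerically-biased retention of
non-syntenic genes and measures the Pearson correlation between window
proportion and centromere distance, mirroring the opposite signs seen
for the focal wheat chromosome vs rice/sorghum.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd
from common import RESULTS

from gendup.landscape import centromere_distance_correlation, sliding_proportion
from gendup.simulate import simulate_landscape_genes

L = 10_000_000
N_SEEDS = 100
rows = []
for bias, label in ((1.2, "distal_retention"), (-1.2, "pericentromeric_retention")):
    rs = []
    for seed in range(N_SEEDS):
        rng = np.random.default_rng(seed)
        pos, cls = simulate_landscape_genes(1000, L, 0.3, bias, rng)
        prof = sliding_proportion(pos, cls, L // 10, L // 100, L, centromere=L // 2)
        rs.append(centromere_distance_correlation(prof))
    rs = np.array(rs)
    rows.append(
        {
            "condition": label,
            "bias": bias,
            "mean_r": round(float(rs.mean()), 3),
            "frac_positive": float((rs > 0).mean()),
            "frac_negative": float((rs < 0).mean()),
        }
    )
df = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "05_landscape_sign.tsv", sep="\t", index=False)
print(df.to_string(index=False))
print(
    "\nDistal retention bias drives r > 0 (moved genes accumulate at the "
    "chromosome ends); pericentromeric bias flips the sign, matching the "
    "wheat-vs-rice/sorghum contrast in distribution shape."
)
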