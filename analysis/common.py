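"""Shared study conditions for the analysis drivers.

One seed-fixed synthetic clade stands in for the four-genome comparison:
1000 ancestral loci on three chromosomes per species, per-lineage
duplication/translocation rates calibrated to the observed non-syntenic
fractions, TE/splice-variant decoys and pseudogene lesions switched on,
and homeolog mode enabled for the recent/old stratification.
"""
from pathlib import Path

from gendup.simulate import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

STUDY_SEED = 1


def study_config(seed: int = STUDY_SEED) -> SimulationConfig:
    return SimulationConfig(
        n_ancestral_genes=1000,
        seed=seed,
        te_decoy_fraction=0.08,
        asv_decoy_fraction=0.15,
        pseudogenization_prob=0.04,
        multi_exon_fraction=0.35,
        homeolog_mode=True,
    )
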