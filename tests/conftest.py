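import pytest

from gendup.simulate import SimulationConfig, simulate_clade


@pytest.fixture(scope="session")
def decoy_bundle():
    """Small clade with every decoy type switched on (shared, read-only)."""
    cfg = SimulationConfig(
        n_ancestral_genes=150,
        seed=42,
        te_decoy_fraction=0.10,
        asv_decoy_fraction=0.20,
        pseudogenization_prob=0.06,
    )
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def clean_bundle():
    """Small clade with no decoys and no duplication events."""
    cfg = SimulationConfig(
        n_ancestral_genes=90,
        seed=7,
        duplication_rate=0.0,
        translocation_rate=0.0,
    )
    return simulate_clade(cfg)


TOY_GFF = """##gff-version 3
chr1\ttest\tgene\t101\t400\t.\t-\t.\tID=g1;Note=demo gene
chr1\ttest\tmRNA\t101\t400\t.\t-\t.\tID=g1.1;Parent=g1
chr1\ttest\texon\t301\t400\t.\t-\t.\tParent=g1.1
chr1\ttest\texon\t101\t220\t.\t-\t.\tParent=g1.1
chr1\ttest\tCDS\t301\t400\t.\t-\t0\tParent=g1.1
chr1\ttest\tCDS\t101\t220\t.\t-\t0\tParent=g1.1
"""


@pytest.fixture
def toy_gff_path(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF)
    return p
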