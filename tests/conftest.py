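import pytest

import cfsieve as cf


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale library: 8 kb two-target panel, 2x125 bp reads."""
    return cf.SimConfig(seed=42, panel_size_bp=8000, n_targets=2,
                        flank_bp=1000, target_gap_bp=1000,
                        n_unique_molecules=800, total_reads=6000,
                        tumor_fraction=0.05)


@pytest.fixture(scope="session")
def reference(small_config):
    return cf.make_reference(small_config)


@pytest.fixture(scope="session")
def assay(reference):
    return cf.VariantAssay.from_reference(reference)


@pytest.fixture(scope="session")
def noise_free_library(small_config, reference):
    """Fragments, reads and consensus of a zero-error amplified library."""
    cfg = small_config
    frags = cf.simulate_fragments(cfg, reference, 800)
    reads = cf.amplify_and_sequence(frags, cfg)
    families, excluded = cf.group_families(reads)
    consensuses = cf.consensus_reads(families)
    return {"config": cfg, "fragments": frags, "reads": reads,
            "families": families, "excluded": excluded,
            "consensuses": consensuses}
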