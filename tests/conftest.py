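import pytest

import mapanchor as ma


@pytest.fixture(scope="session")
def small_world():
    """A small genome, its scaffolds, two noise-free maps and bulk depths."""
    truth, scaffolds = ma.simulate_genome(
        n_chrom=3, chrom_len=500_000, n_scaffolds=12, seed=11,
        markers_per_chrom=40, cm_per_mb=25.0,
    )
    maps = [
        ma.true_map(truth, "MH", 2.0),
        ma.true_map(truth, "YM", 2.0, marker_fraction=0.8, seed=12),
    ]
    return truth, scaffolds, maps


@pytest.fixture(scope="session")
def small_plan(small_world):
    truth, scaffolds, maps = small_world
    return ma.build_anchor_plan(scaffolds, maps)


@pytest.fixture(scope="session")
def small_bundle(small_world, small_plan):
    _truth, scaffolds, maps = small_world
    return ma.build_pseudochromosomes(small_plan, scaffolds, maps=maps)
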