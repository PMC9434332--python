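import pytest

from ciscross.simulate import FixtureSpec, PlantedSignal, build_fixture

# Desk-scale dataset for unit tests: 100 genes on two small chromosomes,
# ten peak tracks, one strongly planted regulator.
SMALL_SPEC_KW = dict(
    chrom_lengths=(200_000, 150_000),
    n_genes=100,
    gene_length=(300, 800),
    promoter_length=500,
    n_peak_sets=10,
    peaks_per_set=40,
    peak_length=(50, 200),
    n_foreground=10,
)


def small_spec(seed=7, planted=(PlantedSignal("TF000_col", 0.9, 0.05),), **overrides):
    kw = {**SMALL_SPEC_KW, **overrides}
    return FixtureSpec(seed=seed, planted=planted, **kw)


@pytest.fixture(scope="session")
def small_fixture():
    return build_fixture(small_spec())


@pytest.fixture(scope="session")
def null_fixture():
    """Same dimensions, no planted signal."""
    return build_fixture(small_spec(seed=11, planted=()))
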