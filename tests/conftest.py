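import pytest

from cgap.simulate import FamilyDesign, simulate_family

SMALL_TAXA = (
    "Homo sapiens",
    "Pan troglodytes",
    "Macaca mulatta",
    "Mus musculus",
    "Bos taurus",
)


@pytest.fixture(scope="session")
def small_design():
    return FamilyDesign(
        n_superclusters=2,
        clusters_per_supercluster=2,
        taxa=SMALL_TAXA,
        hole_probability=0.0,
    )


@pytest.fixture(scope="session")
def small_family(small_design):
    """2 superclusters x 2 clusters x 5 taxa = 20 records, no coverage holes."""
    return simulate_family(small_design, seed=11)


@pytest.fixture(scope="session")
def small_alignment(small_family):
    from cgap.msa import align_records

    records, _, _, _ = small_family
    return align_records(records)
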