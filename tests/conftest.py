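import numpy as np
import pytest

from provmark import GroupLabels, Lineage, OtuTable, SyntheticSpec, simulate


def make_lineage(species="Sp", genus="Gen", phylum="Phy"):
    return Lineage(("Bacteria", phylum, "Cls", "Ord", "Fam", genus, species))


@pytest.fixture
def toy_table():
    """3 OTUs x 4 samples with complete lineages and known counts."""
    lineages = [
        make_lineage(species=f"S{i}", genus=f"G{i}", phylum="P1") for i in range(3)
    ]
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 3, 0],
            [10, 10, 10, 10],
        ]
    )
    return OtuTable(
        otu_ids=["OTU_1", "OTU_2", "OTU_3"],
        lineages=lineages,
        counts=counts,
        sample_ids=["A", "B", "C", "D"],
    )


@pytest.fixture
def two_group_labels():
    return GroupLabels({"A": "north", "B": "north", "C": "south", "D": "south"})


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-marker cohort reused by slower statistical tests."""
    spec = SyntheticSpec(n_background_otus=250, seed=11)
    return simulate(spec)


def random_count_table(rng, n_otus=12, n_samples=6, max_count=50):
    counts = rng.integers(0, max_count, size=(n_otus, n_samples))
    lineages = [make_lineage(species=f"S{i}", genus=f"G{i}") for i in range(n_otus)]
    return OtuTable(
        otu_ids=[f"O{i}" for i in range(n_otus)],
        lineages=lineages,
        counts=counts,
        sample_ids=[f"s{j}" for j in range(n_samples)],
    )
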