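import numpy as np
import pytest

from germdiv import BandMatrix, GenotypeMatrix, TraitMatrix, default_config


@pytest.fixture
def small_bands() -> BandMatrix:
    """Four accessions x two primers covering all four band patterns."""
    bands = np.array(
        [
            [1, 0, 0, 0],
            [0, 1, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 1, 1],
        ]
    )
    return BandMatrix(["a1", "a2", "a3", "a4"], ["BLF-41", "BLF-79"], bands)


@pytest.fixture
def small_traits() -> TraitMatrix:
    values = np.array(
        [
            [129.57, 1.0],
            [140.00, 0.0],
            [100.25, 1.0],
        ]
    )
    return TraitMatrix(
        ["Hongmi", "Baimizi", "Heimizi"],
        ["SH", "IC"],
        ["quantitative", "qualitative"],
        values,
        ["cm", ""],
    )


@pytest.fixture(scope="session")
def panel_genotypes() -> GenotypeMatrix:
    """The default synthetic 147 x 15 genotype panel (fixed seed)."""
    import germdiv

    gm, _, _ = germdiv.gen_structured_genotypes(default_config(seed=7))
    return gm


@pytest.fixture(scope="session")
def collection_traits() -> TraitMatrix:
    """The default synthetic 1,582 x 22 trait collection (fixed seed)."""
    import germdiv

    return germdiv.gen_phenotypes(default_config(seed=1))
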