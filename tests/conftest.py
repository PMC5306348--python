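import numpy as np
import pytest
from hypothesis import settings

from strsim import KitDef, LocusDef, Genotype, make_fixture_kit

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def kit4() -> KitDef:
    """Small 4-locus synthetic panel used by most simulation tests."""
    return make_fixture_kit(4, (70, 450))


@pytest.fixture(scope="session")
def kit1() -> KitDef:
    """Single-locus panel for tests that need exactly one heterozygous locus."""
    return KitDef(
        name="one",
        loci=(
            LocusDef(
                name="L01",
                dye="blue",
                repeat_bp=4,
                alleles={str(8 + j): 100 + 4 * j for j in range(10)},
            ),
        ),
    )


@pytest.fixture
def het_genotype(kit1) -> Genotype:
    """Diploid heterozygote (alleles two repeats apart) on the 1-locus kit."""
    return Genotype(alleles={"L01": ("8", "10")}, ploidy="diploid")


@pytest.fixture
def het_haploid(kit1) -> Genotype:
    return Genotype(alleles={"L01": ("8", "10")}, ploidy="haploid")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
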