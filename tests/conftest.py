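import numpy as np
import pytest

from flymosaic import gwas, synthetic
from flymosaic.kmers import BindingSiteSet


@pytest.fixture
def sites():
    return BindingSiteSet()


@pytest.fixture
def small_retina_config():
    # ~56 spots: fast enough for per-test use
    return synthetic.SimulationConfig(seed=11, n_rows=7, n_cols=8,
                                      on_fraction=0.6)


@pytest.fixture
def deficiency():
    return gwas.DeficiencyInterval("3R", 16_200_000, 16_400_000)


@pytest.fixture
def toy_genotypes():
    """Four lines x four variants covering every code inside and outside
    the deficiency interval."""
    variants = [
        gwas.Variant("3R", 16_100_000, "A", "G"),   # outside
        gwas.Variant("3R", 16_300_000, "A", "AC"),  # inside
        gwas.Variant("3R", 16_350_000, "T", "C"),   # inside
        gwas.Variant("3R", 16_500_000, "G", "T"),   # outside
    ]
    calls = np.array([
        [gwas.HOM_REF, gwas.HOM_ALT, gwas.HET, gwas.MISSING],
        [gwas.HOM_ALT, gwas.HOM_REF, gwas.MISSING, gwas.HET],
        [gwas.HET, gwas.MISSING, gwas.HOM_ALT, gwas.HOM_REF],
        [gwas.MISSING, gwas.HET, gwas.HOM_REF, gwas.HOM_ALT],
    ], dtype=np.int8)
    return gwas.GenotypeMatrix(variants, [f"L{i}" for i in range(4)], calls)
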