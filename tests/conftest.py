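import pytest

from barcodeid import SyntheticConfig, generate
from barcodeid.pipeline import analyze_library

# TOY8: 3 families; family 1 has genera of 3 and 2 species, family 2 two
# monotypic genera, family 3 one monotypic genus -> 8 species total.
TOY8_CONFIG = SyntheticConfig(
    n_families=3,
    genera_per_family=[2, 2, 1],
    species_per_genus=[3, 2, 1, 1, 1],
    seed=1,
    indel_rate=0.0,
    short_fragment_rate=0.0,
)


@pytest.fixture(scope="session")
def toy8():
    lib, manifest = generate(TOY8_CONFIG)
    assert len(lib) == 8
    return lib, manifest


@pytest.fixture(scope="session")
def default_library():
    """One default-condition synthetic library (~150 species, 10 families)."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_library):
    lib, _ = default_library
    return analyze_library(lib)
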