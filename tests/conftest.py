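import pytest
from importlib import resources

from nglyq import build_db, default_glycan_library


@pytest.fixture(scope="session")
def agp_fasta() -> str:
    ref = resources.files("nglyq").joinpath("data", "agp_synthetic.fasta")
    with resources.as_file(ref) as path:
        yield str(path)


@pytest.fixture(scope="session")
def glycan_library():
    return default_glycan_library()


@pytest.fixture(scope="session")
def glyco_db(agp_fasta, glycan_library):
    """Full database over the synthetic AGP-like protein (built once)."""
    return build_db(agp_fasta, glycan_library)
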