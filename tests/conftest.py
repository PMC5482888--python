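import pytest
from hypothesis import settings

from mitocomp import presets

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")
from mitocomp.synthetic import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def reference_record():
    """The published C. sinensis annotation (coordinates only, no sequence)."""
    return presets.reference_record()


@pytest.fixture(scope="session")
def synthetic_record():
    """One deterministic KU589292-like synthetic genome with sequence."""
    return generate_genome(GenomeSpec.ku589292_like(seed=20170623))
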