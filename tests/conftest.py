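import pytest

from pily_profiler import motifs, synthetic


@pytest.fixture(scope="session")
def catalog():
    return motifs.default_catalog()


@pytest.fixture(scope="session")
def small_proteome():
    """Two members per clade: enough for clade structure, cheap to align."""
    return synthetic.generate_proteome(n_per_clade=2, seed=11)


@pytest.fixture(scope="session")
def genome_bundle():
    """One generated genome per layout, with manifests."""
    out = {}
    for i, layout in enumerate(sorted(synthetic.GENOME_LAYOUTS)):
        out[layout] = synthetic.generate_genome([layout], seed=100 + i)
    return out
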