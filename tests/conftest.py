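import pytest

from solstab.designer import DesignConfig
from solstab.fixtures import make_design_fixture
from solstab.pipeline import make_context


@pytest.fixture(scope="session")
def demo():
    """Demo helix + alignment with a full design context (monomer)."""
    structure, msa = make_design_fixture(n_sequences=80, seed=0)
    ctx = make_context(structure, msa, DesignConfig())
    return ctx


@pytest.fixture(scope="session")
def demo_dimer():
    """Identical-chain (A/B) variant of the demo fixture."""
    structure, msa = make_design_fixture(n_sequences=80, seed=0, n_chains=2)
    ctx = make_context(structure, msa, DesignConfig())
    return ctx
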