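import pytest

from gtrec.locus import default_locus, default_locus_spec
from gtrec.simulate import ArtifactParams


@pytest.fixture(scope="session")
def locus():
    """The default two-parent locus emulation (84/36-unit motif 1)."""
    return default_locus()


@pytest.fixture(scope="session")
def locus_spec():
    return default_locus_spec()


@pytest.fixture(scope="session")
def clean_params():
    """Artifact-free simulation parameters."""
    return ArtifactParams.clean()
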