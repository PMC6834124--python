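import random

import pytest

from mirfunc.rna_structure import EnergyModel


@pytest.fixture(scope="session")
def model() -> EnergyModel:
    return EnergyModel.default()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """The demo dataset, generated once per session."""
    from mirfunc.pipeline import make_fixtures

    outdir = tmp_path_factory.mktemp("demo")
    manifest = make_fixtures(outdir, seed=17)
    return manifest
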