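import pathlib

import pandas as pd
import pytest

from colocnet.cli import bundle_config
from colocnet.contacts import CONTACT_COLUMNS, ContactSet
from colocnet.pipeline import run
from colocnet.synthetic import SyntheticScenario, generate


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default synthetic scenario, generated once per session."""
    root = tmp_path_factory.mktemp("bundle")
    return generate(SyntheticScenario(seed=0), root)


@pytest.fixture(scope="session")
def pipeline_result(default_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    config = bundle_config(default_bundle, outdir / "out")
    return run(config)


@pytest.fixture
def make_contacts():
    """Factory for small in-memory contact sets.

    Rows are (chrom_a, bin_a, chrom_b, bin_b, raw, norm).
    """

    def factory(rows, bin_size=100_000, **kwargs):
        df = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
        return ContactSet(df, bin_size, **kwargs)

    return factory
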