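import numpy as np
import pytest

from pdblists import read_structure
from pdblists.fixtures import FixtureSpec, build_fixture


def parse_fixture(kind, **kw):
    fx = build_fixture(FixtureSpec(kind, **kw))
    entry = read_structure(fx.pdb_text)
    return entry, fx.truth


@pytest.fixture(scope="session")
def helix_entry():
    entry, truth = parse_fixture("ideal_helix", length=12)
    return entry, truth


@pytest.fixture(scope="session")
def long_helix_entry():
    entry, truth = parse_fixture("ideal_helix", length=60)
    return entry, truth


@pytest.fixture(scope="session")
def sheet_entry():
    entry, truth = parse_fixture("ideal_sheet", length=6)
    return entry, truth


@pytest.fixture(scope="session")
def extended_entry():
    entry, truth = parse_fixture("extended_chain", length=10)
    return entry, truth


@pytest.fixture(scope="session")
def globule_entry():
    entry, truth = parse_fixture("globule", length=125)
    return entry, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
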