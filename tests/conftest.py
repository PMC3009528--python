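import numpy as np
import pytest
from hypothesis import settings

from pm13 import accessibility, fixtures, structure_io

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canonical_pdb(tmp_path_factory):
    """The canonical synthetic groove complex (identical to the packaged
    reference frame geometry)."""
    path = tmp_path_factory.mktemp("pdb") / "canonical.pdb"
    fixtures.make_complex_pdb(fixtures.FixtureSpec(seed=0), path)
    return path


@pytest.fixture(scope="session")
def standard_complex(canonical_pdb):
    raw = structure_io.parse_structure(canonical_pdb)
    spec = structure_io.identify_complexes(raw)[0]
    return structure_io.standardize_complex(raw, spec)


@pytest.fixture(scope="session")
def all_pockets(standard_complex):
    """Whole groove plus every extractable sub-pocket of the canonical
    complex (computed once; SASA extraction is the slow step)."""
    return accessibility.extract_pockets(standard_complex)


@pytest.fixture(scope="session")
def groove(all_pockets):
    return all_pockets["whole"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sorted_list(rng, max_len=30, scale=20.0):
    n = rng.integers(0, max_len + 1)
    return np.sort(rng.uniform(0.0, scale, n))


def standard_to_raw(sc):
    """View a StandardComplex as a RawStructure (for re-standardization)."""
    chains = [structure_io.Chain(cid, sc.chain(cid)) for cid in "ABC"]
    return structure_io.RawStructure("STD", chains)
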