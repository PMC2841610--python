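import numpy as np
import pytest

from helixpack.contact_labelling import ContactDefinition
from helixpack.io_formats import HelixSpan, ProteinRecord, SequenceProfile, Topology
from helixpack.synthetic_fixtures import BundleSpec, make_bundle, make_profiles


@pytest.fixture
def two_helix_topology() -> Topology:
    return Topology(helices=(HelixSpan(5, 24, 1), HelixSpan(30, 49, 2)))


@pytest.fixture
def small_record() -> ProteinRecord:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=55))
    return ProteinRecord(id="p1", sequence=seq)


@pytest.fixture
def small_profile(small_record) -> SequenceProfile:
    rng = np.random.default_rng(8)
    return SequenceProfile(
        scores=rng.integers(-8, 9, size=(small_record.length, 20)).astype(float)
    )


@pytest.fixture
def two_helix_bundle():
    return make_bundle(BundleSpec(n=2, helix_length=12, seed=5))


@pytest.fixture
def ring7_bundle():
    return make_bundle(BundleSpec(n=7, helix_length=12, seed=5))


def random_bundle_spec(rng: np.random.Generator) -> BundleSpec:
    """A randomized small bundle for oracle-equivalence sweeps."""
    n = int(rng.integers(2, 9))
    return BundleSpec(
        n=n,
        helix_length=int(rng.integers(6, 13)),
        spacing=float(rng.uniform(8.0, 12.0)),
        rotations=tuple(float(a) for a in rng.uniform(0, 360, size=n)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
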