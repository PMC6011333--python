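import pytest

from funcmark import fixtures as fx
from funcmark.seqdb import extract_core_region


@pytest.fixture(scope="session")
def family():
    """Default synthetic gene family (seed 1)."""
    return fx.gen_family(fx.FamilySpec(seed=1))


@pytest.fixture(scope="session")
def family_pair(family):
    return fx.family_primer_pair(family)


@pytest.fixture(scope="session")
def core_db(family, family_pair):
    """133-nt core-region database of the family's targets."""
    targets = [
        r for r in family.nucleotide.records if family.truth[r.id] == "target"
    ]
    cores, _ = extract_core_region(targets, family_pair)
    return cores
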