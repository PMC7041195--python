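import pytest

from paretoflux import solve_fba, toy_b


@pytest.fixture(scope="session")
def toy():
    """The 6-reaction branched toy with a duplicated product branch."""
    return toy_b()


@pytest.fixture(scope="session")
def toy_wt(toy):
    """Wild-type biomass-optimal reference flux of the toy."""
    return solve_fba(toy)


def canon(sets):
    """Canonical (sorted tuple-of-tuples) form of a collection of id sets."""
    return tuple(sorted(tuple(sorted(s)) for s in sets))
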