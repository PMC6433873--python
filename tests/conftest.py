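import pytest

from abatime.synthdata import SimConfig, generate_timecourse


@pytest.fixture(scope="session")
def default_sim():
    """One seeded realization of the default study design (2000 genes)."""
    return generate_timecourse(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_sim_calls(default_sim):
    """Pairwise DEG calls on the default simulation (computed once)."""
    from abatime.degcall import call_degs

    matrix, truth = default_sim
    return call_degs(matrix), truth
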