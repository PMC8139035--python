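import pytest

import mhscaleup as m


@pytest.fixture(scope="session")
def bundle():
    """Seeded synthetic input bundle at full study scale (83M population)."""
    return m.make_bundle(1)


@pytest.fixture(scope="session")
def base_spec():
    return m.default_scenarios()[0]


@pytest.fixture(scope="session")
def base_run(bundle, base_spec):
    """(costs, impacts, result) of the base front-loaded scenario."""
    return m.run_scenario(bundle, base_spec)


@pytest.fixture(scope="session")
def trajectories(bundle):
    from mhscaleup.cea_scenarios import build_trajectories
    return build_trajectories(bundle)


@pytest.fixture(scope="session")
def caseloads(bundle, trajectories):
    return m.build_series(bundle.population, bundle.epi,
                          bundle.interventions, trajectories)
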