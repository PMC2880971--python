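import pytest

from emdesign import (
    GAConfig,
    StrainEvaluator,
    ThermoTable,
    enumerate_efms,
    essential_reactions,
    fixture_dgf_table,
    toy_fixture,
)


@pytest.fixture(scope="session")
def toy_branch():
    return toy_fixture("TOY-BRANCH")


@pytest.fixture(scope="session")
def toy_rev():
    return toy_fixture("TOY-REV")


@pytest.fixture(scope="session")
def toy_coupled():
    return toy_fixture("TOY-COUPLED")


@pytest.fixture(scope="session")
def coupled_ems(toy_coupled):
    return enumerate_efms(toy_coupled)


@pytest.fixture(scope="session")
def coupled_table():
    return ThermoTable(dGf=fixture_dgf_table("TOY-COUPLED"))


@pytest.fixture(scope="session")
def coupled_protected(toy_coupled, coupled_ems):
    return essential_reactions(toy_coupled, coupled_ems)


@pytest.fixture()
def small_ga_config():
    return GAConfig(population_size=20, elite_count=3, max_generations=40,
                    rng_seed=0)


def make_evaluator(model, cfg, table=None, ems=None, protected=None):
    return StrainEvaluator(model, cfg, table, parent_ems=ems, protected=protected)
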