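import pytest

from isflink import SimulationConfig, assign_cohorts, derive_all_isf, generate_population


@pytest.fixture(scope="session")
def study_regime():
    """One mid-sized population under the default study-condition config,
    with ISF and cohorts derived; shared across read-only tests."""
    cfg = SimulationConfig(n_families=10000, seed=1)
    persons, links, records, perinatal = generate_population(cfg)
    isf = derive_all_isf(records, persons)
    cohorts = assign_cohorts(persons, isf, links, records,
                             birth_year_range=cfg.birth_year_range)
    return {
        "config": cfg, "persons": persons, "links": links,
        "records": records, "perinatal": perinatal,
        "isf": isf, "cohorts": cohorts,
    }


@pytest.fixture()
def small_population():
    cfg = SimulationConfig(n_families=400, seed=11)
    persons, links, records, perinatal = generate_population(cfg)
    return cfg, persons, links, records, perinatal
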