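import pytest
from hypothesis import HealthCheck, settings

import karyofish as kf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Published reference karyotypes for the five species.
REFERENCE_KARYOTYPES = {
    "robinia_pseudoacacia": ("2n = 2x = 20m + 2sm", "2B", "3.4821"),
    "robinia_pseudoacacia_idaho": ("2n = 2x = 20m + 2sm", "1A", "1.8997"),
    "robinia_pseudoacacia_decaisneana": ("2n = 2x = 20m + 2sm", "1B", "2.0787"),
    "styphnolobium_japonicum": ("2n = 2x = 14m + 12sm + 2st", "2B", "2.6847"),
    "amorpha_fruticosa": ("2n = 2x = 38m + 2sm", "1B", "3.2058"),
}

#: Reported number of 5S rDNA-bearing chromosomes per species.
N_5S_CHROMOSOMES = {
    "robinia_pseudoacacia": 8,
    "robinia_pseudoacacia_idaho": 6,
    "robinia_pseudoacacia_decaisneana": 8,
    "styphnolobium_japonicum": 2,
    "amorpha_fruticosa": 4,
}


@pytest.fixture(scope="session")
def fixtures_by_id():
    return {f.species_id: f for f in kf.load_all_fixtures()}


@pytest.fixture(scope="session")
def noise_free_tables(fixtures_by_id):
    return {
        sid: kf.generate_measurement_table(f)
        for sid, f in fixtures_by_id.items()
    }


@pytest.fixture(scope="session")
def sj_run():
    """Rendered S. japonicum spread (2n = 28), fixed seed."""
    return kf.simulate_species("styphnolobium_japonicum", seed=3)


@pytest.fixture(scope="session")
def sj_masks(sj_run):
    return kf.segment_chromosomes(sj_run.image)


@pytest.fixture(scope="session")
def rp_run():
    """Rendered R. pseudoacacia spread (2n = 22), fixed seed."""
    return kf.simulate_species("robinia_pseudoacacia", seed=11)


@pytest.fixture(scope="session")
def rp_masks(rp_run):
    return kf.segment_chromosomes(rp_run.image)
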