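import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def site_frames():
    from mortfeas import datasets

    return datasets.load_site_frames()


@pytest.fixture(scope="session")
def site_table():
    from mortfeas import datasets

    return datasets.load_site_table().set_index("site_id")


@pytest.fixture(scope="session")
def printed_totals():
    from mortfeas import datasets

    return datasets.load_printed_totals()


def projected_survey(site_id: str, recall: str):
    """Project a packaged survey scenario with its site's observed ledgers."""
    from mortfeas import costing, datasets

    scenario = datasets.load_scenario(site_id, recall)
    observed_time, observed_cost = datasets.load_observed_ledgers(site_id)
    rates_map, _ = datasets.load_staff_rates(site_id)
    return costing.project_survey(
        scenario, rates_map, observed_time=observed_time, observed_cost=observed_cost
    )
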