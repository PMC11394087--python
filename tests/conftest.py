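import pytest

from crocdiet import build_study_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    return build_study_fixture()


@pytest.fixture(scope="session")
def fixture_diet(fixture_dataset):
    return fixture_dataset.diet_table()


@pytest.fixture(scope="session")
def fixture_metrics(fixture_dataset, fixture_diet):
    from crocdiet import summarize_diet

    return summarize_diet(fixture_diet, vtd=fixture_dataset.vtd_ml)
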