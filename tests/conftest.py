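import pytest

from rsmextract import anova, datasets, fit_quadratic


@pytest.fixture(scope="session")
def extraction_table():
    return datasets.load_extraction_runs()


@pytest.fixture(scope="session")
def extraction_design():
    return datasets.extraction_design()


@pytest.fixture(scope="session")
def tpc_fit(extraction_table):
    return fit_quadratic(extraction_table, "TPC")


@pytest.fixture(scope="session")
def tfc_fit(extraction_table):
    return fit_quadratic(extraction_table, "TFC")


@pytest.fixture(scope="session")
def tpc_anova(tpc_fit, extraction_table):
    return anova(tpc_fit, extraction_table)


@pytest.fixture(scope="session")
def tfc_anova(tfc_fit, extraction_table):
    return anova(tfc_fit, extraction_table)
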