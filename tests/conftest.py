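import pytest

from tgskit.genotype_data import derive_national, load_fixture_table2
from tgskit.association import run_case_control_screen
from tgskit.tgs import build_wrm, load_score_tables


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_table2()


@pytest.fixture(scope="session")
def national_table(fixture_tables):
    return derive_national(fixture_tables.all_weightlifters, fixture_tables.international)


@pytest.fixture(scope="session")
def case_tables(fixture_tables):
    return {
        "all_weightlifters": fixture_tables.all_weightlifters,
        "international": fixture_tables.international,
    }


@pytest.fixture(scope="session")
def screen_results(case_tables, fixture_tables):
    return run_case_control_screen(case_tables, fixture_tables.controls)


@pytest.fixture(scope="session")
def score_tables():
    return load_score_tables()


@pytest.fixture(scope="session")
def derived_wrm(screen_results, case_tables, fixture_tables):
    wrm, audit = build_wrm(screen_results, case_tables, fixture_tables.controls)
    return wrm, audit
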