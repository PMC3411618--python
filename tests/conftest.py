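import pytest

from dla_hapassoc import FrequencyTable, assign_all, fixture_from_tables
from dla_hapassoc import reference_data as ref


@pytest.fixture(scope="session")
def fixture_cohort():
    """The published ESS cohort reconstructed from its printed counts."""
    return fixture_from_tables()


@pytest.fixture(scope="session")
def phased(fixture_cohort):
    return assign_all(fixture_cohort.cohort)


@pytest.fixture(scope="session")
def drb1_published_table():
    """The 2x10 DRB1 allele chromosome-count table, as printed."""
    return FrequencyTable.from_counts(ref.DRB1_ALLELE_COUNTS)


@pytest.fixture(scope="session")
def haplotype_published_table():
    """The 2x12 haplotype chromosome-count table (incl. the other row)."""
    return FrequencyTable.from_counts(ref.haplotype_table_rows())
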