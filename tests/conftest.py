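import pandas as pd
import pytest

from soilrisk import (
    ReferenceSet,
    SampleTable,
    generate_study_table,
    reference_site_summaries,
)


@pytest.fixture(scope="session")
def refs() -> ReferenceSet:
    return ReferenceSet.default()


@pytest.fixture(scope="session")
def survey_summaries():
    """The shipped 11-land-use survey statistics."""
    return reference_site_summaries()


@pytest.fixture(scope="session")
def study_table() -> SampleTable:
    """One synthetic 71-sample campaign, fixed seed."""
    return generate_study_table(1234)


@pytest.fixture()
def small_table() -> SampleTable:
    """Hand-written three-sample table (park-area As values chosen so the
    mean and range equal the published park-area statistics)."""
    data = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "land_use": ["PA", "PA", "PA"],
            "As": [3.32, 8.46, 13.90],
            "Cd": [0.70, 0.85, 1.05],
            "Pb": [1.16, 6.78, 13.87],
            "Cr": [20.09, 38.85, 56.58],
            "Ni": [5.98, 12.99, 17.88],
            "Cu": [9.13, 15.64, 23.10],
        }
    )
    return SampleTable(data=data)
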