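"""Shared fixtures: the hospital worked example and its printed outcomes."""

import pytest

from sdctab import DataTable
from sdctab.fixtures import hospital_hierarchies, hospital_schema, hospital_table

HOSPITAL_COLUMNS = ["name", "age", "gender", "city", "religion", "disease"]

# the k=2 k-anonymized version: name starred, age in 10-year bins
TABLE5_ROWS = [
    ("*", "[20, 30)", "Female", "Tamil Nadu", "Hindu", "Cancer"),
    ("*", "[20, 30)", "Male", "Tamil Nadu", "Hindu", "Cancer"),
    ("*", "[20, 30)", "Male", "Tamil Nadu", "Hindu", "Cancer"),
    ("*", "[20, 30)", "Male", "Tamil Nadu", "Hindu", "Cancer"),
    ("*", "[20, 30)", "Female", "Kerala", "Hindu", "Viral infection"),
    ("*", "[20, 30)", "Female", "Tamil Nadu", "Muslim", "TB"),
    ("*", "[20, 30)", "Male", "Karnataka", "Parsi", "No illness"),
    ("*", "[20, 30)", "Female", "Kerala", "Christian", "Heart-related"),
    ("*", "[20, 30)", "Male", "Karnataka", "Buddhist", "TB"),
    ("*", "[10, 20)", "Male", "Kerala", "Hindu", "Cancer"),
    ("*", "[20, 30)", "Male", "Karnataka", "Hindu", "Heart-related"),
    ("*", "[10, 20)", "Male", "Kerala", "Christian", "Heart-related"),
    ("*", "[10, 20)", "Male", "Kerala", "Christian", "Viral infection"),
]

# the k=2 + l=2 l-diversified version: additionally city suppressed
TABLE6_ROWS = [row[:3] + ("*",) + row[4:] for row in TABLE5_ROWS]


@pytest.fixture
def hospital() -> DataTable:
    return hospital_table()


@pytest.fixture
def schema():
    return hospital_schema()


@pytest.fixture
def hierarchies():
    return hospital_hierarchies()


@pytest.fixture
def table5() -> DataTable:
    return DataTable.from_records(HOSPITAL_COLUMNS, TABLE5_ROWS)


@pytest.fixture
def table6() -> DataTable:
    return DataTable.from_records(HOSPITAL_COLUMNS, TABLE6_ROWS)
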