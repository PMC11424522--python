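import pytest

from growthref.datasets import load_published_reference


@pytest.fixture(scope="session")
def published_table():
    return load_published_reference()


#: published cells that disagree with their own row's printed L/S/M by
#: exactly 0.02 — consistent with the parameters being printed at three
#: decimals; pinned separately rather than folded into the exact check
BOYS_BMI_ROUNDING_CELLS = {
    ("male", 12, "bmi", "P15"),
    ("male", 12, "bmi", "P85"),
    ("male", 15, "bmi", "P85"),
    ("male", 16, "bmi", "P85"),
}


def reproducible_cells(table):
    """Published cells expected to follow the LMS transform exactly.

    Excluded as internally inconsistent in the published table: the
    girls' BMI off-median cells, the girls' weight P65/P90 cells at ages
    15-16 (the two ages' upper cells appear swapped), and the four boys'
    BMI cells in ``BOYS_BMI_ROUNDING_CELLS``.
    """
    cells = []
    for row in table.rows:
        for label, printed in row.percentiles.items():
            if row.sex == "female" and row.measure == "bmi" and label != "P50":
                continue
            if (
                row.sex == "female"
                and row.measure == "weight"
                and row.age_group >= 15
                and label in ("P65", "P90")
            ):
                continue
            if (row.sex, row.age_group, row.measure, label) in BOYS_BMI_ROUNDING_CELLS:
                continue
            cells.append((row.sex, row.age_group, row.measure, row.params, label, printed))
    return cells


@pytest.fixture(scope="session")
def published_cells(published_table):
    return reproducible_cells(published_table)
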