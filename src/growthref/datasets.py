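"""Packaged published tables: the local LMS reference, international
median standards, and the published back-substitution pairs."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compare import ExternalReference
from .reference import PercentileTable

__all__ = [
    "load_published_reference",
    "load_international_medians",
    "load_back_substitution_pairs",
]


def _data_path(name: str):
    return resources.files("growthref.data").joinpath(name)


def load_published_reference() -> PercentileTable:
    """The published South Punjab 2019 LMS reference (heights, weights, BMI)."""
    from .io import read_percentile_table

    with resources.as_file(_data_path("south_punjab_2019_lms.csv")) as path:
        return read_percentile_table(path)


def load_international_medians() -> list[ExternalReference]:
    """External P50 standards (WHO, US-CDC, India, Turkey, China)."""
    from .io import read_external_references

    with resources.as_file(_data_path("international_p50.csv")) as path:
        return read_external_references(path)


def load_back_substitution_pairs() -> pd.DataFrame:
    """Published actual/fitted P50 pairs with their printed signed errors."""
    with resources.as_file(_data_path("back_substitution_published.csv")) as path:
        return pd.read_csv(path, comment="#")
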