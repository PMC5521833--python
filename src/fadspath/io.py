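"""Cohort table I/O: comma-delimited text, header row, UTF-8, '.' decimal,
empty field for missing."""

from __future__ import annotations

import pandas as pd

__all__ = ["read_cohort", "write_cohort"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep="", encoding="utf-8", float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
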