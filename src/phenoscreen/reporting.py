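"""Content tables with the survey's missing-value and rounding conventions.

Per-sample contents (mg/kg dry sample) are tabulated with an ``Average``
row holding the arithmetic mean over the non-missing samples of each
column; a column with no quantifiable sample stays missing.  Displayed
values are truncated toward zero at three significant digits (internal
values keep full precision; truncation is display-only), and missing
cells render as an em dash ("—") in text and as empty cells in CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, Decimal
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["ContentTable", "average_content", "display_round", "MISSING_MARK"]

MISSING_MARK = "—"
SIG_DIGITS = 3


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def average_content(values: Sequence[float | None]) -> float | None:
    """Mean over the non-missing values; missing when all are missing."""
    if len(values) == 0:
        raise ValueError("empty value list")
    present = [v for v in values if not _is_missing(v)]
    if not present:
        return None
    return sum(present) / len(present)


def display_round(value: float) -> str:
    """Truncate toward zero to three significant digits; integers print
    without a trailing '.0'."""
    if value < 0:
        raise ValueError("contents are non-negative")
    if value == 0:
        return "0"
    d = Decimal(repr(value))
    quantum = Decimal(1).scaleb(d.adjusted() - (SIG_DIGITS - 1))
    t = d.quantize(quantum, rounding=ROUND_DOWN)
    s = format(t, "f")
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


def _cell(v) -> str:
    return MISSING_MARK if _is_missing(v) else display_round(v)


@dataclass
class ContentTable:
    """Per-sample contents plus the derived Average row.

    ``values`` maps sample id -> {compound code: mg/kg or None}.
    """

    compounds: list[str]
    values: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def add_sample(self, sample_id: str, contents: Mapping[str, float | None]) -> None:
        self.values[str(sample_id)] = {c: contents.get(c) for c in self.compounds}

    def column(self, code: str) -> list[float | None]:
        return [self.values[s].get(code) for s in self.values]

    def averages(self) -> dict[str, float | None]:
        if not self.values:
            raise ValueError("no samples in table")
        return {c: average_content(self.column(c)) for c in self.compounds}

    def to_frame(self, rendered: bool = True) -> pd.DataFrame:
        """The full table (samples + Average row) as a DataFrame.

        With ``rendered=True`` cells are display strings (missing = "—");
        otherwise full-precision floats with NaN for missing.
        """
        rows = {}
        for s, contents in self.values.items():
            rows[s] = {c: contents.get(c) for c in self.compounds}
        rows["Average"] = self.averages()
        df = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
        df = df.reindex(columns=self.compounds)
        if rendered:
            df = df.map(_cell)
        else:
            df = df.map(lambda v: float("nan") if _is_missing(v) else float(v))
        df.index.name = "sample"
        return df

    def to_csv(self, path) -> None:
        """CSV with display-rounded cells; missing cells are empty."""
        df = self.to_frame(rendered=True).replace(MISSING_MARK, "")
        df.to_csv(path)

    def render(self) -> str:
        """Plain-text table with em dashes for missing values."""
        return self.to_frame(rendered=True).to_string()
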