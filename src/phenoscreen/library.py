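"""Compound library: the twelve target phenols and their acquisition constants.

Each record bundles what the instrument method needs to know about one
analyte: its phenol family, nominal molecular weight, the unit-resolution
adduct fingerprint observed in dual-polarity full scans, the retention
time, the SIM channel used for quantification, and the reference standard
whose calibration line quantifies it.  Nine compounds are reference
standards and quantify against themselves; the three newly elucidated
bibenzyls map to a family surrogate (DDB -> GI, MOL -> ER, CHT -> ER).

All m/z values are nominal, integer-centred 1-Da bins, as produced by a
single-quadrupole detector: [M+H]+ = M+1, [M+Na]+ = M+23, [M-H]- = M-1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "FragmentIon",
    "CompoundRecord",
    "make_compound_library",
    "load_library_csv",
    "save_library_csv",
    "get_compound",
    "standards_only",
    "PROTON", "SODIUM",
]

PROTON = 1    # nominal mass shift of [M+H]+ / -1 for [M-H]-
SODIUM = 23   # nominal mass shift of [M+Na]+

FAMILIES = ("bibenzyl", "phenanthrene", "coumarin", "flavone")


@dataclass(frozen=True)
class FragmentIon:
    """One ion of an adduct fingerprint at unit mass resolution."""

    mz: int                    # nominal m/z, Da
    relative_abundance: float  # % of the base peak, in (0, 100]
    polarity: str              # "positive" | "negative"

    def __post_init__(self) -> None:
        if not (0 < self.relative_abundance <= 100):
            raise ValueError(f"relative abundance {self.relative_abundance} not in (0, 100]")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """Acquisition and quantification constants for one analyte."""

    code: str
    name: str
    family: str
    mw: int                      # nominal molecular weight, Da
    rt: float                    # retention time, min
    ions: tuple[FragmentIon, ...]
    has_negative_signal: bool    # does the compound ionise in negative mode?
    sim_mz: int                  # SIM quantification ion, Da
    sim_polarity: str
    sim_window: tuple[float, float]  # SIM acquisition window, min
    surrogate: str               # code of the quantifying standard
    is_standard: bool

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.sim_window[0] >= self.sim_window[1]:
            raise ValueError("SIM window start must precede stop")
        if not any(abs(i.relative_abundance - 100) < 1e-9 for i in self.ions):
            raise ValueError("fingerprint must contain a base peak at 100%")

    @property
    def base_ion(self) -> FragmentIon:
        return max(self.ions, key=lambda i: i.relative_abundance)

    def ions_for(self, polarity: str) -> tuple[FragmentIon, ...]:
        return tuple(i for i in self.ions if i.polarity == polarity)


def _parse_ions(spec: str) -> tuple[FragmentIon, ...]:
    # e.g. "297+:100;275+:52" -> two positive ions
    out = []
    for part in spec.split(";"):
        head, abund = part.split(":")
        pol = "positive" if head.endswith("+") else "negative"
        out.append(FragmentIon(int(head[:-1]), float(abund), pol))
    return tuple(out)


def _format_ions(ions: Iterable[FragmentIon]) -> str:
    sign = {"positive": "+", "negative": "-"}
    return ";".join(f"{i.mz}{sign[i.polarity]}:{i.relative_abundance:g}" for i in ions)


def load_library_csv(path) -> list[CompoundRecord]:
    """Read a compound-library table (comment lines start with '#')."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(l for l in fh if not l.startswith("#"))]
    records = []
    for r in rows:
        records.append(
            CompoundRecord(
                code=r["code"],
                name=r["name"],
                family=r["family"],
                mw=int(r["mw"]),
                rt=float(r["rt_min"]),
                ions=_parse_ions(r["ions"]),
                has_negative_signal=bool(int(r["has_negative_signal"])),
                sim_mz=int(r["sim_mz"]),
                sim_polarity=r["sim_polarity"],
                sim_window=(float(r["sim_start_min"]), float(r["sim_stop_min"])),
                surrogate=r["surrogate"],
                is_standard=bool(int(r["is_standard"])),
            )
        )
    return records


def save_library_csv(records: Iterable[CompoundRecord], path) -> None:
    cols = ["code", "name", "family", "mw", "rt_min", "ions", "has_negative_signal",
            "sim_mz", "sim_polarity", "sim_start_min", "sim_stop_min", "surrogate",
            "is_standard"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for rec in records:
            w.writerow([rec.code, rec.name, rec.family, rec.mw, rec.rt,
                        _format_ions(rec.ions), int(rec.has_negative_signal),
                        rec.sim_mz, rec.sim_polarity, rec.sim_window[0],
                        rec.sim_window[1], rec.surrogate, int(rec.is_standard)])


def make_compound_library() -> list[CompoundRecord]:
    """The packaged twelve-compound library (nine standards + DDB, MOL, CHT)."""
    with resources.as_file(
        resources.files("phenoscreen.data") / "compound_library.csv"
    ) as p:
        return load_library_csv(p)


def get_compound(library: Iterable[CompoundRecord], code: str) -> CompoundRecord:
    for rec in library:
        if rec.code == code:
            return rec
    raise KeyError(f"compound {code!r} not in library")


def standards_only(library: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """The subset of records backed by an authentic reference standard."""
    return [r for r in library if r.is_standard]
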