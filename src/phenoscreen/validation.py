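"""Method validation: spike recovery and repeatability (RSD).

Recovery is the fraction of a known fortification recovered through the
whole procedure, 100 * (mean spiked content - endogenous content) / added;
the endogenous level is the mean content of paired unspiked blanks, with
below-LOQ blanks treated as zero.  Repeatability is the relative standard
deviation of the replicate contents (sample SD, n-1 denominator, over the
mean, in percent) — the analytical-chemistry convention.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .simulate import SpikedBatch

__all__ = ["ValidationRecord", "recovery_pct", "rsd_pct", "validate_batch",
           "write_validation_report"]


@dataclass
class ValidationRecord:
    """Recovery/RSD summary for one compound at one fortification level."""

    compound: str
    spike_level: float               # mg/kg added
    endogenous: float                # mg/kg (0 when not found in blanks)
    replicate_contents: list[float]  # measured contents of spiked replicates
    recovery: float                  # %
    rsd: float                       # %

    def __post_init__(self) -> None:
        if len(self.replicate_contents) < 2:
            raise ValueError("need at least 2 replicate contents")
        if self.rsd < 0:
            raise ValueError("RSD must be >= 0")


def recovery_pct(mean_spiked: float, endogenous: float, added: float) -> float:
    """Spike recovery in percent of the added amount."""
    if added <= 0:
        raise ValueError("added amount must be positive")
    if mean_spiked < 0:
        raise ValueError("mean spiked content must be >= 0")
    return 100.0 * (mean_spiked - endogenous) / added


def rsd_pct(values: Sequence[float]) -> float:
    """Relative standard deviation (%%), sample SD over mean."""
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    mean = statistics.fmean(values)
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * statistics.stdev(values) / abs(mean)


def validate_batch(batch: SpikedBatch,
                   measure: Callable,
                   codes: Sequence[str] | None = None) -> list[ValidationRecord]:
    """Run the measurement pipeline over a fortified batch.

    Parameters
    ----------
    batch
        Spiked replicates with paired blanks (see ``simulate_spiked_batch``).
    measure
        Callable mapping a RawRun to {code: content-or-None}; normally
        ``pipeline.make_measurer(...)`` wrapping detect -> integrate ->
        quantify.
    codes
        Compounds to report; defaults to the batch's spiked compounds.
    """
    if not batch.blanks:
        raise ValueError("paired blank runs are required")
    if len(batch.spiked) < 2:
        raise ValueError("need at least 2 spiked replicates")
    codes = list(codes) if codes is not None else list(batch.endogenous)

    spiked_contents = [measure(run) for run, _ in batch.spiked]
    blank_contents = [measure(run) for run, _ in batch.blanks]

    records = []
    for code in codes:
        reps = [c.get(code) or 0.0 for c in spiked_contents]
        blanks = [c.get(code) or 0.0 for c in blank_contents]  # below LOQ -> 0
        endogenous = statistics.fmean(blanks)
        mean_spiked = statistics.fmean(reps)
        records.append(ValidationRecord(
            compound=code, spike_level=batch.spike_level, endogenous=endogenous,
            replicate_contents=reps,
            recovery=recovery_pct(mean_spiked, endogenous, batch.spike_level),
            rsd=rsd_pct(reps) if any(reps) else 0.0))
    return records


def write_validation_report(records: Sequence[ValidationRecord], path) -> None:
    """CSV report: compound, endogenous level, recovery and RSD per spike level."""
    levels = sorted({r.spike_level for r in records})
    by_key: Mapping = {(r.compound, r.spike_level): r for r in records}
    compounds = list(dict.fromkeys(r.compound for r in records))
    header = ["compound", "sample_mg_kg"]
    for lv in levels:
        header += [f"recovery_{lv:g}_pct", f"rsd_{lv:g}_pct"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for code in compounds:
            any_rec = next(r for r in records if r.compound == code)
            row = [code, f"{any_rec.endogenous:.4g}" if any_rec.endogenous else ""]
            for lv in levels:
                r = by_key.get((code, lv))
                row += ([f"{r.recovery:.1f}", f"{r.rsd:.1f}"] if r else ["", ""])
            w.writerow(row)
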