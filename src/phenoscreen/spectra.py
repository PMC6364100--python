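"""In-memory containers for unit-resolution dual-polarity LC-MS runs.

A :class:`RawRun` is one injection: a time-ordered series of scan cycles,
each holding one positive and one negative full-scan spectrum over the
configured m/z range (50-400 Da by default), plus a set of SIM traces
recorded on fixed (m/z, polarity) channels inside retention-time windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["MassSpectrum", "ScanCycle", "SimChannel", "Chromatogram", "RawRun"]

POLARITIES = ("positive", "negative")


@dataclass
class MassSpectrum:
    """One centroided unit-resolution spectrum: integer m/z bins + intensities."""

    polarity: str
    mz: np.ndarray          # nominal integer bins, Da, unique & ascending
    intensity: np.ndarray   # counts, >= 0
    rt: float               # min

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.polarity not in POLARITIES:
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if len(np.unique(self.mz)) != len(self.mz):
            raise ValueError("duplicate m/z bins in spectrum")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")

    @property
    def is_empty(self) -> bool:
        return len(self.mz) == 0 or not np.any(self.intensity > 0)

    def intensity_at(self, mz: int) -> float:
        idx = np.nonzero(self.mz == int(mz))[0]
        return float(self.intensity[idx[0]]) if len(idx) else 0.0

    def base_peak(self) -> tuple[int, float]:
        if self.is_empty:
            raise ValueError("empty spectrum has no base peak")
        i = int(np.argmax(self.intensity))
        return int(self.mz[i]), float(self.intensity[i])


@dataclass
class ScanCycle:
    """One acquisition cycle: a positive and a negative full scan at one RT."""

    rt: float
    positive: MassSpectrum
    negative: MassSpectrum

    def spectrum(self, polarity: str) -> MassSpectrum:
        if polarity == "positive":
            return self.positive
        if polarity == "negative":
            return self.negative
        raise ValueError(f"bad polarity {polarity!r}")


@dataclass(frozen=True)
class SimChannel:
    """A selected-ion-monitoring channel: nominal m/z, polarity, RT window."""

    mz: int
    polarity: str
    window: tuple[float, float]   # (start, stop) min

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede stop")

    @property
    def label(self) -> str:
        sign = "+" if self.polarity == "positive" else "-"
        return f"SIM {self.mz}{sign} {self.window[0]:g}-{self.window[1]:g}min"


@dataclass
class Chromatogram:
    """Intensity vs retention time on one channel (SIM, XIC or TIC)."""

    rt: np.ndarray         # min, strictly increasing
    intensity: np.ndarray  # counts, >= 0
    channel: str = ""      # human-readable channel descriptor

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if len(self.rt) > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")

    def __len__(self) -> int:
        return len(self.rt)


@dataclass
class RawRun:
    """One injection: full-scan cycles plus SIM traces and acquisition metadata."""

    cycles: list[ScanCycle]
    sim_traces: dict[SimChannel, Chromatogram] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = self.rts
        if len(rts) > 1 and np.any(np.diff(rts) <= 0):
            raise ValueError("cycle retention times must be strictly increasing")
        lo, hi = self.metadata.get("scan_range", (None, None))
        if lo is not None:
            for c in self.cycles:
                for spec in (c.positive, c.negative):
                    if len(spec.mz) and (spec.mz.min() < lo or spec.mz.max() > hi):
                        raise ValueError("full-scan m/z outside the scan range")

    @property
    def rts(self) -> np.ndarray:
        return np.array([c.rt for c in self.cycles], dtype=float)

    def spectra(self, polarity: str) -> Iterator[MassSpectrum]:
        for c in self.cycles:
            yield c.spectrum(polarity)

    def sim_trace(self, mz: int, polarity: str) -> Chromatogram:
        """The SIM trace whose channel monitors (mz, polarity)."""
        for ch, trace in self.sim_traces.items():
            if ch.mz == int(mz) and ch.polarity == polarity:
                return trace
        raise KeyError(f"no SIM channel at m/z {mz} ({polarity})")
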