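"""Chromatogram extraction, peak detection/integration, baseline noise.

Detection operates on a lightly smoothed trace (centred 5-point moving
average); heights and areas are measured on the raw trace after
subtracting a linear baseline drawn between the peak boundaries, so peak
lists and areas are invariant to constant baseline offsets.  S/N is the
baseline-subtracted height divided by the baseline noise SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks as _find_maxima

from .spectra import Chromatogram, RawRun, POLARITIES

__all__ = [
    "Peak",
    "extract_xic",
    "total_ion_chromatogram",
    "smooth",
    "detect_peaks",
    "integrate_peak",
    "estimate_baseline_noise",
]

#: boundary threshold: fraction of (smoothed) peak height above the local base
BOUNDARY_FRACTION = 0.01
#: centred moving-average width, points.  At the default sampling (0.05 min
#: cycles, 0.05 min elution sigma) a 5-point window spans 5 sigma and merges
#: peaks 0.3 min apart (erianin/chrysotoxin share a SIM channel at that
#: spacing), so 3 points is the widest usable window.
SMOOTH_WINDOW = 3


@dataclass
class Peak:
    """One detected chromatographic feature (baseline-subtracted)."""

    apex_rt: float
    start_rt: float
    end_rt: float
    height: float   # counts
    area: float     # counts*min
    snr: float      # height / baseline-noise SD; inf on a noise-free trace

    def __post_init__(self) -> None:
        if not (self.start_rt < self.apex_rt < self.end_rt):
            raise ValueError("peak boundaries must bracket the apex")
        if self.height < 0 or self.area < 0:
            raise ValueError("height and area must be >= 0")

    @property
    def width(self) -> float:
        return self.end_rt - self.start_rt


def extract_xic(run: RawRun, mz: float, tol: float, polarity: str) -> Chromatogram:
    """Extracted-ion chromatogram: per-cycle summed intensity of full-scan
    bins within ``mz +- tol``."""
    if polarity not in POLARITIES:
        raise ValueError(f"bad polarity {polarity!r}")
    lo_r, hi_r = run.metadata.get("scan_range", (50, 400))
    if not (lo_r <= mz <= hi_r):
        raise ValueError(f"m/z {mz} outside scan range {lo_r}-{hi_r}")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    intens = np.empty(len(run.cycles))
    for i, spec in enumerate(run.spectra(polarity)):
        sel = (spec.mz >= mz - tol) & (spec.mz <= mz + tol)
        intens[i] = spec.intensity[sel].sum()
    return Chromatogram(run.rts, intens, f"XIC {mz:g}±{tol:g} {polarity}")


def total_ion_chromatogram(run: RawRun, polarity: str) -> Chromatogram:
    """Per-cycle total ion current for one polarity."""
    if polarity not in POLARITIES:
        raise ValueError(f"bad polarity {polarity!r}")
    intens = np.array([spec.intensity.sum() for spec in run.spectra(polarity)])
    return Chromatogram(run.rts, intens, f"TIC {polarity}")


def smooth(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centred moving average; edges use the available shorter window."""
    y = np.asarray(y, dtype=float)
    if window <= 1 or len(y) < 2:
        return y.copy()
    kernel = np.ones(window)
    return np.convolve(y, kernel, "same") / np.convolve(np.ones_like(y), kernel, "same")


def _residual_noise(y: np.ndarray, sm: np.ndarray) -> float:
    """Robust noise SD from the smoothing residual (MAD-scaled)."""
    r = y - sm
    mad = np.median(np.abs(r - np.median(r)))
    return 1.4826 * float(mad)


def _walk_boundary(sm: np.ndarray, apex: int, step: int, tol: float) -> int:
    """Boundary index on one side: nearest point where the smoothed trace
    reaches the local base + 1% of height, or the local minimum if the
    trace turns upward first.  The descent tolerates upticks below ``tol``
    (noise), stopping only when the trace rises materially above the
    running minimum."""
    j = k = apex
    while 0 < k < len(sm) - 1:
        k += step
        if sm[k] < sm[j]:
            j = k
        elif sm[k] - sm[j] > tol:
            break
    base = sm[j]
    target = base + BOUNDARY_FRACTION * (sm[apex] - base)
    k = apex
    while k != j and sm[k] > target:
        k += step
    return k


def detect_peaks(chrom: Chromatogram, min_snr: float = 3.0,
                 min_width: float = 0.0) -> list[Peak]:
    """Detect disjoint peaks on a chromatogram, ordered by apex RT.

    A flat trace yields an empty list.  On a noise-free trace every local
    maximum with positive height is reported (S/N is infinite).
    """
    if len(chrom) == 0:
        raise ValueError("empty chromatogram")
    y = chrom.intensity
    rt = chrom.rt
    if len(y) < 3 or np.ptp(y) == 0:
        return []
    sm = smooth(y)
    noise = _residual_noise(y, sm)
    # offset-invariant detection floor: noise-scaled, or 1% of the trace's
    # dynamic range on an effectively noise-free trace
    floor = max(min_snr * noise, BOUNDARY_FRACTION * float(np.ptp(sm)), 1e-12)
    apexes, _ = _find_maxima(sm, prominence=floor)
    if len(apexes) == 0:
        return []

    walk_tol = max(3.0 * noise, BOUNDARY_FRACTION * float(np.ptp(sm)))
    bounds = [[_walk_boundary(sm, a, -1, walk_tol),
               _walk_boundary(sm, a, +1, walk_tol)] for a in apexes]
    # neighbours whose boundaries overlap or nearly touch share a boundary
    # at the raw-trace valley between their apexes (perpendicular drop)
    adjacent = []
    for i in range(len(apexes) - 1):
        touching = bounds[i][1] >= bounds[i + 1][0] - 3
        adjacent.append(touching)
        if touching:
            valley = apexes[i] + int(np.argmin(y[apexes[i]:apexes[i + 1] + 1]))
            bounds[i][1] = valley
            bounds[i + 1][0] = valley

    # adjacent peaks form a cluster; every member's baseline is the line
    # between the cluster's outer boundaries, so a small peak is not cut
    # off by the flank of a large neighbour
    clusters: list[list[int]] = []
    for i in range(len(apexes)):
        if clusters and adjacent[i - 1]:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    anchor = {}
    for members in clusters:
        lo, hi = bounds[members[0]][0], bounds[members[-1]][1]
        for i in members:
            anchor[i] = (lo, hi)

    def anchor_value(idx: int, outward: int) -> float:
        # noise-robust baseline level: mean of up to 5 points from the anchor
        # going away from the peak (never into it)
        if outward < 0:
            return float(np.mean(y[max(idx - 4, 0):idx + 1]))
        return float(np.mean(y[idx:idx + 5]))

    peaks = []
    for i, (a, (s, e)) in enumerate(zip(apexes, bounds)):
        if e - s < 2:
            continue
        lo, hi = anchor[i]
        base_lo, base_hi = anchor_value(lo, -1), anchor_value(hi, +1)

        # clamp the integration span to apex +- 4 sigma, with sigma taken
        # from the smoothed peak's FWHM; keeps the noise integral short
        # while the (systematic) tail loss cancels through calibration
        width_idx = _half_height_width(sm, a, s, e)
        if width_idx > 0:
            clamp = max(int(round(4 * width_idx / 2.355)), 2)
            s = max(s, a - clamp)
            e = min(e, a + clamp)
        if e - s < 2:
            continue

        def base_of(idx):
            return np.interp(rt[idx], [rt[lo], rt[hi]], [base_lo, base_hi])

        apex_idx = s + int(np.argmax(y[s:e + 1]))
        if apex_idx in (s, e):
            apex_idx = a
        height = float(y[apex_idx] - base_of(apex_idx))
        if height <= 0:
            continue
        snr = height / noise if noise > 0 else math.inf
        if snr < min_snr:
            continue
        if rt[e] - rt[s] < min_width:
            continue
        if not (rt[s] < rt[apex_idx] < rt[e]):
            continue
        seg = slice(s, e + 1)
        baseline = np.interp(rt[seg], [rt[lo], rt[hi]], [base_lo, base_hi])
        area = max(float(np.trapezoid(y[seg] - baseline, rt[seg])), 0.0)
        peaks.append(Peak(apex_rt=float(rt[apex_idx]), start_rt=float(rt[s]),
                          end_rt=float(rt[e]), height=height, area=area,
                          snr=snr))
    return sorted(peaks, key=lambda p: p.apex_rt)


def _half_height_width(sm: np.ndarray, apex: int, s: int, e: int) -> int:
    """Full width at half the smoothed height, in samples (0 if undefined)."""
    base = min(sm[s], sm[e])
    half = base + 0.5 * (sm[apex] - base)
    left = apex
    while left > s and sm[left - 1] > half:
        left -= 1
    right = apex
    while right < e and sm[right + 1] > half:
        right += 1
    w = right - left
    return w if w > 0 else 0


def integrate_peak(chrom: Chromatogram, peak: Peak) -> float:
    """Trapezoidal area above a linear baseline between the boundaries."""
    rt, y = chrom.rt, chrom.intensity
    if peak.start_rt < rt[0] or peak.end_rt > rt[-1]:
        raise ValueError("peak boundaries outside the chromatogram range")
    s = int(np.searchsorted(rt, peak.start_rt, side="left"))
    e = int(np.searchsorted(rt, peak.end_rt, side="right")) - 1
    if e <= s:
        return 0.0
    seg_rt, seg_y = rt[s:e + 1], y[s:e + 1]
    baseline = np.interp(seg_rt, [seg_rt[0], seg_rt[-1]], [seg_y[0], seg_y[-1]])
    area = float(np.trapezoid(seg_y - baseline, seg_rt))
    return max(area, 0.0)


def estimate_baseline_noise(chrom: Chromatogram,
                            blank_window: tuple[float, float]) -> float:
    """Noise as the sample SD of intensities in a peak-free blank window."""
    lo, hi = blank_window
    sel = (chrom.rt >= lo) & (chrom.rt <= hi)
    if sel.sum() < 20:
        raise ValueError("blank window must contain at least 20 points")
    for p in detect_peaks(chrom):
        if p.end_rt >= lo and p.start_rt <= hi:
            raise ValueError(
                f"blank window overlaps a detected peak at {p.apex_rt:.2f} min")
    return float(np.std(chrom.intensity[sel], ddof=1))
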