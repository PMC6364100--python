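"""Screening of unknown peaks: spectra averaging, adduct fingerprints,
family classification and identification against the standard library.

The classification rules encode how each phenol family ionises on a
unit-resolution single-quadrupole detector:

* **Bibenzyls** sodiate readily: they show an [M+Na]+ / [M+H]+ pair
  spaced 22 Da in positive mode (usually with the sodium adduct as base
  peak) and, except for the hydroxyl-free chrysotobibenzyl, also ionise
  in negative mode.  MW = m/z([M+Na]+) - 23.
* **Flavones** ionise far more strongly in negative mode ([M-H]-);
  MW = m/z + 1.
* **Phenanthrenes** are positive-only with a characteristic neutral loss
  (28 or 32 Da) next to [M+H]+; MW = m/z - 1.
* A positive-only single-ion spectrum is called **coumarin-like**;
  MW = m/z - 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .library import PROTON, SODIUM, CompoundRecord
from .signal import Peak
from .spectra import MassSpectrum, RawRun

__all__ = [
    "AdductFingerprint",
    "FingerprintIon",
    "FamilyCall",
    "Identification",
    "average_spectrum",
    "build_fingerprint",
    "classify_family",
    "identify_compound",
    "screen_run",
    "write_screening_report",
]

#: positive-ion pair spacing of the sodium/proton adduct pair, Da
NA_H_SPACING = SODIUM - PROTON  # 22
#: accepted [M+H]+ relative abundance when [M+Na]+ is the base peak
H_ADDUCT_WINDOW = (20.0, 80.0)
#: neutral-loss spacings characteristic of phenanthrenes, Da
PHENANTHRENE_LOSSES = (28, 32)

DEFAULT_RT_TOL = 0.1    # min
DEFAULT_MZ_TOL = 0.5    # Da (unit resolution)
DEFAULT_MIN_REL_ABUND = 10.0  # %


@dataclass(frozen=True)
class FingerprintIon:
    mz: int
    relative_abundance: float  # % of base peak
    polarity: str


@dataclass
class AdductFingerprint:
    """Adduct pattern of one chromatographic peak, both polarities."""

    base_peak_mz: int
    base_polarity: str
    ions: list[FingerprintIon]       # sorted by m/z, abundances in (0, 100]
    has_positive_signal: bool
    has_negative_signal: bool
    rt: float

    def __post_init__(self) -> None:
        self.ions = sorted(self.ions, key=lambda i: i.mz)
        for i in self.ions:
            if not (0 < i.relative_abundance <= 100):
                raise ValueError("relative abundances must lie in (0, 100]")
        if not any(i.mz == self.base_peak_mz
                   and abs(i.relative_abundance - 100) < 1e-9
                   for i in self.ions):
            raise ValueError("base peak must appear in the ion list at 100%")

    def ions_for(self, polarity: str) -> list[FingerprintIon]:
        return [i for i in self.ions if i.polarity == polarity]

    def most_intense(self, polarity: str | None = None) -> FingerprintIon:
        pool = self.ions if polarity is None else self.ions_for(polarity)
        return max(pool, key=lambda i: i.relative_abundance)


@dataclass
class FamilyCall:
    family: str                  # bibenzyl|phenanthrene|coumarin|flavone|unknown
    inferred_mw: int | None      # set iff family != unknown
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family == "unknown" and self.inferred_mw is not None:
            raise ValueError("unknown family cannot carry an inferred MW")


@dataclass
class Identification:
    compound: str                # code, or "unknown"
    status: str                  # known_standard | newly_elucidated | unidentified
    matched_rt: float
    surrogate_standard: str | None
    sim_ion: int | None
    sim_polarity: str | None

    def __post_init__(self) -> None:
        if self.status == "newly_elucidated" and self.surrogate_standard is None:
            raise ValueError("newly elucidated compounds need a surrogate standard")
        if self.status != "unidentified" and self.sim_ion is None:
            raise ValueError("identified compounds need a SIM ion")


def average_spectrum(run: RawRun, rt_window: tuple[float, float],
                     polarity: str) -> MassSpectrum:
    """Bin-wise mean spectrum over the window, background-subtracted using
    the mean of an equal number of flanking blank cycles."""
    lo, hi = rt_window
    rts = run.rts
    inside = np.nonzero((rts >= lo) & (rts <= hi))[0]
    if len(inside) == 0:
        raise ValueError(f"no scan cycle inside window {rt_window}")
    scan_lo, scan_hi = run.metadata.get("scan_range", (50, 400))
    axis = np.arange(scan_lo, scan_hi + 1)

    def dense_mean(indices) -> np.ndarray:
        acc = np.zeros(len(axis))
        for i in indices:
            spec = run.cycles[i].spectrum(polarity)
            acc[spec.mz - scan_lo] += spec.intensity
        return acc / max(len(indices), 1)

    signal = dense_mean(inside)
    n_flank = len(inside)
    flank = list(range(max(inside[0] - n_flank, 0), inside[0])) + \
        list(range(inside[-1] + 1, min(inside[-1] + 1 + n_flank, len(rts))))
    background = dense_mean(flank) if flank else np.zeros_like(signal)
    net = np.clip(signal - background, 0.0, None)
    nz = np.nonzero(net > 0)[0]
    mid = float(rts[inside].mean())
    return MassSpectrum(polarity, axis[nz], net[nz], mid)


def build_fingerprint(spec_pos: MassSpectrum, spec_neg: MassSpectrum,
                      min_rel_abund: float = DEFAULT_MIN_REL_ABUND,
                      detection_threshold: float = 0.0) -> AdductFingerprint:
    """Merge a positive and a negative averaged spectrum into a fingerprint.

    The base peak is the most intense positive bin, falling back to the
    negative spectrum only when the positive one is empty; relative
    abundances are % of the base peak and ions below ``min_rel_abund``
    are dropped (the base peak itself is always retained).
    """
    pos_ok = not spec_pos.is_empty and spec_pos.intensity.max() > detection_threshold
    neg_ok = not spec_neg.is_empty and spec_neg.intensity.max() > detection_threshold
    if not pos_ok and not neg_ok:
        raise ValueError("both spectra are empty: nothing to fingerprint")
    base_spec, base_pol = (spec_pos, "positive") if pos_ok else (spec_neg, "negative")
    base_mz, base_int = base_spec.base_peak()

    ions: list[FingerprintIon] = []
    for spec, pol, ok in ((spec_pos, "positive", pos_ok),
                          (spec_neg, "negative", neg_ok)):
        if not ok:
            continue
        for mz, inten in zip(spec.mz, spec.intensity):
            rel = min(100.0 * (float(inten) / base_int), 100.0)
            if rel >= min_rel_abund or (int(mz) == base_mz and pol == base_pol):
                ions.append(FingerprintIon(int(mz), rel, pol))
    return AdductFingerprint(base_peak_mz=base_mz, base_polarity=base_pol,
                             ions=ions, has_positive_signal=pos_ok,
                             has_negative_signal=neg_ok, rt=base_spec.rt)


def _na_pair(pos_ions: Sequence[FingerprintIon]) -> tuple[FingerprintIon, FingerprintIon] | None:
    """The (protonated, sodiated) ion pair spaced 22 Da, if present."""
    by_mz = {i.mz: i for i in pos_ions}
    for i in pos_ions:
        if i.mz + NA_H_SPACING in by_mz:
            return i, by_mz[i.mz + NA_H_SPACING]
    return None


def classify_family(fp: AdductFingerprint) -> FamilyCall:
    """Assign a phenol family and infer the nominal molecular weight."""
    pos = fp.ions_for("positive")

    pair = _na_pair(pos)
    if pair is not None:
        h_ion, na_ion = pair
        mw = na_ion.mz - SODIUM
        if na_ion.relative_abundance == 100:
            lo, hi = H_ADDUCT_WINDOW
            if lo <= h_ion.relative_abundance <= hi:
                return FamilyCall("bibenzyl", mw, ["na_base_with_h_partner"])
        elif na_ion.relative_abundance >= H_ADDUCT_WINDOW[0]:
            # protonated base peak with a substantial sodium adduct
            return FamilyCall("bibenzyl", mw, ["h_base_with_na_partner"])

    if fp.has_negative_signal:
        neg = fp.ions_for("negative")
        neg_max = max((i.relative_abundance for i in neg), default=0.0)
        pos_max = max((i.relative_abundance for i in pos), default=0.0)
        if neg and neg_max > pos_max:
            neg_base = max(neg, key=lambda i: i.relative_abundance)
            return FamilyCall("flavone", neg_base.mz + PROTON,
                              ["negative_dominant"])

    if pos and not fp.has_negative_signal and pair is None:
        base = max(pos, key=lambda i: i.relative_abundance)
        if len(pos) == 2:
            spacing = abs(pos[1].mz - pos[0].mz)
            if spacing in PHENANTHRENE_LOSSES:
                return FamilyCall("phenanthrene", base.mz - PROTON,
                                  [f"neutral_loss_{spacing}"])
        if len(pos) == 1:
            return FamilyCall("coumarin", base.mz - PROTON, ["single_positive_ion"])

    return FamilyCall("unknown", None, ["no_rule_matched"])


#: designated family surrogate standards for newly elucidated compounds
_FAMILY_SURROGATES = {"flavone": "NA", "phenanthrene": "MON", "coumarin": "COM"}
_GIGANTOL_MW = 274


def _surrogate_for(call: FamilyCall) -> str:
    if call.family == "bibenzyl":
        # nearest-mass family standard: gigantol for its own MW, erianin otherwise
        return "GI" if call.inferred_mw == _GIGANTOL_MW else "ER"
    return _FAMILY_SURROGATES[call.family]


def identify_compound(peak: Peak, fp: AdductFingerprint, call: FamilyCall,
                      library: Sequence[CompoundRecord],
                      rt_tol: float = DEFAULT_RT_TOL,
                      mz_tol: float = DEFAULT_MZ_TOL) -> Identification:
    """Match a classified peak against the reference-standard library.

    A known standard requires both a retention-time and a base-ion match;
    otherwise a classified family yields a newly elucidated compound
    quantified against its family surrogate, and an unknown family is
    left unidentified.
    """
    if not library:
        raise ValueError("empty library")
    for rec in library:
        rec_base = rec.base_ion
        if (abs(peak.apex_rt - rec.rt) <= rt_tol
                and abs(fp.base_peak_mz - rec_base.mz) <= mz_tol
                and fp.base_polarity == rec_base.polarity):
            return Identification(compound=rec.code, status="known_standard",
                                  matched_rt=rec.rt,
                                  surrogate_standard=rec.surrogate,
                                  sim_ion=rec.sim_mz, sim_polarity=rec.sim_polarity)
    if call.family != "unknown":
        if call.family == "bibenzyl":
            # prefer the sodium adduct for SIM even when [M+H]+ is the base
            na_mz = call.inferred_mw + SODIUM
            sim_ion = na_mz if any(i.mz == na_mz for i in fp.ions_for("positive")) \
                else fp.most_intense("positive").mz
            sim_pol = "positive"
        elif call.family == "flavone":
            sim_ion = fp.most_intense("negative").mz
            sim_pol = "negative"
        else:
            sim_ion = fp.most_intense("positive").mz
            sim_pol = "positive"
        return Identification(compound="unknown", status="newly_elucidated",
                              matched_rt=peak.apex_rt,
                              surrogate_standard=_surrogate_for(call),
                              sim_ion=sim_ion, sim_polarity=sim_pol)
    return Identification(compound="unknown", status="unidentified",
                          matched_rt=peak.apex_rt, surrogate_standard=None,
                          sim_ion=None, sim_polarity=None)


@dataclass
class ScreeningHit:
    peak: Peak
    fingerprint: AdductFingerprint
    call: FamilyCall
    identification: Identification


def screen_run(run: RawRun, library: Sequence[CompoundRecord],
               min_snr: float = 3.0, rt_tol: float = DEFAULT_RT_TOL,
               mz_tol: float = DEFAULT_MZ_TOL,
               min_rel_abund: float = DEFAULT_MIN_REL_ABUND) -> list[ScreeningHit]:
    """Full-scan screening of one run: detect peaks on both TICs, average
    spectra at each peak, fingerprint, classify and identify."""
    from .signal import detect_peaks, total_ion_chromatogram

    peaks: list[Peak] = []
    for pol in ("positive", "negative"):
        for p in detect_peaks(total_ion_chromatogram(run, pol), min_snr=min_snr):
            if all(abs(p.apex_rt - q.apex_rt) > rt_tol for q in peaks):
                peaks.append(p)
    hits = []
    for p in sorted(peaks, key=lambda q: q.apex_rt):
        window = (p.start_rt, p.end_rt)
        spec_pos = average_spectrum(run, window, "positive")
        spec_neg = average_spectrum(run, window, "negative")
        try:
            fp = build_fingerprint(spec_pos, spec_neg, min_rel_abund)
        except ValueError:
            continue
        fp.rt = p.apex_rt
        call = classify_family(fp)
        ident = identify_compound(p, fp, call, library, rt_tol, mz_tol)
        hits.append(ScreeningHit(p, fp, call, ident))
    return hits


def write_screening_report(hits: Sequence[ScreeningHit], path) -> None:
    """CSV report: one row per screened peak."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rt_min", "base_mz", "base_polarity", "ions",
                    "positive_signal", "negative_signal", "family",
                    "inferred_mw", "compound", "status", "surrogate",
                    "sim_ion", "sim_polarity"])
        for h in hits:
            sign = {"positive": "+", "negative": "-"}
            ions = ";".join(f"{i.mz}{sign[i.polarity]}:{i.relative_abundance:.0f}"
                            for i in h.fingerprint.ions)
            w.writerow([f"{h.peak.apex_rt:.2f}", h.fingerprint.base_peak_mz,
                        h.fingerprint.base_polarity, ions,
                        int(h.fingerprint.has_positive_signal),
                        int(h.fingerprint.has_negative_signal),
                        h.call.family, h.call.inferred_mw or "",
                        h.identification.compound, h.identification.status,
                        h.identification.surrogate_standard or "",
                        h.identification.sim_ion or "",
                        h.identification.sim_polarity or ""])
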