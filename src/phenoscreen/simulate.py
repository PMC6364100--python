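"""Synthetic single-quadrupole LC-MS runs with known ground truth.

The instrument model emulates a UPLC coupled to a miniature mass detector:
alternating positive/negative full scans over 50-400 Da at unit mass
resolution, plus SIM traces on the quantification channels.  Each analyte
elutes as a Gaussian of width ``peak_sigma`` centred at its library
retention time; its ions are spread over nominal 1-Da bins according to
the adduct fingerprint's relative abundances, and the SIM trace is scaled
so that the integrated area follows the affine response model

    area = response_factor * concentration + area_intercept

with concentration in ug/mL of the injected extract.  Sample content
(mg/kg of dry sample) maps to extract concentration through the
matrix-solid-phase-dispersion constants:

    concentration = content * recovery_factor * sample_mass / elution_volume

(0.5 g of sample eluted into 10 mL by default, i.e. content = 20 x conc).
Baseline noise is i.i.d. Gaussian, clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .library import CompoundRecord, get_compound, make_compound_library
from .datasets import load_calibration_constants
from .spectra import Chromatogram, MassSpectrum, RawRun, ScanCycle, SimChannel

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "CalibrationRun",
    "SpikedBatch",
    "UnknownCompoundError",
    "extract_concentration",
    "default_response_factors",
    "simulate_run",
    "simulate_calibration_series",
    "simulate_spiked_batch",
    "gaussian_height_per_area",
]

SCAN_RANGE = (50, 400)           # Da
#: relative abundance assigned to the [M-H]- ion of compounds that show a
#: negative-mode signal but whose published fingerprint lists no negative ion
NEGATIVE_SIGNAL_ABUNDANCE = 30.0


class UnknownCompoundError(KeyError):
    """A scenario references a compound absent from the library."""


def gaussian_height_per_area(sigma: float) -> float:
    """Peak height per unit area for a Gaussian of width ``sigma`` (1/min)."""
    return 1.0 / (sigma * math.sqrt(2.0 * math.pi))


def extract_concentration(content: float, recovery: float,
                          sample_mass: float, elution_volume: float) -> float:
    """Extract concentration (ug/mL) from dry-sample content (mg/kg)."""
    return content * recovery * sample_mass / elution_volume


@dataclass
class ScenarioConfig:
    """Ground-truth description of one simulated measurement scenario.

    Parameters
    ----------
    compounds
        Map compound code -> true content in mg/kg of dry sample.
    response_factor
        Map code -> SIM area counts per (ug/mL); defaults to each
        compound's quantifying standard's published calibration slope.
    area_intercept
        Additive area offset (counts*min) of the affine response model;
        scalar or per-compound map.  Default 0.
    peak_sigma
        Gaussian elution width sigma, min.
    noise_level
        Baseline noise SD in counts; scalar (applied to full scans and
        every SIM trace) or per-compound map (applied to SIM traces only;
        a shared channel receives the largest of its members' values).
    recovery_factor
        Fraction of analyte surviving extraction, scalar or map, in [0, 1].
    sample_mass, elution_volume
        Extraction constants (g, mL); defaults 0.5 g into 10 mL.
    cycle_period, run_length
        Full-scan cycle spacing and run duration, min.
    seed
        Seed for all stochastic draws.
    """

    compounds: dict[str, float]
    response_factor: dict[str, float] | None = None
    area_intercept: float | Mapping[str, float] = 0.0
    peak_sigma: float = 0.05
    noise_level: float | Mapping[str, float] = 0.0
    recovery_factor: float | Mapping[str, float] = 1.0
    sample_mass: float = 0.5
    elution_volume: float = 10.0
    cycle_period: float = 0.05
    run_length: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_mass <= 0 or self.elution_volume <= 0:
            raise ValueError("sample_mass and elution_volume must be positive")
        if self.peak_sigma <= 0 or self.cycle_period <= 0:
            raise ValueError("peak_sigma and cycle_period must be positive")
        for v in self._values(self.noise_level):
            if v < 0:
                raise ValueError("noise_level must be >= 0")
        for v in self._values(self.recovery_factor):
            if not (0.0 <= v <= 1.0):
                raise ValueError("recovery_factor must lie in [0, 1]")
        if self.response_factor is not None:
            for v in self.response_factor.values():
                if v <= 0:
                    raise ValueError("response_factor must be positive")
        for v in self.compounds.values():
            if v < 0:
                raise ValueError("content must be >= 0")

    @staticmethod
    def _values(x):
        return x.values() if isinstance(x, Mapping) else [x]

    def per_compound(self, attr: str, code: str, default=None):
        val = getattr(self, attr)
        if isinstance(val, Mapping):
            return val.get(code, 0.0 if default is None else default)
        return val

    def recovery(self, code: str) -> float:
        return self.per_compound("recovery_factor", code, 1.0)

    def noise(self, code: str) -> float:
        return self.per_compound("noise_level", code, 0.0)


@dataclass
class TrueSignal:
    """Ground truth for one compound in one simulated run."""

    content: float        # mg/kg dry sample
    concentration: float  # ug/mL in the injected extract
    area: float           # counts*min on the SIM channel
    channel: SimChannel


@dataclass
class GroundTruth:
    signals: dict[str, TrueSignal] = field(default_factory=dict)

    def area(self, code: str) -> float:
        return self.signals[code].area

    def concentration(self, code: str) -> float:
        return self.signals[code].concentration

    def content(self, code: str) -> float:
        return self.signals[code].content


def default_response_factors(library: Sequence[CompoundRecord] | None = None
                             ) -> dict[str, float]:
    """Each compound responds like its quantifying standard (the working
    assumption behind surrogate quantification)."""
    library = library if library is not None else make_compound_library()
    slopes = load_calibration_constants()["slope"]
    return {rec.code: float(slopes[rec.surrogate]) for rec in library}


def _gaussian(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _simulate_from_concentrations(conc: Mapping[str, float],
                                  scenario: ScenarioConfig,
                                  library: Sequence[CompoundRecord],
                                  rng: np.random.Generator) -> tuple[RawRun, GroundTruth]:
    """Core instrument model; ``conc`` maps code -> extract ug/mL."""
    rf = scenario.response_factor or default_response_factors(library)
    sigma = scenario.peak_sigma
    hpa = gaussian_height_per_area(sigma)
    t = np.arange(0.0, scenario.run_length + 1e-9, scenario.cycle_period)
    lo, hi = SCAN_RANGE
    nbins = hi - lo + 1

    full = {"positive": np.zeros((len(t), nbins)),
            "negative": np.zeros((len(t), nbins))}
    truth = GroundTruth()
    profiles: dict[str, np.ndarray] = {}

    for code, c in conc.items():
        try:
            rec = get_compound(library, code)
        except KeyError as e:
            raise UnknownCompoundError(code) from e
        if code not in rf:
            raise UnknownCompoundError(f"no response factor for {code}")
        intercept = scenario.per_compound("area_intercept", code, 0.0)
        area = max(rf[code] * c + intercept, 0.0) if c > 0 else 0.0
        amp = area * hpa
        profile = amp * _gaussian(t, rec.rt, sigma)
        profiles[code] = profile
        channel = SimChannel(rec.sim_mz, rec.sim_polarity, rec.sim_window)
        truth.signals[code] = TrueSignal(content=float("nan"), concentration=c,
                                         area=area, channel=channel)
        # spread the elution profile over the fingerprint's m/z bins
        for ion in rec.ions:
            if lo <= ion.mz <= hi:
                full[ion.polarity][:, ion.mz - lo] += profile * ion.relative_abundance / 100.0
        if rec.has_negative_signal and not rec.ions_for("negative"):
            neg_mz = rec.mw - 1
            if lo <= neg_mz <= hi:
                full["negative"][:, neg_mz - lo] += profile * NEGATIVE_SIGNAL_ABUNDANCE / 100.0

    scalar_noise = scenario.noise_level if not isinstance(scenario.noise_level, Mapping) else 0.0
    if scalar_noise > 0:
        for pol in full:
            full[pol] = np.clip(full[pol] + rng.normal(0.0, scalar_noise, full[pol].shape), 0.0, None)

    mz_axis = np.arange(lo, hi + 1)
    cycles = []
    for i, rt in enumerate(t):
        specs = {}
        for pol in ("positive", "negative"):
            row = full[pol][i]
            nz = np.nonzero(row > 0)[0]
            specs[pol] = MassSpectrum(pol, mz_axis[nz], row[nz], float(rt))
        cycles.append(ScanCycle(float(rt), specs["positive"], specs["negative"]))

    # SIM traces are acquired on every method channel, eluting analyte or not
    sim_traces: dict[SimChannel, Chromatogram] = {}
    for channel in sorted({SimChannel(r.sim_mz, r.sim_polarity, r.sim_window)
                           for r in library},
                          key=lambda ch: (ch.window, ch.mz, ch.polarity)):
        mask = (t >= channel.window[0]) & (t <= channel.window[1])
        if not mask.any():
            continue  # window entirely outside the simulated run
        trace = np.zeros(int(mask.sum()))
        members = [r for r in library
                   if SimChannel(r.sim_mz, r.sim_polarity, r.sim_window) == channel]
        for r in members:
            if r.code in profiles:
                trace = trace + profiles[r.code][mask]
        noise = max((scenario.noise(r.code) for r in members), default=0.0)
        if noise > 0:
            trace = trace + rng.normal(0.0, noise, trace.shape)
        sim_traces[channel] = Chromatogram(t[mask], np.clip(trace, 0.0, None),
                                           channel.label)

    run = RawRun(cycles, sim_traces,
                 metadata={"scan_range": SCAN_RANGE,
                           "cycle_period": scenario.cycle_period,
                           "peak_sigma": sigma,
                           "source": {"ionisation": "ESI", "resolution": "unit"}})
    return run, truth


def simulate_run(scenario: ScenarioConfig,
                 library: Sequence[CompoundRecord] | None = None,
                 rng: np.random.Generator | None = None) -> tuple[RawRun, GroundTruth]:
    """Simulate one injection of an extracted sample.

    Returns the raw run plus per-compound ground truth (true content,
    extract concentration and SIM area).
    """
    library = library if library is not None else make_compound_library()
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    conc = {code: extract_concentration(content, scenario.recovery(code),
                                        scenario.sample_mass, scenario.elution_volume)
            for code, content in scenario.compounds.items()}
    run, truth = _simulate_from_concentrations(conc, scenario, library, rng)
    for code, content in scenario.compounds.items():
        truth.signals[code].content = content
    return run, truth


@dataclass
class CalibrationRun:
    level: float            # standard concentration, ug/mL
    replicate: int
    run: RawRun
    true_area: float


def simulate_calibration_series(compound: str,
                                levels: Sequence[float],
                                scenario: ScenarioConfig,
                                n_replicates: int = 3,
                                library: Sequence[CompoundRecord] | None = None
                                ) -> list[CalibrationRun]:
    """Simulate injections of a standard dilution series.

    Standards are injected directly (no extraction step), so each level is
    the extract concentration itself.  One run per level per replicate.
    """
    if len(levels) == 0:
        raise ValueError("empty calibration series")
    arr = np.asarray(levels, dtype=float)
    if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
        raise ValueError("levels must be positive and strictly increasing")
    library = library if library is not None else make_compound_library()
    get_compound(library, compound)  # raises early for unknown compounds
    rng = np.random.default_rng(scenario.seed)
    out = []
    for level in arr:
        for rep in range(n_replicates):
            run, truth = _simulate_from_concentrations(
                {compound: float(level)}, scenario, library, rng)
            out.append(CalibrationRun(float(level), rep, run, truth.area(compound)))
    return out


@dataclass
class SpikedBatch:
    """Fortified-sample batch: replicate spiked runs with paired blanks."""

    spike_level: float                 # mg/kg added
    endogenous: dict[str, float]      # mg/kg present before spiking
    true_recovery: dict[str, float]
    spiked: list[tuple[RawRun, GroundTruth]]
    blanks: list[tuple[RawRun, GroundTruth]]


def simulate_spiked_batch(endogenous: Mapping[str, float],
                          spike_level: float,
                          n_replicates: int = 5,
                          recovery_true: float | Mapping[str, float] = 1.0,
                          noise: float | Mapping[str, float] = 0.0,
                          seed: int = 0,
                          scenario: ScenarioConfig | None = None,
                          library: Sequence[CompoundRecord] | None = None) -> SpikedBatch:
    """Simulate a spike-recovery experiment at one fortification level.

    The measured content of a spiked replicate is
    ``endogenous + recovery_true * spike_level``: the spike passes through
    extraction with efficiency ``recovery_true`` while the endogenous level
    is taken as the already-measured (post-extraction) value.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if spike_level <= 0:
        raise ValueError("spike_level must be positive")
    library = library if library is not None else make_compound_library()
    base = scenario if scenario is not None else ScenarioConfig(compounds={}, seed=seed)

    def rec_of(code):
        if isinstance(recovery_true, Mapping):
            return recovery_true.get(code, 1.0)
        return recovery_true

    codes = list(endogenous)
    spiked_contents = {c: endogenous[c] + rec_of(c) * spike_level for c in codes}
    blank_contents = dict(endogenous)
    spiked, blanks = [], []
    for rep in range(n_replicates):
        for tag, (contents, sink) in enumerate(
                ((spiked_contents, spiked), (blank_contents, blanks))):
            sc = replace(base, compounds=dict(contents), noise_level=noise,
                         recovery_factor=1.0, seed=seed)
            rng = np.random.default_rng([seed, rep, tag])
            sink.append(simulate_run(sc, library, rng=rng))
    return SpikedBatch(spike_level=float(spike_level),
                       endogenous=dict(endogenous),
                       true_recovery={c: rec_of(c) for c in codes},
                       spiked=spiked, blanks=blanks)
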