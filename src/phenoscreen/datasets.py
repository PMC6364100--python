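"""Loaders for the small constant tables shipped with the package.

These are the published method constants: calibration-line parameters for
the nine reference standards, the spike-recovery design, and the measured
per-sample phenol contents of four *Dendrobium chrysotoxum* samples.  They
parameterise the simulator and serve as fixtures for validation studies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_calibration_constants",
    "load_recovery_design",
    "load_sample_contents",
]


def _read(name: str, **kw) -> pd.DataFrame:
    # keep_default_na=False so the compound code "NA" (naringenin) survives;
    # only genuinely empty cells become NaN
    with resources.as_file(resources.files("phenoscreen.data") / name) as p:
        return pd.read_csv(p, comment="#", keep_default_na=False,
                           na_values=[""], **kw)


def load_calibration_constants() -> pd.DataFrame:
    """Published calibration lines (slope, intercept, R^2, LOD/LOQ, range),
    indexed by standard code."""
    return _read("calibration_curves.csv", index_col="code")


def load_recovery_design() -> pd.DataFrame:
    """Published spike-recovery design: endogenous content and recovery/RSD
    at the 50 and 200 mg/kg fortification levels, indexed by compound code."""
    return _read("recovery_design.csv", index_col="code")


def load_sample_contents() -> pd.DataFrame:
    """Published per-sample contents (mg/kg dry sample) of the four samples;
    NaN marks 'not found / below quantification'."""
    return _read("sample_contents.csv", index_col="sample")
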