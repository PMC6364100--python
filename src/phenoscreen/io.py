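"""Serialization: CSV long format, a minimal mzML subset, configs.

The plain CSV long format (one row per recorded point: record kind, rt,
polarity, m/z, intensity, SIM window) is the package's fixture format and
round-trips a :class:`~phenoscreen.spectra.RawRun` exactly.

The mzML writer/reader covers the subset this instrument model needs —
centroided unit-resolution spectra with per-spectrum polarity and scan
start time, plus SIM traces as chromatograms — using uncompressed 64-bit
little-endian binary arrays.  It is a self-contained implementation
(no mzML library is required at run time) and reads back only files it
wrote itself or files restricted to the same subset.
"""

from __future__ import annotations

import base64
import csv
import struct
from typing import Mapping
from xml.etree import ElementTree as ET

import numpy as np
import yaml

from .simulate import GroundTruth, ScenarioConfig
from .spectra import Chromatogram, MassSpectrum, RawRun, ScanCycle, SimChannel

__all__ = [
    "run_to_csv", "run_from_csv",
    "run_to_mzml", "run_from_mzml",
    "chromatogram_to_csv", "chromatogram_from_csv",
    "save_scenario", "load_scenario",
    "ground_truth_to_csv",
]


# ---------------------------------------------------------------- CSV long

def run_to_csv(run: RawRun, path) -> None:
    """One row per point: (record, rt, polarity, mz, intensity, window)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record", "rt_min", "polarity", "mz", "intensity",
                    "window_start_min", "window_stop_min"])
        for c in run.cycles:
            for spec in (c.positive, c.negative):
                if len(spec.mz) == 0:
                    w.writerow(["scan", repr(c.rt), spec.polarity, "", "", "", ""])
                for mz, inten in zip(spec.mz, spec.intensity):
                    w.writerow(["scan", repr(c.rt), spec.polarity,
                                int(mz), repr(float(inten)), "", ""])
        for ch, trace in run.sim_traces.items():
            for rt, inten in zip(trace.rt, trace.intensity):
                w.writerow(["sim", repr(float(rt)), ch.polarity, ch.mz,
                            repr(float(inten)),
                            repr(ch.window[0]), repr(ch.window[1])])


def run_from_csv(path, metadata: dict | None = None) -> RawRun:
    cycles: dict[float, dict[str, list]] = {}
    sims: dict[SimChannel, list] = {}
    with open(path, newline="") as fh:
        for r in csv.DictReader(fh):
            rt = float(r["rt_min"])
            if r["record"] == "scan":
                slot = cycles.setdefault(rt, {"positive": [], "negative": []})
                if r["mz"] != "":
                    slot[r["polarity"]].append((int(r["mz"]), float(r["intensity"])))
            else:
                ch = SimChannel(int(r["mz"]), r["polarity"],
                                (float(r["window_start_min"]),
                                 float(r["window_stop_min"])))
                sims.setdefault(ch, []).append((rt, float(r["intensity"])))
    cycle_objs = []
    for rt in sorted(cycles):
        specs = {}
        for pol in ("positive", "negative"):
            pts = sorted(cycles[rt][pol])
            specs[pol] = MassSpectrum(pol, [p[0] for p in pts],
                                      [p[1] for p in pts], rt)
        cycle_objs.append(ScanCycle(rt, specs["positive"], specs["negative"]))
    traces = {}
    for ch, pts in sims.items():
        pts.sort()
        traces[ch] = Chromatogram([p[0] for p in pts], [p[1] for p in pts],
                                  ch.label)
    return RawRun(cycle_objs, traces, metadata or {"scan_range": (50, 400)})


# ------------------------------------------------------------------- mzML

_CV = {
    "positive": ("MS:1000130", "positive scan"),
    "negative": ("MS:1000129", "negative scan"),
}


def _encode(values) -> str:
    arr = np.asarray(values, dtype="<f8")
    return base64.b64encode(arr.tobytes()).decode("ascii")


def _decode(text: str) -> np.ndarray:
    raw = base64.b64decode(text)
    return np.frombuffer(raw, dtype="<f8").copy()


def _cv(parent, accession, name, value=None, unit=None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name,
             "value": "" if value is None else str(value)}
    if unit:
        attrs.update({"unitCvRef": "UO", "unitAccession": unit[0],
                      "unitName": unit[1]})
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent, values, accession, name) -> None:
    bda = ET.SubElement(parent, "binaryDataArray")
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    _cv(bda, accession, name)
    ET.SubElement(bda, "binary").text = _encode(values)


def run_to_mzml(run: RawRun, path) -> None:
    """Write the run as a centroided dual-polarity mzML file."""
    root = ET.Element("mzML", {"xmlns": "http://psi.hupo.org/ms/mzml",
                               "version": "1.1.0"})
    mzml_run = ET.SubElement(root, "run", {"id": "run1"})
    spec_list = ET.SubElement(mzml_run, "spectrumList",
                              {"count": str(2 * len(run.cycles))})
    idx = 0
    for c in run.cycles:
        for spec in (c.positive, c.negative):
            el = ET.SubElement(spec_list, "spectrum",
                               {"index": str(idx), "id": f"scan={idx}",
                                "defaultArrayLength": str(len(spec.mz))})
            idx += 1
            _cv(el, "MS:1000579", "MS1 spectrum")
            _cv(el, "MS:1000127", "centroid spectrum")
            _cv(el, *_CV[spec.polarity])
            scans = ET.SubElement(el, "scanList", {"count": "1"})
            scan = ET.SubElement(scans, "scan")
            _cv(scan, "MS:1000016", "scan start time", value=repr(c.rt),
                unit=("UO:0000031", "minute"))
            arrays = ET.SubElement(el, "binaryDataArrayList", {"count": "2"})
            _binary_array(arrays, spec.mz, "MS:1000514", "m/z array")
            _binary_array(arrays, spec.intensity, "MS:1000515", "intensity array")
    chrom_list = ET.SubElement(mzml_run, "chromatogramList",
                               {"count": str(len(run.sim_traces))})
    for i, (ch, trace) in enumerate(run.sim_traces.items()):
        el = ET.SubElement(chrom_list, "chromatogram",
                           {"index": str(i), "id": f"SIM_{ch.mz}_{ch.polarity}",
                            "defaultArrayLength": str(len(trace))})
        _cv(el, "MS:1000627", "selected ion current chromatogram")
        _cv(el, *_CV[ch.polarity])
        for name, val in (("sim_mz", ch.mz), ("window_start", ch.window[0]),
                          ("window_stop", ch.window[1])):
            ET.SubElement(el, "userParam", {"name": name, "value": repr(val)})
        arrays = ET.SubElement(el, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, trace.rt, "MS:1000595", "time array")
        _binary_array(arrays, trace.intensity, "MS:1000515", "intensity array")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _params(el) -> dict:
    out = {}
    for p in el:
        if _strip_ns(p.tag) == "cvParam":
            out[p.get("accession")] = p.get("value", "")
        elif _strip_ns(p.tag) == "userParam":
            out[p.get("name")] = p.get("value", "")
    return out


def _read_arrays(el) -> dict[str, np.ndarray]:
    arrays = {}
    for bda in el.iter():
        if _strip_ns(bda.tag) != "binaryDataArray":
            continue
        params = _params(bda)
        binary = next(b for b in bda if _strip_ns(b.tag) == "binary")
        values = _decode(binary.text or "")
        if "MS:1000514" in params:
            arrays["mz"] = values
        elif "MS:1000595" in params:
            arrays["time"] = values
        elif "MS:1000515" in params:
            arrays["intensity"] = values
    return arrays


def run_from_mzml(path, metadata: dict | None = None) -> RawRun:
    root = ET.parse(path).getroot()
    cycles: dict[float, dict[str, MassSpectrum]] = {}
    traces: dict[SimChannel, Chromatogram] = {}
    for el in root.iter():
        tag = _strip_ns(el.tag)
        if tag == "spectrum":
            params = _params(el)
            polarity = "positive" if "MS:1000130" in params else "negative"
            rt = None
            for scan in el.iter():
                if _strip_ns(scan.tag) == "scan":
                    rt = float(_params(scan)["MS:1000016"])
            arrays = _read_arrays(el)
            spec = MassSpectrum(polarity, arrays.get("mz", []),
                                arrays.get("intensity", []), rt)
            cycles.setdefault(rt, {})[polarity] = spec
        elif tag == "chromatogram":
            params = _params(el)
            polarity = "positive" if "MS:1000130" in params else "negative"
            ch = SimChannel(int(float(params["sim_mz"])), polarity,
                            (float(params["window_start"]),
                             float(params["window_stop"])))
            arrays = _read_arrays(el)
            traces[ch] = Chromatogram(arrays["time"], arrays["intensity"],
                                      ch.label)
    cycle_objs = [
        ScanCycle(rt,
                  cycles[rt].get("positive", MassSpectrum("positive", [], [], rt)),
                  cycles[rt].get("negative", MassSpectrum("negative", [], [], rt)))
        for rt in sorted(cycles)
    ]
    return RawRun(cycle_objs, traces, metadata or {"scan_range": (50, 400)})


# ----------------------------------------------------------- chromatograms

def chromatogram_to_csv(chrom: Chromatogram, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# channel: {chrom.channel}\n")
        w = csv.writer(fh)
        w.writerow(["rt_min", "intensity"])
        for rt, inten in zip(chrom.rt, chrom.intensity):
            w.writerow([repr(float(rt)), repr(float(inten))])


def chromatogram_from_csv(path) -> Chromatogram:
    with open(path, newline="") as fh:
        first = fh.readline()
        channel = first.split(":", 1)[1].strip() if first.startswith("#") else ""
        if not first.startswith("#"):
            fh.seek(0)
        rows = list(csv.DictReader(fh))
    return Chromatogram([float(r["rt_min"]) for r in rows],
                        [float(r["intensity"]) for r in rows], channel)


# ---------------------------------------------------------------- configs

def save_scenario(scenario: ScenarioConfig, path) -> None:
    """Flat YAML mapping of the scenario parameters."""
    data = {
        "compounds": dict(scenario.compounds),
        "response_factor": scenario.response_factor,
        "area_intercept": scenario.area_intercept
        if not isinstance(scenario.area_intercept, Mapping)
        else dict(scenario.area_intercept),
        "peak_sigma": scenario.peak_sigma,
        "noise_level": scenario.noise_level
        if not isinstance(scenario.noise_level, Mapping)
        else dict(scenario.noise_level),
        "recovery_factor": scenario.recovery_factor
        if not isinstance(scenario.recovery_factor, Mapping)
        else dict(scenario.recovery_factor),
        "sample_mass": scenario.sample_mass,
        "elution_volume": scenario.elution_volume,
        "cycle_period": scenario.cycle_period,
        "run_length": scenario.run_length,
        "seed": scenario.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScenarioConfig(**data)


def ground_truth_to_csv(truth: GroundTruth, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound", "content_mg_kg", "concentration_ug_ml",
                    "area", "sim_mz", "sim_polarity"])
        for code, sig in truth.signals.items():
            w.writerow([code, repr(sig.content), repr(sig.concentration),
                        repr(sig.area), sig.channel.mz, sig.channel.polarity])
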