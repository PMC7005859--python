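"""File formats: mzML, spectral-library TSV, report tables, run manifests.

mzML support is a small lxml-based writer/reader pair for centroided spectra:
base64 little-endian float arrays (zlib-compressed input also accepted on
read), MS2 scans carrying isolation window target and offsets, scan start
times normalized to seconds. All tabular interchange is UTF-8 tab-separated
text that round-trips bit-exactly through pandas.
"""

from __future__ import annotations

import base64
import logging
import os
import struct
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lxml import etree

from .dia_extraction import IsolationWindow, SpectrumRecord
from .peptide_model import ModifiedPeptide, SiteCandidate, theoretical_fragments

logger = logging.getLogger("phosphodia")

__all__ = [
    "write_mzml", "read_mzml", "read_spectral_library", "write_spectral_library",
    "write_report", "read_report", "RunManifest",
]

_NS = "http://psi.hupo.org/ms/mzml"

LIBRARY_COLUMNS = ("precursor_mz", "modified_sequence", "charge", "fragment_series",
                   "fragment_index", "fragment_charge", "fragment_mz",
                   "relative_intensity", "rt")

REPORT_LEVELS = ("precursor", "peptide", "site", "occupancy")


def _encode(array: np.ndarray) -> str:
    data = struct.pack(f"<{len(array)}d", *np.asarray(array, dtype=float))
    return base64.b64encode(data).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "",
        unit: tuple[str, str, str] | None = None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit:
        attrs.update(unitCvRef=unit[0], unitAccession=unit[1], unitName=unit[2])
    etree.SubElement(parent, f"{{{_NS}}}cvParam", **attrs)


def write_mzml(run: list[SpectrumRecord], path: str | os.PathLike) -> None:
    """Write a centroided run as minimal valid mzML (indexless)."""
    root = etree.Element(f"{{{_NS}}}mzML", nsmap={None: _NS}, version="1.1.0")
    cv_list = etree.SubElement(root, f"{{{_NS}}}cvList", count="2")
    etree.SubElement(cv_list, f"{{{_NS}}}cv", id="MS", fullName="PSI-MS",
                     URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    etree.SubElement(cv_list, f"{{{_NS}}}cv", id="UO", fullName="Unit Ontology",
                     URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo")
    run_el = etree.SubElement(root, f"{{{_NS}}}run", id="run")
    spec_list = etree.SubElement(run_el, f"{{{_NS}}}spectrumList",
                                 count=str(len(run)))
    for i, scan in enumerate(run):
        spec = etree.SubElement(spec_list, f"{{{_NS}}}spectrum", index=str(i),
                                id=f"scan={i + 1}",
                                defaultArrayLength=str(scan.mz.size))
        _cv(spec, "MS:1000511", "ms level", str(scan.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(spec, f"{{{_NS}}}scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = etree.SubElement(scan_list, f"{{{_NS}}}scan")
        _cv(scan_el, "MS:1000016", "scan start time", f"{scan.rt:.6f}",
            ("UO", "UO:0000010", "second"))
        if scan.ms_level == 2 and scan.window is not None:
            w = scan.window
            plist = etree.SubElement(spec, f"{{{_NS}}}precursorList", count="1")
            prec = etree.SubElement(plist, f"{{{_NS}}}precursor")
            iso = etree.SubElement(prec, f"{{{_NS}}}isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z",
                f"{w.center:.6f}", ("MS", "MS:1000040", "m/z"))
            _cv(iso, "MS:1000828", "isolation window lower offset",
                f"{w.width / 2:.6f}", ("MS", "MS:1000040", "m/z"))
            _cv(iso, "MS:1000829", "isolation window upper offset",
                f"{w.width / 2:.6f}", ("MS", "MS:1000040", "m/z"))
            etree.SubElement(prec, f"{{{_NS}}}selectedIonList", count="0")
            act = etree.SubElement(prec, f"{{{_NS}}}activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        arr_list = etree.SubElement(spec, f"{{{_NS}}}binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
                (scan.mz, "MS:1000514", "m/z array", ("MS", "MS:1000040", "m/z")),
                (scan.intensity, "MS:1000515", "intensity array",
                 ("MS", "MS:1000131", "number of detector counts"))):
            encoded = _encode(arr)
            bda = etree.SubElement(arr_list, f"{{{_NS}}}binaryDataArray",
                                   encodedLength=str(len(encoded)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name, unit=unit)
            etree.SubElement(bda, f"{{{_NS}}}binary").text = encoded
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


def _cv_params(element) -> dict[str, str]:
    return {cv.get("accession"): cv.get("value", "")
            for cv in element.iter(f"{{{_NS}}}cvParam")}


def _decode_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    text = bda.findtext(f"{{{_NS}}}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | os.PathLike) -> list[SpectrumRecord]:
    """Read a centroided mzML file into SpectrumRecords (rt in seconds)."""
    run: list[SpectrumRecord] = []
    window_cache: dict[tuple[float, float], IsolationWindow] = {}
    tree = etree.parse(str(path))
    for spec in tree.iter(f"{{{_NS}}}spectrum"):
        params = _cv_params(spec)
        ms_level = int(params.get("MS:1000511", "1"))
        rt_seconds = 0.0
        for scan in spec.iter(f"{{{_NS}}}scan"):
            for cv in scan.iter(f"{{{_NS}}}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt_seconds = float(cv.get("value"))
                    if cv.get("unitName") == "minute":
                        rt_seconds *= 60.0
        window = None
        if ms_level == 2:
            iso = spec.find(f".//{{{_NS}}}isolationWindow")
            if iso is not None:
                p = _cv_params(iso)
                target = float(p["MS:1000827"])
                lo = target - float(p.get("MS:1000828", 0.0))
                hi = target + float(p.get("MS:1000829", 0.0))
                key = (round(lo, 6), round(hi, 6))
                if key not in window_cache:
                    window_cache[key] = IsolationWindow(len(window_cache), lo, hi)
                window = window_cache[key]
        mz_arr = intensity_arr = None
        for bda in spec.iter(f"{{{_NS}}}binaryDataArray"):
            p = _cv_params(bda)
            if "MS:1000514" in p:
                mz_arr = _decode_array(bda)
            elif "MS:1000515" in p:
                intensity_arr = _decode_array(bda)
        if mz_arr is None or intensity_arr is None:
            raise ValueError(f"spectrum {spec.get('id')} lacks m/z or intensity array")
        run.append(SpectrumRecord(ms_level, rt_seconds, mz_arr, intensity_arr,
                                  window=window))
    run.sort(key=lambda s: s.rt)
    return run


def write_spectral_library(entries: pd.DataFrame, path: str | os.PathLike) -> None:
    missing = [c for c in LIBRARY_COLUMNS if c not in entries.columns]
    if missing:
        raise ValueError(f"missing column: {', '.join(missing)}")
    entries.to_csv(path, sep="\t", index=False)


def read_spectral_library(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a transition-list TSV.

    Fragment m/z values are cross-checked against the theoretical value for
    the annotated ion; entries off by more than 0.01 Da are kept with the
    recomputed m/z and a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty spectral library: {path}")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column: {', '.join(missing)}")
    from .collapse import parse_localization_string

    corrected = 0
    for idx, row in df.iterrows():
        probs = parse_localization_string(str(row.modified_sequence))
        sequence = "".join(c for c in str(row.modified_sequence) if c.isupper())
        peptide = ModifiedPeptide(sequence, len(probs))
        cand = SiteCandidate(peptide, tuple(sorted(probs)))
        match = [i for i in theoretical_fragments(cand, charges=(int(row.fragment_charge),))
                 if i.series == row.fragment_series and i.index == int(row.fragment_index)]
        if not match:
            continue
        theo = match[0].mz
        if abs(theo - float(row.fragment_mz)) > 0.01:
            warnings.warn(
                f"library row {idx}: fragment m/z {row.fragment_mz} deviates from "
                f"theoretical {theo:.4f}; recomputed value used")
            df.loc[idx, "fragment_mz"] = theo
            corrected += 1
    if corrected:
        logger.info("recomputed %d fragment m/z values in %s", corrected, path)
    return df


def write_report(results: pd.DataFrame, level: str, path: str | os.PathLike,
                 overwrite: bool = False) -> None:
    """Write one of the output levels (precursor / peptide / site / occupancy)
    as TSV; round-trips bit-exactly via :func:`read_report`."""
    if level not in REPORT_LEVELS:
        raise ValueError(f"unknown report level: {level}; expected one of {REPORT_LEVELS}")
    if results is None or len(results) == 0:
        raise ValueError("empty results")
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path}; pass overwrite=True")
    df = results.reset_index() if results.index.name or isinstance(
        results.index, pd.MultiIndex) else results
    df.to_csv(path, sep="\t", index=False)


def read_report(path: str | os.PathLike, index_cols: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_cols:
        df = df.set_index(index_cols)
    return df


@dataclass
class RunManifest:
    """Run id -> (mzML path, condition, replicate) bookkeeping."""

    entries: pd.DataFrame  # columns: run, path, condition, replicate

    def __post_init__(self) -> None:
        required = {"run", "path", "condition", "replicate"}
        if not required <= set(self.entries.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        if self.entries["run"].duplicated().any():
            dup = self.entries.loc[self.entries["run"].duplicated(), "run"].tolist()
            raise ValueError(f"duplicate run ids: {dup}")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, check_files: bool = True) -> "RunManifest":
        manifest = cls(pd.read_csv(path, sep="\t"))
        if check_files:
            base = os.path.dirname(str(path))
            for p in manifest.entries["path"]:
                full = p if os.path.isabs(p) else os.path.join(base, p)
                if not os.path.exists(full):
                    raise FileNotFoundError(f"manifest references missing file: {p}")
        return manifest
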