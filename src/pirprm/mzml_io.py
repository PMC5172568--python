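"""Minimal mzML writing and reading for PRM (MS2-only) runs.

Writing: a deliberately small mzML 1.1 emitter covering exactly what a
targeted PRM run needs — centroided MS2 spectra with scan start time,
isolation-window target m/z and uncompressed 64-bit float m/z / intensity
arrays, tagged with the standard PSI-MS CV accessions. Files it produces
are readable by pyteomics (and by any conformant mzML reader).

Reading: a matching namespace-tolerant iterparse reader that flattens each
MS2 spectrum into the fields the quantifier needs. It accepts 32/64-bit
float arrays, uncompressed or zlib-compressed, and both minute- and
second-valued scan start times.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

__all__ = ["Ms2Scan", "write_prm_mzml", "iter_ms2_scans"]


@dataclass
class Ms2Scan:
    """One centroided MS2 scan of a PRM run."""

    rt_min: float
    isolation_target_mz: float
    precursor_charge: Optional[int]
    mz: np.ndarray
    intensity: np.ndarray


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: str = "") -> str:
    s = f'<cvParam cvRef="MS" accession="{accession}" name="{escape(name)}" value="{escape(value)}"'
    if unit:
        s += f' unitCvRef="UO" unitAccession="{unit[0]}" unitName="{unit[1]}"'
    return s + "/>"


_MINUTE = ("UO:0000031", "minute")


def _spectrum_xml(index: int, scan: Ms2Scan) -> str:
    mz_b64 = _b64(np.asarray(scan.mz, dtype=float))
    int_b64 = _b64(np.asarray(scan.intensity, dtype=float))
    n = len(scan.mz)
    charge = (
        _cv("MS:1000041", "charge state", str(scan.precursor_charge))
        if scan.precursor_charge
        else ""
    )
    return f"""<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{n}">
{_cv("MS:1000580", "MSn spectrum")}
{_cv("MS:1000511", "ms level", "2")}
{_cv("MS:1000127", "centroid spectrum")}
<scanList count="1">
{_cv("MS:1000795", "no combination")}
<scan>
{_cv("MS:1000016", "scan start time", f"{scan.rt_min:.6f}", _MINUTE)}
</scan>
</scanList>
<precursorList count="1">
<precursor>
<isolationWindow>
{_cv("MS:1000827", "isolation window target m/z", f"{scan.isolation_target_mz:.6f}")}
</isolationWindow>
<selectedIonList count="1">
<selectedIon>
{_cv("MS:1000744", "selected ion m/z", f"{scan.isolation_target_mz:.6f}")}
{charge}
</selectedIon>
</selectedIonList>
<activation>
{_cv("MS:1000422", "beam-type collision-induced dissociation")}
</activation>
</precursor>
</precursorList>
<binaryDataArrayList count="2">
<binaryDataArray encodedLength="{len(mz_b64)}">
{_cv("MS:1000523", "64-bit float")}
{_cv("MS:1000576", "no compression")}
{_cv("MS:1000514", "m/z array")}
<binary>{mz_b64}</binary>
</binaryDataArray>
<binaryDataArray encodedLength="{len(int_b64)}">
{_cv("MS:1000523", "64-bit float")}
{_cv("MS:1000576", "no compression")}
{_cv("MS:1000515", "intensity array")}
<binary>{int_b64}</binary>
</binaryDataArray>
</binaryDataArrayList>
</spectrum>"""


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
</cvList>
<fileDescription>
<fileContent>
<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
</fileContent>
</fileDescription>
<softwareList count="1">
<software id="pirprm" version="0.1.0"/>
</softwareList>
<instrumentConfigurationList count="1">
<instrumentConfiguration id="IC1"/>
</instrumentConfigurationList>
<dataProcessingList count="1">
<dataProcessing id="DP1">
<processingMethod order="1" softwareRef="pirprm">
<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
</processingMethod>
</dataProcessing>
</dataProcessingList>
<run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
<spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_FOOTER = """</spectrumList>
</run>
</mzML>
"""


def write_prm_mzml(scans: Sequence[Ms2Scan], path, run_id: str = "prm_run") -> None:
    """Write MS2 scans (sorted by retention time) to an mzML file."""
    ordered = sorted(scans, key=lambda s: s.rt_min)
    with open(path, "w", newline="\n") as fh:
        fh.write(_HEADER.format(run_id=escape(run_id), count=len(ordered)))
        for i, scan in enumerate(ordered):
            fh.write(_spectrum_xml(i, scan))
            fh.write("\n")
        fh.write(_FOOTER)


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict:
    """accession -> (value, unitName) for cvParams anywhere under elem."""
    out = {}
    for cv in elem.iter():
        if _localname(cv.tag) == "cvParam":
            out[cv.get("accession")] = (cv.get("value", ""), cv.get("unitName", ""))
    return out


def _first(elem, name):
    for child in elem.iter():
        if _localname(child.tag) == name:
            return child
    return None


def _decode_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = _first(bda, "binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32-bit vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> Optional[Ms2Scan]:
    """Convert one <spectrum> element into an Ms2Scan; None for non-MS2."""
    top = _cv_params(elem)
    if top.get("MS:1000511", ("",))[0] != "2":
        return None
    sid = elem.get("id", "?")
    precursor = _first(elem, "precursor")
    window = _first(elem, "isolationWindow") if precursor is not None else None
    target = None
    if window is not None:
        target = _cv_params(window).get("MS:1000827", (None,))[0]
    if target is None:
        raise ValueError(f"scan {sid}: missing isolation window target m/z")
    charge = None
    ion = _first(precursor, "selectedIon")
    if ion is not None:
        charge_val = _cv_params(ion).get("MS:1000041", (None,))[0]
        charge = int(charge_val) if charge_val else None
    scan_meta = _first(elem, "scan")
    rt_entry = _cv_params(scan_meta).get("MS:1000016") if scan_meta is not None else None
    if rt_entry is None:
        raise ValueError(f"scan {sid}: missing scan start time")
    rt = float(rt_entry[0])
    if rt_entry[1] == "second":
        rt /= 60.0
    mz_arr = intensity_arr = None
    for bda in elem.iter():
        if _localname(bda.tag) != "binaryDataArray":
            continue
        params = _cv_params(bda)
        if "MS:1000514" in params:
            mz_arr = _decode_array(bda)
        elif "MS:1000515" in params:
            intensity_arr = _decode_array(bda)
    if mz_arr is None or intensity_arr is None:
        raise ValueError(f"scan {sid}: missing m/z or intensity array")
    return Ms2Scan(
        rt_min=rt,
        isolation_target_mz=float(target),
        precursor_charge=charge,
        mz=mz_arr,
        intensity=intensity_arr,
    )


def iter_ms2_scans(path) -> Iterator[Ms2Scan]:
    """Yield MS2 scans from an mzML file (any conformant producer).

    Raises ``ValueError`` when a scan lacks isolation-target metadata, and
    after iteration when the file contained no MS2 scans at all.
    """
    n_ms2 = 0
    for _, elem in ElementTree.iterparse(str(path), events=("end",)):
        if _localname(elem.tag) != "spectrum":
            continue
        scan = _parse_spectrum(elem)
        elem.clear()
        if scan is not None:
            n_ms2 += 1
            yield scan
    if n_ms2 == 0:
        raise ValueError(f"{path}: no MS2 scans found")
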