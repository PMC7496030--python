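"""Centroided MS1 runs and mzML round-tripping.

A :class:`Run` is an ordered list of centroided MS1 scans with acquisition
metadata (laboratory, replicate, sample, time point). Writing produces a
standard mzML 1.1.0 document (64-bit arrays, zlib compression, scan start
times declared in minutes); the reader parses the standard cvParam
vocabulary (spectrum type, ms level, scan time units, array encodings)
directly from the XML and re-validates the invariants, so a write/read
round trip is exact to float64.
"""
from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np


@dataclass
class RunMetadata:
    lab: str = "lab0"
    replicate: int = 0
    sample: str = "sample"
    timepoint: float = 0.0

    def encode(self) -> str:
        return f"lab={self.lab};replicate={self.replicate};sample={self.sample};timepoint={self.timepoint:g}"

    @classmethod
    def decode(cls, text: str) -> "RunMetadata":
        try:
            kv = dict(item.split("=", 1) for item in text.split(";"))
            return cls(lab=kv["lab"], replicate=int(kv["replicate"]),
                       sample=kv["sample"], timepoint=float(kv["timepoint"]))
        except (ValueError, KeyError):
            return cls()


@dataclass
class Run:
    """Ordered centroided MS1 scans: parallel lists of RT (minutes) and peak arrays."""

    rt_minutes: np.ndarray
    mz_arrays: list[np.ndarray]
    intensity_arrays: list[np.ndarray]
    metadata: RunMetadata = field(default_factory=RunMetadata)

    def __post_init__(self) -> None:
        self.rt_minutes = np.asarray(self.rt_minutes, dtype=float)
        if self.rt_minutes.size == 0:
            raise ValueError("a run needs at least one MS1 scan")
        if len(self.mz_arrays) != self.rt_minutes.size or len(self.intensity_arrays) != self.rt_minutes.size:
            raise ValueError("scan array lists must match the RT vector length")
        if np.any(np.diff(self.rt_minutes) <= 0):
            raise ValueError("scan retention times must be strictly increasing")
        for i, (mz, inten) in enumerate(zip(self.mz_arrays, self.intensity_arrays)):
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.shape != inten.shape:
                raise ValueError(f"scan {i}: m/z and intensity arrays differ in length")
            if np.any(inten < 0):
                raise ValueError(f"scan {i}: negative intensity")
            if mz.size > 1 and np.any(np.diff(mz) < 0):  # normalise: sort by m/z
                order = np.argsort(mz, kind="stable")
                mz, inten = mz[order], inten[order]
            self.mz_arrays[i] = mz
            self.intensity_arrays[i] = inten

    @property
    def n_scans(self) -> int:
        return int(self.rt_minutes.size)

    @cached_property
    def _flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All centroids flattened and globally sorted by m/z: (mz, intensity, scan index)."""
        sizes = [a.size for a in self.mz_arrays]
        if sum(sizes) == 0:
            return np.empty(0), np.empty(0), np.empty(0, dtype=np.intp)
        mz = np.concatenate(self.mz_arrays)
        inten = np.concatenate(self.intensity_arrays)
        scan = np.repeat(np.arange(self.n_scans, dtype=np.intp), sizes)
        order = np.argsort(mz, kind="stable")
        return mz[order], inten[order], scan[order]


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *map(float, values))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_CV = {
    "ms1": ("MS:1000579", "MS1 spectrum"),
    "level": ("MS:1000511", "ms level"),
    "centroid": ("MS:1000127", "centroid spectrum"),
    "scan_start": ("MS:1000016", "scan start time"),
    "mz_array": ("MS:1000514", "m/z array"),
    "intensity_array": ("MS:1000515", "intensity array"),
    "f64": ("MS:1000523", "64-bit float"),
    "zlib": ("MS:1000574", "zlib compression"),
    "positive": ("MS:1000130", "positive scan"),
}


def _cvparam(key: str, value: str = "", unit: tuple[str, str, str] | None = None) -> str:
    acc, name = _CV[key]
    parts = [f'<cvParam cvRef="MS" accession="{acc}" name={quoteattr(name)} value={quoteattr(value)}']
    if unit:
        ref, uacc, uname = unit
        parts.append(f' unitCvRef="{ref}" unitAccession="{uacc}" unitName={quoteattr(uname)}')
    parts.append("/>")
    return "".join(parts)


def write_mzml(run: Run, path: str | Path) -> Path:
    """Serialise a run as centroided-MS1 mzML; returns the written path."""
    path = Path(path)
    n = run.n_scans
    with open(path, "w", encoding="utf-8") as fh:
        fh.write('<?xml version="1.0" encoding="utf-8"?>\n')
        fh.write('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n')
        fh.write('<cvList count="2">'
                 '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
                 'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
                 '<cv id="UO" fullName="Unit Ontology" '
                 'URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>'
                 '</cvList>\n')
        fh.write('<fileDescription><fileContent>'
                 + _cvparam("ms1") + _cvparam("centroid")
                 + '</fileContent></fileDescription>\n')
        fh.write('<softwareList count="1"><software id="mampep" version="0.1.0"/></softwareList>\n')
        fh.write('<instrumentConfigurationList count="1">'
                 '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>\n')
        fh.write('<dataProcessingList count="1"><dataProcessing id="mampep_simulation">'
                 '<processingMethod order="1" softwareRef="mampep"/>'
                 '</dataProcessing></dataProcessingList>\n')
        fh.write(f'<run id={quoteattr(run.metadata.encode())} '
                 f'defaultInstrumentConfigurationRef="IC1">\n')
        fh.write(f'<spectrumList count="{n}" defaultDataProcessingRef="mampep_simulation">\n')
        for i in range(n):
            mz = run.mz_arrays[i]
            inten = run.intensity_arrays[i]
            mz_b64 = _encode_array(mz)
            in_b64 = _encode_array(inten)
            fh.write(f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{mz.size}">')
            fh.write(_cvparam("ms1"))
            fh.write(_cvparam("level", "1"))
            fh.write(_cvparam("centroid"))
            fh.write(_cvparam("positive"))
            fh.write('<scanList count="1"><scan>')
            fh.write(_cvparam("scan_start", f"{run.rt_minutes[i]:.8f}",
                              ("UO", "UO:0000031", "minute")))
            fh.write('</scan></scanList>')
            fh.write('<binaryDataArrayList count="2">')
            fh.write(f'<binaryDataArray encodedLength="{len(mz_b64)}">'
                     + _cvparam("f64") + _cvparam("zlib") + _cvparam("mz_array")
                     + f'<binary>{mz_b64}</binary></binaryDataArray>')
            fh.write(f'<binaryDataArray encodedLength="{len(in_b64)}">'
                     + _cvparam("f64") + _cvparam("zlib") + _cvparam("intensity_array")
                     + f'<binary>{in_b64}</binary></binaryDataArray>')
            fh.write('</binaryDataArrayList></spectrum>\n')
        fh.write('</spectrumList>\n</run>\n</mzML>\n')
    return path


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(binary_el, accessions: set[str], length: int, scan_id: str) -> np.ndarray:
    text = (binary_el.text or "").strip()
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib
        raw = zlib.decompress(raw)
    if "MS:1000521" in accessions:  # 32-bit float
        dtype = "<f4"
    else:  # default / MS:1000523 64-bit float
        dtype = "<f8"
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    if length and arr.size != length:
        raise ValueError(f"scan {scan_id}: array length {arr.size} != declared {length}")
    return arr


def read_mzml(path: str | Path, metadata: RunMetadata | None = None) -> Run:
    """Read centroided MS1 scans from an mzML file into a Run.

    Only MS1 spectra are loaded; profile-mode spectra are rejected with a
    clear message; scan times are converted to minutes; centroid arrays are
    returned m/z-sorted even if stored unsorted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed mzML {path}: {exc}") from exc
    run_id = ""
    rts, mzs, intens = [], [], []
    for el in root.iter():
        name = _localname(el.tag)
        if name == "run":
            run_id = el.get("id", "")
        elif name == "spectrum":
            sid = el.get("id", "?")
            params = {}  # accession -> (value, unit accession/name)
            scan_params = {}
            array_blocks = []
            for child in el.iter():
                cname = _localname(child.tag)
                if cname == "cvParam":
                    acc = child.get("accession", "")
                    params.setdefault(acc, (child.get("value", ""),
                                            child.get("unitAccession")
                                            or child.get("unitName") or ""))
                elif cname == "binaryDataArray":
                    accs = {c.get("accession", "")
                            for c in child.iter() if _localname(c.tag) == "cvParam"}
                    binary = next((c for c in child.iter()
                                   if _localname(c.tag) == "binary"), None)
                    array_blocks.append((accs, binary))
                elif cname == "scan":
                    for c in child:
                        if _localname(c.tag) == "cvParam":
                            scan_params[c.get("accession", "")] = (
                                c.get("value", ""),
                                c.get("unitAccession") or c.get("unitName") or "")
            level = params.get("MS:1000511", ("", ""))[0]
            if level and int(level) != 1:
                continue
            if "MS:1000128" in params:  # profile spectrum
                raise ValueError(
                    f"scan {sid}: profile-mode data; this pipeline requires centroided MS1")
            if "MS:1000016" not in scan_params:
                raise ValueError(f"scan {sid}: missing scan start time")
            value, unit = scan_params["MS:1000016"]
            rt_min = float(value)
            if unit in ("UO:0000010", "second", "seconds"):
                rt_min /= 60.0
            length = int(el.get("defaultArrayLength", 0))
            mz_arr = int_arr = None
            for accs, binary in array_blocks:
                if binary is None:
                    continue
                if "MS:1000514" in accs:
                    mz_arr = _decode_binary(binary, accs, length, sid)
                elif "MS:1000515" in accs:
                    int_arr = _decode_binary(binary, accs, length, sid)
            if mz_arr is None or int_arr is None:
                raise ValueError(f"scan {sid}: missing m/z or intensity array")
            rts.append(rt_min)
            mzs.append(mz_arr)
            intens.append(int_arr)
    if not rts:
        raise ValueError(f"{path}: no MS1 scans present")
    meta = metadata if metadata is not None else RunMetadata.decode(run_id)
    return Run(rt_minutes=np.asarray(rts), mz_arrays=mzs, intensity_arrays=intens,
               metadata=meta)
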