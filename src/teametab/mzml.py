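"""Minimal centroided-mzML reading and writing.

Only the subset of mzML 1.1 needed for flow-infusion fingerprints is
supported: a flat spectrum list where every spectrum is centroided,
carries a polarity cvParam and two 64-bit, uncompressed, base64-encoded
binary arrays (m/z and intensity).  This is the subset msconvert emits
for centroided FIE-MS runs.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError

MZML_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions
_CV_POSITIVE = "MS:1000130"
_CV_NEGATIVE = "MS:1000129"
_CV_CENTROID = "MS:1000127"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_64BIT = "MS:1000523"
_CV_NO_COMPRESSION = "MS:1000576"


@dataclass
class CentroidScan:
    """One centroided scan: polarity tag plus parallel m/z / intensity arrays.

    Peaks are kept sorted by m/z; intensities are non-negative.
    """

    polarity: str  # "positive" | "negative"
    scan_index: int
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


def _encode(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def _decode(text: str, n: int) -> np.ndarray:
    raw = base64.b64decode(text.encode("ascii"))
    return np.array(struct.unpack(f"<{n}d", raw), dtype=float)


def write_mzml(path, scans: list[CentroidScan]) -> None:
    """Write scans as a centroided mzML file (uncompressed 64-bit arrays)."""
    if not scans:
        raise EmptyInputError("no scans to write")
    root = ET.Element("mzML", xmlns=MZML_NS, version="1.1.0")
    run = ET.SubElement(root, "run", id="run")
    slist = ET.SubElement(run, "spectrumList", count=str(len(scans)))
    for i, scan in enumerate(scans):
        spec = ET.SubElement(
            slist,
            "spectrum",
            index=str(i),
            id=f"scan={scan.scan_index}",
            defaultArrayLength=str(len(scan.mz)),
        )
        ET.SubElement(spec, "cvParam", accession=_CV_CENTROID, name="centroid spectrum")
        if scan.polarity == "positive":
            ET.SubElement(spec, "cvParam", accession=_CV_POSITIVE, name="positive scan")
        else:
            ET.SubElement(spec, "cvParam", accession=_CV_NEGATIVE, name="negative scan")
        arrays = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for accession, name, values in (
            (_CV_MZ_ARRAY, "m/z array", scan.mz),
            (_CV_INT_ARRAY, "intensity array", scan.intensity),
        ):
            arr = ET.SubElement(arrays, "binaryDataArray")
            ET.SubElement(arr, "cvParam", accession=_CV_64BIT, name="64-bit float")
            ET.SubElement(
                arr, "cvParam", accession=_CV_NO_COMPRESSION, name="no compression"
            )
            ET.SubElement(arr, "cvParam", accession=accession, name=name)
            binary = ET.SubElement(arr, "binary")
            binary.text = _encode(values)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")


def read_mzml(path) -> list[CentroidScan]:
    """Read a centroided mzML file written by :func:`write_mzml` or msconvert."""
    tree = ET.parse(path)
    ns = {"m": MZML_NS}
    scans: list[CentroidScan] = []
    for spec in tree.getroot().iter(f"{{{MZML_NS}}}spectrum"):
        n = int(spec.get("defaultArrayLength", "0"))
        scan_id = spec.get("id", "scan=0")
        scan_index = int(scan_id.rsplit("=", 1)[-1])
        polarity = "positive"
        for cv in spec.findall("m:cvParam", ns):
            if cv.get("accession") == _CV_NEGATIVE:
                polarity = "negative"
        mz = intensity = np.empty(0)
        for arr in spec.iter(f"{{{MZML_NS}}}binaryDataArray"):
            accessions = {cv.get("accession") for cv in arr.findall("m:cvParam", ns)}
            binary = arr.find("m:binary", ns)
            values = _decode(binary.text or "", n) if n else np.empty(0)
            if _CV_MZ_ARRAY in accessions:
                mz = values
            elif _CV_INT_ARRAY in accessions:
                intensity = values
        scans.append(
            CentroidScan(
                polarity=polarity, scan_index=scan_index, mz=mz, intensity=intensity
            )
        )
    if not scans:
        raise EmptyInputError(f"no spectra found in {path}")
    return scans
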