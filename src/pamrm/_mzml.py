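"""Minimal mzML reader/writer for MRM chromatograms and product-ion spectra.

Only the subset of mzML needed by this package is supported: spectrum and
chromatogram lists with uncompressed or zlib-compressed 32/64-bit float
binary arrays.  Retention times are converted to minutes on read.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from typing import List, Optional, Sequence, Tuple

import numpy as np

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_TIME_ARRAY = "MS:1000595"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_ISOLATION_TARGET = "MS:1000827"


def _encode(values: np.ndarray) -> str:
    data = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(data).decode("ascii")


def _cv(parent: ET.Element, accession: str, name: str, value: str = "",
        unit: Optional[Tuple[str, str]] = None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit is not None:
        attrs.update(
            {"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]}
        )
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent: ET.Element, values: np.ndarray, kind_acc: str,
                  kind_name: str, unit: Optional[Tuple[str, str]] = None) -> None:
    encoded = _encode(values)
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(encoded))})
    _cv(bda, _ACC_F64, "64-bit float")
    _cv(bda, _ACC_NO_COMPRESSION, "no compression")
    _cv(bda, kind_acc, kind_name, unit=unit)
    ET.SubElement(bda, "binary").text = encoded


def write_mzml(
    path: str,
    chromatograms: Sequence[Tuple[float, float, np.ndarray, np.ndarray]] = (),
    spectra: Sequence[Tuple[float, float, np.ndarray, np.ndarray]] = (),
) -> None:
    """Write chromatograms (q1, q3, times_min, intensities) and product-ion
    spectra (precursor_mz, rt_min, mz, intensities) to an mzML file."""
    root = ET.Element("mzML", {"xmlns": _NS, "version": "1.1.0"})
    run = ET.SubElement(root, "run", {"id": "run0"})

    if spectra:
        spec_list = ET.SubElement(
            run, "spectrumList", {"count": str(len(spectra))}
        )
        for i, (precursor_mz, rt_min, mz, intensity) in enumerate(spectra):
            spec = ET.SubElement(
                spec_list,
                "spectrum",
                {"index": str(i), "id": f"spectrum={i}",
                 "defaultArrayLength": str(len(mz))},
            )
            _cv(spec, "MS:1000511", "ms level", "2")
            scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
            scan = ET.SubElement(scan_list, "scan")
            _cv(scan, _ACC_SCAN_START, "scan start time", repr(float(rt_min)),
                unit=("UO:0000031", "minute"))
            precursors = ET.SubElement(spec, "precursorList", {"count": "1"})
            precursor = ET.SubElement(precursors, "precursor")
            ion_list = ET.SubElement(precursor, "selectedIonList", {"count": "1"})
            ion = ET.SubElement(ion_list, "selectedIon")
            _cv(ion, _ACC_SELECTED_MZ, "selected ion m/z", repr(float(precursor_mz)))
            arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
            _binary_array(arrays, mz, _ACC_MZ_ARRAY, "m/z array")
            _binary_array(arrays, intensity, _ACC_INT_ARRAY, "intensity array")

    if chromatograms:
        chrom_list = ET.SubElement(
            run, "chromatogramList", {"count": str(len(chromatograms))}
        )
        for i, (q1, q3, times, intensity) in enumerate(chromatograms):
            chrom = ET.SubElement(
                chrom_list,
                "chromatogram",
                {"index": str(i),
                 "id": f"SRM SIC Q1={q1:.4f} Q3={q3:.4f}",
                 "defaultArrayLength": str(len(times))},
            )
            _cv(chrom, "MS:1001473", "selected reaction monitoring chromatogram")
            precursor = ET.SubElement(chrom, "precursor")
            iso = ET.SubElement(precursor, "isolationWindow")
            _cv(iso, _ACC_ISOLATION_TARGET, "isolation window target m/z",
                repr(float(q1)))
            product = ET.SubElement(chrom, "product")
            iso = ET.SubElement(product, "isolationWindow")
            _cv(iso, _ACC_ISOLATION_TARGET, "isolation window target m/z",
                repr(float(q3)))
            arrays = ET.SubElement(chrom, "binaryDataArrayList", {"count": "2"})
            _binary_array(arrays, times, _ACC_TIME_ARRAY, "time array",
                          unit=("UO:0000031", "minute"))
            _binary_array(arrays, intensity, _ACC_INT_ARRAY, "intensity array")

    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element: ET.Element) -> dict:
    params = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            params[child.get("accession")] = child.get("name"), child.get("value"), \
                child.get("unitName")
    return params


def _decode_arrays(element: ET.Element) -> dict:
    """Map array-kind accession -> numpy array for one spectrum/chromatogram."""
    arrays = {}
    for bda_list in element:
        if _local(bda_list.tag) != "binaryDataArrayList":
            continue
        for bda in bda_list:
            if _local(bda.tag) != "binaryDataArray":
                continue
            params = _cv_params(bda)
            binary_text = ""
            for child in bda:
                if _local(child.tag) == "binary":
                    binary_text = child.text or ""
            data = base64.b64decode(binary_text)
            if _ACC_ZLIB in params:
                data = zlib.decompress(data)
            dtype = "<f4" if _ACC_F32 in params else "<f8"
            values = np.frombuffer(data, dtype=dtype).astype(float)
            unit = None
            for acc in (_ACC_MZ_ARRAY, _ACC_INT_ARRAY, _ACC_TIME_ARRAY):
                if acc in params:
                    unit = params[acc][2]
                    arrays[acc] = (values, unit)
        break
    return arrays


def _to_minutes(values: np.ndarray, unit: Optional[str]) -> np.ndarray:
    if unit and unit.lower() in ("second", "seconds", "s"):
        return values / 60.0
    return values


def read_mzml(path: str):
    """Parse an mzML file.

    Returns ``(chromatograms, spectra, n_skipped)`` where chromatograms are
    (q1, q3, times_min, intensities) tuples, spectra are
    (precursor_mz, rt_min, mz, intensities) tuples, and ``n_skipped`` counts
    spectra without MS2 data (e.g. MS1 surveys) that were ignored.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, column = exc.position
        offset = 0
        with open(path, "rb") as handle:
            for _ in range(line - 1):
                offset += len(handle.readline())
        offset += column
        raise ValueError(
            f"malformed mzML file {path!r}: {exc.msg} at byte offset {offset}"
        ) from exc

    root = tree.getroot()
    chromatograms: List[tuple] = []
    spectra: List[tuple] = []
    n_skipped = 0

    for element in root.iter():
        tag = _local(element.tag)
        if tag == "chromatogram":
            q1 = q3 = None
            for child in element:
                child_tag = _local(child.tag)
                if child_tag in ("precursor", "product"):
                    for iso in child:
                        params = _cv_params(iso)
                        if _ACC_ISOLATION_TARGET in params:
                            value = float(params[_ACC_ISOLATION_TARGET][1])
                            if child_tag == "precursor":
                                q1 = value
                            else:
                                q3 = value
            arrays = _decode_arrays(element)
            if _ACC_TIME_ARRAY not in arrays or _ACC_INT_ARRAY not in arrays:
                n_skipped += 1
                continue
            times, time_unit = arrays[_ACC_TIME_ARRAY]
            intensities, _ = arrays[_ACC_INT_ARRAY]
            chromatograms.append(
                (q1, q3, _to_minutes(times, time_unit), intensities)
            )
        elif tag == "spectrum":
            params = _cv_params(element)
            ms_level = params.get("MS:1000511", (None, None, None))[1]
            if ms_level is not None and ms_level != "2":
                n_skipped += 1
                continue
            precursor_mz = None
            rt_min = 0.0
            for sub in element.iter():
                sub_params = _cv_params(sub)
                if _ACC_SELECTED_MZ in sub_params:
                    precursor_mz = float(sub_params[_ACC_SELECTED_MZ][1])
                if _ACC_SCAN_START in sub_params:
                    name, value, unit = sub_params[_ACC_SCAN_START]
                    rt_min = float(_to_minutes(np.array([float(value)]), unit)[0])
            if precursor_mz is None:
                n_skipped += 1
                continue
            arrays = _decode_arrays(element)
            if _ACC_MZ_ARRAY not in arrays or _ACC_INT_ARRAY not in arrays:
                n_skipped += 1
                continue
            spectra.append(
                (precursor_mz, rt_min, arrays[_ACC_MZ_ARRAY][0],
                 arrays[_ACC_INT_ARRAY][0])
            )

    if not chromatograms and not spectra:
        raise ValueError(f"empty mzML run in {path!r}")
    return chromatograms, spectra, n_skipped
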