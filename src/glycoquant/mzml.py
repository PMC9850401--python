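"""Minimal mzML 1.1.0 reading and writing.

Covers the subset of mzML this pipeline produces and consumes: centroided
MS1/MS2 spectra with 64-bit (or 32-bit) float arrays, no compression or
zlib, scan start times in minutes or seconds, and per-MS2 precursor
selected-ion metadata. Vendor conversions with this profile load fine;
exotic features (ion mobility, chromatogram lists, numpress) are out of
scope.
"""

from __future__ import annotations

import base64
import zlib
from typing import TYPE_CHECKING

import numpy as np
from lxml import etree

if TYPE_CHECKING:  # pragma: no cover
    from .lcms import SpectrumRecord

_NS = "http://psi.hupo.org/ms/mzml"

_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_CE = "MS:1000045"


class MzMLParseError(ValueError):
    """Malformed mzML; the message names the offending scan where known."""


def _cv_params(elem) -> dict[str, str]:
    return {
        c.get("accession"): c.get("value", "")
        for c in elem.iter(f"{{{_NS}}}cvParam")
    }


def _decode_binary_array(bda, scan_id: str) -> tuple[str | None, np.ndarray]:
    params = _cv_params(bda)
    if _ACC_F64 in params:
        dtype = "<f8"
    elif _ACC_F32 in params:
        dtype = "<f4"
    else:
        raise MzMLParseError(f"scan {scan_id}: binary array without a float-type cvParam")
    binary = bda.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    data = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = "mz" if _ACC_MZ_ARRAY in params else ("intensity" if _ACC_INT_ARRAY in params else None)
    return kind, data


def read_mzml(path) -> list["SpectrumRecord"]:
    from .lcms import SpectrumRecord

    records: list[SpectrumRecord] = []
    try:
        context = etree.iterparse(str(path), events=("end",), tag=f"{{{_NS}}}spectrum")
        for _, spec in context:
            scan_id = spec.get("id", f"index={spec.get('index')}")
            params = _cv_params_direct(spec)
            try:
                ms_level = int(params[_ACC_MS_LEVEL])
            except KeyError:
                raise MzMLParseError(f"scan {scan_id}: missing ms level cvParam") from None
            rt = _read_rt(spec, scan_id)
            mz = inten = None
            for bda in spec.iter(f"{{{_NS}}}binaryDataArray"):
                kind, data = _decode_binary_array(bda, scan_id)
                if kind == "mz":
                    mz = data
                elif kind == "intensity":
                    inten = data
            if mz is None or inten is None:
                raise MzMLParseError(f"scan {scan_id}: missing m/z or intensity array")
            precursor_mz = precursor_charge = None
            sel = spec.find(
                f"{{{_NS}}}precursorList/{{{_NS}}}precursor/"
                f"{{{_NS}}}selectedIonList/{{{_NS}}}selectedIon"
            )
            if sel is not None:
                sp = _cv_params(sel)
                if _ACC_SELECTED_MZ in sp:
                    precursor_mz = float(sp[_ACC_SELECTED_MZ])
                if _ACC_CHARGE in sp:
                    precursor_charge = int(float(sp[_ACC_CHARGE]))
            records.append(
                SpectrumRecord(
                    scan_id=scan_id,
                    ms_level=ms_level,
                    rt=rt,
                    mz=mz,
                    intensity=inten,
                    precursor_mz=precursor_mz,
                    precursor_charge=precursor_charge,
                )
            )
            spec.clear()
    except etree.XMLSyntaxError as exc:
        at = f" after scan {records[-1].scan_id}" if records else ""
        raise MzMLParseError(f"malformed mzML{at}: {exc}") from exc
    return records


def _cv_params_direct(spec) -> dict[str, str]:
    # cvParams that belong to the spectrum itself, not nested scans/arrays
    return {
        c.get("accession"): c.get("value", "")
        for c in spec.findall(f"{{{_NS}}}cvParam")
    }


def _read_rt(spec, scan_id: str) -> float:
    scan = spec.find(f"{{{_NS}}}scanList/{{{_NS}}}scan")
    if scan is None:
        raise MzMLParseError(f"scan {scan_id}: missing scanList/scan")
    for c in scan.findall(f"{{{_NS}}}cvParam"):
        if c.get("accession") == _ACC_SCAN_START:
            value = float(c.get("value"))
            unit = (c.get("unitName") or "minute").lower()
            return value / 60.0 if unit.startswith("second") else value
    raise MzMLParseError(f"scan {scan_id}: missing scan start time")


def _b64(a: np.ndarray) -> str:
    return base64.b64encode(np.asarray(a, dtype="<f8").tobytes()).decode("ascii")


def _binary_array_xml(data: np.ndarray, acc: str, name: str) -> str:
    enc = _b64(data)
    return (
        f'<binaryDataArray encodedLength="{len(enc)}">'
        f'<cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>'
        f'<cvParam cvRef="MS" accession="{_ACC_NOCOMP}" name="no compression" value=""/>'
        f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>'
        f"<binary>{enc}</binary></binaryDataArray>"
    )


def write_mzml(spectra, path, run_id: str = "run") -> None:
    """Write spectra as minimal, standard-readable mzML 1.1.0.

    RTs are written in minutes; MS2 spectra carry selected-ion m/z, charge
    and collision energy (when set on the record).
    """
    spectra = list(spectra)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write('<?xml version="1.0" encoding="utf-8"?>\n')
        fh.write(f'<mzML xmlns="{_NS}" version="1.1.0">\n')
        fh.write('<cvList count="1"><cv id="MS" fullName="PSI-MS" '
                 'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>\n')
        fh.write(f'<run id="{run_id}"><spectrumList count="{len(spectra)}">\n')
        for i, s in enumerate(spectra):
            fh.write(
                f'<spectrum index="{i}" id="{s.scan_id}" defaultArrayLength="{len(s.mz)}">'
                f'<cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" value="{s.ms_level}"/>'
            )
            fh.write(
                f'<scanList count="1"><scan><cvParam cvRef="MS" accession="{_ACC_SCAN_START}" '
                f'name="scan start time" value="{s.rt!r}" unitName="minute"/></scan></scanList>'
            )
            if s.ms_level == 2 and s.precursor_mz is not None:
                ce = getattr(s, "collision_energy", None)
                act = (
                    f'<activation><cvParam cvRef="MS" accession="{_ACC_CE}" '
                    f'name="collision energy" value="{ce!r}" unitName="electronvolt"/></activation>'
                    if ce is not None
                    else "<activation/>"
                )
                charge = (
                    f'<cvParam cvRef="MS" accession="{_ACC_CHARGE}" name="charge state" '
                    f'value="{s.precursor_charge}"/>'
                    if s.precursor_charge is not None
                    else ""
                )
                fh.write(
                    f'<precursorList count="1"><precursor><selectedIonList count="1">'
                    f'<selectedIon><cvParam cvRef="MS" accession="{_ACC_SELECTED_MZ}" '
                    f'name="selected ion m/z" value="{s.precursor_mz!r}"/>{charge}</selectedIon>'
                    f"</selectedIonList>{act}</precursor></precursorList>"
                )
            fh.write('<binaryDataArrayList count="2">')
            fh.write(_binary_array_xml(s.mz, _ACC_MZ_ARRAY, "m/z array"))
            fh.write(_binary_array_xml(s.intensity, _ACC_INT_ARRAY, "intensity array"))
            fh.write("</binaryDataArrayList></spectrum>\n")
        fh.write("</spectrumList></run></mzML>\n")
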