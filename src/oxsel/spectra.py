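"""Reading, writing and integrating flow-injection ESI-MS spectra.

Flow injection yields a train of scans at (ideally) constant analyte
concentration; scans are summed into one composite centroided spectrum per
injection. Integration is either over a mass window (stage 1) or an extracted
ion current within a tolerance of a target m/z (stage 2).

Supported formats: two-column CSV (``mz,intensity``) and mzML. mzML support
is a compact reader/writer pair for centroided spectra (base64 32/64-bit
little-endian arrays, optional zlib), covering the subset of the standard
that stick spectra need.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .species import MassWindow, TargetIon

__all__ = [
    "Spectrum",
    "AreaResult",
    "read_spectrum",
    "write_spectrum",
    "write_mzml",
    "read_mzml",
    "window_area",
    "eic_area",
    "average_replicates",
]


@dataclass(frozen=True)
class Spectrum:
    """A centroided composite spectrum with campaign metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    condition_set_id: int | None = None
    replicate: int | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if np.any(~np.isfinite(mz)):
            raise ValueError("m/z values must be finite")
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(inten < 0) or np.any(~np.isfinite(inten)):
            raise ValueError("intensities must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, intensity=self.intensity * factor)


@dataclass(frozen=True)
class AreaResult:
    """Integrated intensity for one window or target ion."""

    label: str
    area: float
    n_peaks: int

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be >= 0")


# ---------------------------------------------------------------------------
# I/O


def _merge_scans(arrays: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Sum multiple centroided scans into one composite spectrum.

    Sticks at identical m/z are co-added; the composite preserves total
    intensity exactly.
    """
    mz = np.concatenate([a for a, _ in arrays])
    inten = np.concatenate([b for _, b in arrays])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, inten)
    return uniq, summed


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    condition_set_id: int | None = None,
    replicate: int | None = None,
    sample: str | None = None,
) -> Spectrum:
    """Read a spectrum from CSV or mzML; multi-scan files are summed.

    ``format`` defaults from the file suffix. Metadata fields are attached
    from the keyword arguments (typically taken from a manifest table).
    """
    path = Path(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
        if not {"mz", "intensity"} <= set(df.columns):
            raise ValueError(f"{path}: CSV needs 'mz' and 'intensity' columns")
        if df["mz"].isna().any() or df["intensity"].isna().any():
            raise ValueError(f"{path}: NaN values in spectrum")
        arrays = [(df["mz"].to_numpy(float), df["intensity"].to_numpy(float))]
    elif fmt == "mzml":
        arrays = read_mzml(path)
        if not arrays:
            warnings.warn(f"{path}: no scans found; returning empty spectrum")
            arrays = [(np.array([]), np.array([]))]
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")
    if not arrays[0][0].size and len(arrays) == 1:
        warnings.warn(f"{path}: empty spectrum")
    mz, inten = _merge_scans(arrays) if len(arrays) > 1 else arrays[0]
    if mz.size and np.any(np.diff(mz) <= 0):
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        mz, inten = _merge_scans([(mz, inten)])
    return Spectrum(mz, inten, condition_set_id, replicate, sample)


_MZML_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS accessions describing binary array encoding
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary_array(bda: ElementTree.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values).

    ``kind`` is 'mz', 'intensity' or None for other array types. Handles
    32/64-bit floats and optional zlib compression.
    """
    dtype, compressed, kind = "<d", False, None
    for cv in bda.iter(f"{{{_MZML_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_F32:
            dtype = "<f"
        elif acc == _ACC_ZLIB:
            compressed = True
        elif acc == _ACC_MZ_ARRAY:
            kind = "mz"
        elif acc == _ACC_INT_ARRAY:
            kind = "intensity"
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parse centroided scans from an mzML file: [(mz, intensity), ...]."""
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise ValueError(f"{path}: not well-formed mzML: {exc}") from exc
    scans = []
    for spectrum in tree.iter(f"{{{_MZML_NS}}}spectrum"):
        mz = inten = None
        for bda in spectrum.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mz is None or inten is None:
            raise ValueError(f"{path}: spectrum without m/z or intensity array")
        scans.append((mz, inten))
    return scans


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{n_scans}">
"""

_MZML_SCAN = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len_mz}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{b64_mz}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len_int}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{b64_int}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64_f64(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % values.size, *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(
    scans: Sequence[tuple[np.ndarray, np.ndarray]], path: str | Path, run_id: str = "run"
) -> Path:
    """Serialize centroided (mz, intensity) scans as a minimal mzML file."""
    path = Path(path)
    parts = [_MZML_HEADER.format(run_id=escape(run_id), n_scans=len(scans))]
    for i, (mz, inten) in enumerate(scans):
        b64_mz, b64_int = _b64_f64(np.asarray(mz)), _b64_f64(np.asarray(inten))
        parts.append(
            _MZML_SCAN.format(
                index=i,
                scan=i + 1,
                n=len(mz),
                len_mz=len(b64_mz),
                b64_mz=b64_mz,
                len_int=len(b64_int),
                b64_int=b64_int,
            )
        )
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts))
    return path


def write_spectrum(s: Spectrum, path: str | Path, format: str | None = None) -> Path:
    """Write a spectrum as CSV (``mz,intensity``) or single-scan mzML."""
    path = Path(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "csv":
        pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(path, index=False)
    elif fmt == "mzml":
        write_mzml([(s.mz, s.intensity)], path, run_id=s.sample or "run")
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Integration


def window_area(s: Spectrum, w: MassWindow) -> AreaResult:
    """Summed intensity of sticks with lo <= m/z < hi (half-open window)."""
    mask = (s.mz >= w.lo) & (s.mz < w.hi)
    return AreaResult(w.label, float(s.intensity[mask].sum()), int(mask.sum()))


def eic_area(s: Spectrum, ion: TargetIon, tol: float = 0.35) -> AreaResult:
    """Extracted-ion area: summed intensity within ``|mz - ion.mz| <= tol``.

    The default tolerance matches unit-resolution quadrupole targets quoted
    to one decimal.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    mask = np.abs(s.mz - ion.mz) <= tol
    return AreaResult(ion.label, float(s.intensity[mask].sum()), int(mask.sum()))


def check_eic_overlap(ions: Sequence[TargetIon], tol: float = 0.35) -> list[tuple[str, str]]:
    """Warn about target pairs closer than 2*tol (ambiguous EIC assignment)."""
    clashes = []
    ordered = sorted(ions, key=lambda i: i.mz)
    for a, b in zip(ordered, ordered[1:]):
        if b.mz - a.mz < 2 * tol:
            clashes.append((a.label, b.label))
    if clashes:
        warnings.warn(f"EIC targets closer than 2*tol: {clashes}")
    return clashes


def average_replicates(values: Iterable[float]) -> tuple[float, float, bool]:
    """Mean and sample SD (ddof=1) across replicates.

    Returns ``(mean, sd, single_replicate_flag)``; with one replicate the SD
    is 0 and the flag is set.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one replicate")
    if arr.size == 1:
        return float(arr[0]), 0.0, True
    return float(arr.mean()), float(arr.std(ddof=1)), False
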