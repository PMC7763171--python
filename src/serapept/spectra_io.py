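"""Reading, writing and scan-averaging of MALDI-TOF spectra and peak lists.

Two on-disk representations are supported:

* **mzML** — profile (or centroid) scans; a self-contained reader/writer
  handling the common binary-data conventions (32/64-bit little-endian
  floats, base64, optional zlib compression).
* **text peak lists** — two whitespace/tab-separated columns (m/z, abundance),
  optional ``#`` comments and an optional non-numeric header line.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree

__all__ = [
    "Spectrum",
    "PeakList",
    "read_spectra",
    "read_peaklist_text",
    "write_peaklist_text",
    "write_mzml",
    "average_scans",
]


class SpectraIOError(ValueError):
    """Malformed spectrum/peak-list input."""


@dataclass
class Spectrum:
    """One acquisition (scan) or an averaged replicate spectrum.

    m/z values are strictly increasing; intensities are non-negative and the
    two arrays have equal length.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectraIOError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz, kind="stable")
            if np.any(np.diff(self.mz[order]) <= 0):
                raise SpectraIOError("duplicate m/z values in spectrum")
            warnings.warn("m/z values were not sorted; sorting", stacklevel=2)
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class PeakList:
    """Centroided signals of one spectrum: (m/z, abundance) pairs.

    Strictly increasing m/z, no duplicates closer than 1e-6 Da.
    """

    mz: np.ndarray
    abundance: np.ndarray
    sample_id: str = ""
    replicate: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.mz.shape != self.abundance.shape or self.mz.ndim != 1:
            raise SpectraIOError("mz and abundance must be 1-D arrays of equal length")
        if self.mz.size > 1:
            if not np.all(np.diff(self.mz) > 0):
                order = np.argsort(self.mz, kind="stable")
                self.mz = self.mz[order]
                self.abundance = self.abundance[order]
            if np.any(np.diff(self.mz) < 1e-6):
                raise SpectraIOError("duplicate m/z (closer than 1e-6 Da) in peak list")

    def __len__(self) -> int:
        return self.mz.size


def read_peaklist_text(path: str | Path, sample_id: str = "", replicate: int | None = None) -> PeakList:
    """Read a 2-column text peak list.

    Lines starting with ``#`` are comments. A single leading header line
    whose first token is not numeric is skipped.
    """
    path = Path(path)
    mzs: list[float] = []
    abunds: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise SpectraIOError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                mzs.append(float(parts[0]))
                abunds.append(float(parts[1]))
            except ValueError:
                if not mzs:  # header line
                    continue
                raise SpectraIOError(f"{path}:{lineno}: non-numeric value {parts[:2]!r}") from None
    return PeakList(np.array(mzs), np.array(abunds), sample_id=sample_id, replicate=replicate)


def write_peaklist_text(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list as two tab-separated columns (m/z, abundance)."""
    with open(path, "w") as fh:
        fh.write("# m/z\tabundance\n")
        for mz, ab in zip(peaklist.mz, peaklist.abundance):
            fh.write(f"{mz:.6f}\t{ab:.6g}\n")


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read spectra from an mzML file or a 2-column text file.

    Parameters
    ----------
    path : file to read.
    format : ``"mzML"`` or ``"text"``; inferred from the suffix when None.

    Returns a list of :class:`Spectrum` in file order.
    """
    path = Path(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "text"
    if format.lower() == "mzml":
        return _read_mzml(path)
    pl = read_peaklist_text(path)
    return [Spectrum(pl.mz, pl.abundance)]


_NS = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions for binary array decoding
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary(bda: etree._Element, spectrum_id: str) -> tuple[str, np.ndarray]:
    dtype, compressed, kind = np.float64, False, None
    for cv in bda.iter(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_F32:
            dtype = np.float32
        elif acc == _ACC_ZLIB:
            compressed = True
        elif acc == _ACC_MZ_ARRAY:
            kind = "mz"
        elif acc == _ACC_INT_ARRAY:
            kind = "intensity"
    node = bda.find(f"{_NS}binary")
    if node is None or kind is None:
        raise SpectraIOError(f"spectrum {spectrum_id!r}: malformed binaryDataArray")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Spectrum]:
    out: list[Spectrum] = []
    try:
        for i, (_, elem) in enumerate(etree.iterparse(str(path), tag=f"{_NS}spectrum")):
            sid = elem.get("id", f"scan={i}")
            arrays: dict[str, np.ndarray] = {}
            for bda in elem.iter(f"{_NS}binaryDataArray"):
                kind, arr = _decode_binary(bda, sid)
                arrays[kind] = arr
            if "mz" not in arrays or "intensity" not in arrays:
                raise SpectraIOError(f"{path}: spectrum {sid!r} lacks m/z or intensity array")
            out.append(Spectrum(arrays["mz"], arrays["intensity"], sample_id=sid, replicate=i))
            elem.clear()
    except etree.XMLSyntaxError as exc:
        raise SpectraIOError(f"{path}: {exc}") from exc
    return out


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
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


def _b64_f64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr.astype(float))).decode("ascii")


def write_mzml(spectra: list[Spectrum], path: str | Path, run_id: str = "run") -> None:
    """Write spectra as minimal mzML (64-bit floats, no compression)."""
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(run_id=escape(run_id, {'"': "&quot;"}), count=len(spectra)))
        for i, sp in enumerate(spectra):
            b64_mz = _b64_f64(sp.mz)
            b64_int = _b64_f64(sp.intensity)
            fh.write(_MZML_SPECTRUM.format(index=i, npts=len(sp),
                                           len_mz=len(b64_mz), b64_mz=b64_mz,
                                           len_int=len(b64_int), b64_int=b64_int))
        fh.write(_MZML_FOOTER)


def average_scans(scans: list[Spectrum], window: int = 15, offset: int = 0) -> Spectrum:
    """Average ``window`` consecutive scans into one spectrum.

    Replicate spectra on a MALDI target spot are acquired as a train of scans
    over one spot; a representative spectrum is the pointwise arithmetic mean
    of ``window`` consecutive scans starting at ``offset``. All scans must
    share the same m/z grid — mismatched grids raise (resampling is never
    applied implicitly).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(scans) < offset + window:
        raise ValueError(f"need at least {offset + window} scans, got {len(scans)}")
    chosen = scans[offset:offset + window]
    grid = chosen[0].mz
    for sp in chosen[1:]:
        if sp.mz.shape != grid.shape or not np.allclose(sp.mz, grid, rtol=0, atol=1e-9):
            raise SpectraIOError("scans do not share an m/z grid; refusing to resample")
    mean = np.mean([sp.intensity for sp in chosen], axis=0)
    out = Spectrum(grid.copy(), mean, sample_id=chosen[0].sample_id)
    return out
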