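"""Centroided LC-HRMS data access: mzXML/mzML reading, per-scan m/z lookup,
and extracted-ion-chromatogram (EIC) construction.

All retention times are handled internally in seconds. mzXML is the primary
dialect (the usual MSConvert output for this workflow); mzML is accepted as a
convenience. Only centroided MS1 spectra are processed; MS2 scans are ignored.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mzxml

__all__ = [
    "MassSpectrum",
    "Run",
    "EIC",
    "ParseError",
    "read_run",
    "lookup",
    "extract_eic",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed as centroided MS1 data."""


@dataclass
class MassSpectrum:
    """One centroided full-scan mass spectrum.

    ``mz`` is strictly ascending and parallel to ``intensity``; intensities
    are non-negative ion counts.
    """

    scan_index: int
    rt: float  # seconds
    polarity: str  # '+' or '-'
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if not np.all(np.diff(self.mz) > 0):
                raise ValueError("scan m/z values must be strictly ascending")
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("negative intensity in scan")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class Run:
    """An ordered single-polarity sequence of MS1 scans from one sample."""

    sample_id: str
    scans: list[MassSpectrum]
    polarity: str

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.rt)

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=float)

    @property
    def rt_span(self) -> tuple[float, float]:
        if not self.scans:
            raise ValueError("empty run has no rt span")
        return self.scans[0].rt, self.scans[-1].rt


@dataclass
class EIC:
    """Extracted ion chromatogram: per-scan summed intensity in a ppm window."""

    target_mz: float
    ppm_window: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity arrays must have equal length")


def _polarity_from_mzxml(entry: dict) -> str | None:
    pol = entry.get("polarity")
    if pol in ("+", "-"):
        return pol
    return None


def _iter_mzxml(path: str):
    with mzxml.read(path) as reader:
        for entry in reader:
            yield (
                int(entry.get("msLevel", 1)),
                float(entry["retentionTime"]) * 60.0,
                _polarity_from_mzxml(entry),
                entry["m/z array"],
                entry["intensity array"],
            )


def _decode_binary_array(array_el, nsmap: dict) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray> (32/64-bit float, optional zlib)."""
    dtype = "<f8"
    compressed = False
    kind = None
    for cv in array_el.findall("mz:cvParam", nsmap):
        name = cv.get("name", "")
        if name == "32-bit float":
            dtype = "<f4"
        elif name == "64-bit float":
            dtype = "<f8"
        elif name == "zlib compression":
            compressed = True
        elif name == "m/z array":
            kind = "mz"
        elif name == "intensity array":
            kind = "intensity"
    binary = array_el.find("mz:binary", nsmap)
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _iter_mzml(path: str):
    """Minimal mzML spectrum iterator (centroided MS1 use case)."""
    ns = "http://psi.hupo.org/ms/mzml"
    nsmap = {"mz": ns}
    context = etree.iterparse(path, events=("end",), tag=f"{{{ns}}}spectrum")
    for _, spectrum in context:
        ms_level = 1
        polarity = None
        for cv in spectrum.findall("mz:cvParam", nsmap):
            name = cv.get("name", "")
            if name == "ms level":
                ms_level = int(cv.get("value", 1))
            elif name == "positive scan":
                polarity = "+"
            elif name == "negative scan":
                polarity = "-"
        rt = None
        for cv in spectrum.findall("mz:scanList/mz:scan/mz:cvParam", nsmap):
            if cv.get("name") == "scan start time":
                value = float(cv.get("value"))
                unit = cv.get("unitName", "minute")
                rt = value if unit.startswith("second") else value * 60.0
        if rt is None:
            raise ParseError(f"{path}: spectrum without scan start time")
        mz = intensity = np.array([])
        for array_el in spectrum.findall(
            "mz:binaryDataArrayList/mz:binaryDataArray", nsmap
        ):
            kind, values = _decode_binary_array(array_el, nsmap)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
        yield ms_level, rt, polarity, mz, intensity
        spectrum.clear()


def _profile_mode_suspected(scans: list[MassSpectrum], max_centroids: int = 2000) -> bool:
    """Heuristic: profile data has very dense, near-contiguous m/z sampling."""
    sizes = [s.mz.size for s in scans if s.mz.size]
    if not sizes or int(np.median(sizes)) <= max_centroids:
        return False
    dense = [s for s in scans if s.mz.size > max_centroids]
    spacing = np.concatenate([np.diff(s.mz) for s in dense[:5]])
    return bool(spacing.size and np.median(spacing) < 0.01)


def read_run(
    path: str,
    polarity: str = "+",
    rt_range: tuple[float, float] | None = None,
    sample_id: str | None = None,
) -> Run:
    """Read MS1 scans of one polarity from an mzXML or mzML file.

    Parameters
    ----------
    path:
        Input file; the dialect is chosen by extension (``.mzxml`` vs
        ``.mzml``, case-insensitive).
    polarity:
        '+' or '-'. Scans with an undeclared polarity are accepted as-is so
        that minimal writers remain readable; mixed-polarity files are thereby
        split on read.
    rt_range:
        Optional ``(low, high)`` window in seconds; scans outside it are
        dropped.
    """
    if polarity not in ("+", "-"):
        raise ValueError("polarity must be '+' or '-'")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty file")

    lower = path.lower()
    if lower.endswith(".mzml"):
        iterator = _iter_mzml(path)
    else:
        iterator = _iter_mzxml(path)

    scans: list[MassSpectrum] = []
    try:
        for ms_level, rt, pol, mz, inten in iterator:
            if ms_level != 1:
                continue
            if pol is not None and pol != polarity:
                continue
            if rt_range is not None and not (rt_range[0] <= rt <= rt_range[1]):
                continue
            scans.append(
                MassSpectrum(
                    scan_index=len(scans),
                    rt=rt,
                    polarity=pol or polarity,
                    ms_level=1,
                    mz=np.asarray(mz, dtype=float),
                    intensity=np.asarray(inten, dtype=float),
                )
            )
    except ParseError:
        raise
    except Exception as exc:  # lxml / pyteomics structural errors
        raise ParseError(f"{path}: cannot parse ({exc})") from exc

    scans.sort(key=lambda s: s.rt)
    for i, scan in enumerate(scans):
        scan.scan_index = i

    if _profile_mode_suspected(scans):
        warnings.warn(
            f"{path}: spectra look like profile-mode data "
            "(very dense, near-contiguous m/z sampling); centroided input expected",
            UserWarning,
            stacklevel=2,
        )
    return Run(
        sample_id=sample_id or os.path.splitext(os.path.basename(path))[0],
        scans=scans,
        polarity=polarity,
    )


def lookup(scan: MassSpectrum, mz: float, ppm: float) -> tuple[float, float] | None:
    """Return the most intense centroid within ``±ppm`` of ``mz``, or None.

    Ties on intensity break deterministically toward the smaller ``|Δm/z|``.
    """
    tol = mz * ppm * 1e-6
    lo = np.searchsorted(scan.mz, mz - tol, side="left")
    hi = np.searchsorted(scan.mz, mz + tol, side="right")
    if hi <= lo:
        return None
    window_mz = scan.mz[lo:hi]
    window_int = scan.intensity[lo:hi]
    best = np.flatnonzero(window_int == window_int.max())
    if best.size > 1:
        best = best[np.argmin(np.abs(window_mz[best] - mz))]
    else:
        best = best[0]
    return float(window_mz[best]), float(window_int[best])


def extract_eic(
    run: Run,
    mz: float,
    ppm: float,
    rt_range: tuple[float, float] | None = None,
) -> EIC:
    """Extract the summed-intensity chromatogram for ``mz ± ppm``.

    Every scan in ``rt_range`` contributes one point: the sum of all centroid
    intensities inside the window (0 where no centroid matches). Summation is
    the default aggregation; it conserves total ion current over a full m/z
    range and is robust to split centroids.
    """
    if not run.scans:
        raise ValueError("cannot extract an EIC from an empty run")
    if rt_range is not None and rt_range[1] < rt_range[0]:
        raise ValueError("empty rt_range")
    tol = mz * ppm * 1e-6
    rts, values = [], []
    for scan in run.scans:
        if rt_range is not None and not (rt_range[0] <= scan.rt <= rt_range[1]):
            continue
        lo = np.searchsorted(scan.mz, mz - tol, side="left")
        hi = np.searchsorted(scan.mz, mz + tol, side="right")
        rts.append(scan.rt)
        values.append(float(scan.intensity[lo:hi].sum()))
    if not rts:
        raise ValueError("rt_range contains no scans")
    return EIC(target_mz=mz, ppm_window=ppm, rt=np.array(rts), intensity=np.array(values))
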