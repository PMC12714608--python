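"""In-memory run containers and file I/O (mzML, MSP, CSV).

A DIA run is a sequence of acquisition cycles; each cycle holds one MS1 survey
scan plus one MS2 scan per SWATH isolation window. Centroids are stored in a
flat column layout (:class:`ScanSeries`) so that XIC extraction is a vectorised
mask over the whole run rather than a per-scan loop.

mzML is written by a minimal centroided writer (lxml) and read back with
``pyteomics.mzml``; the two are round-trip tested against each other.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree


@dataclass
class ScanSeries:
    """Centroided scans on a common time axis, stored column-wise.

    Attributes
    ----------
    times : (n_scans,) float array, minutes
    scan_index : (n_centroids,) int array — owning scan of each centroid
    mz : (n_centroids,) float array, Da
    intensity : (n_centroids,) float array, counts
    """

    times: np.ndarray
    scan_index: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.scan_index = np.asarray(self.scan_index, dtype=np.int64)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.scan_index) == len(self.mz) == len(self.intensity)):
            raise ValueError("centroid columns must have equal length")

    @property
    def n_scans(self) -> int:
        return len(self.times)

    def scan(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(mz, intensity) arrays of scan ``i``, sorted by m/z."""
        sel = self.scan_index == i
        mz = self.mz[sel]
        inten = self.intensity[sel]
        order = np.argsort(mz)
        return mz[order], inten[order]

    @classmethod
    def from_scan_lists(
        cls, times: np.ndarray, peak_lists: list[tuple[np.ndarray, np.ndarray]]
    ) -> "ScanSeries":
        if len(times) != len(peak_lists):
            raise ValueError("one peak list per scan required")
        idx = np.concatenate(
            [np.full(len(mz), i, dtype=np.int64) for i, (mz, _) in enumerate(peak_lists)]
        ) if peak_lists else np.empty(0, dtype=np.int64)
        mz = np.concatenate([m for m, _ in peak_lists]) if peak_lists else np.empty(0)
        inten = np.concatenate([x for _, x in peak_lists]) if peak_lists else np.empty(0)
        return cls(np.asarray(times, float), idx, mz, inten)


@dataclass
class Run:
    """One LC-MS acquisition: MS1 survey series plus per-window MS2 series."""

    run_id: str
    mode: str                      # "positive" | "negative"
    column_mode: str               # "RPLC" | "HILIC"
    gradient_id: str
    sample_id: str | None          # None for QC runs
    ms1: ScanSeries
    ms2: dict[int, ScanSeries] = field(default_factory=dict)
    swath_windows: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", unit: tuple[str, str, str] | None = None):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit is not None:
        attrs.update(
            {"unitCvRef": unit[0], "unitAccession": unit[1], "unitName": unit[2]}
        )
    etree.SubElement(parent, "cvParam", attrs)


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a centroided run as indexed-free mzML 1.1.

    MS1 scans carry ``ms level=1``; each MS2 scan carries its SWATH isolation
    window (target = window centre, lower/upper offsets = half-width).
    """
    root = etree.Element("mzML", nsmap={None: _MZML_NS}, version="1.1.0")
    etree.SubElement(root, "cvList", count="1")
    runel = etree.SubElement(root, "run", id=run.run_id)
    series: list[tuple[int, int, float, np.ndarray, np.ndarray, int | None]] = []
    for i in range(run.ms1.n_scans):
        mz, inten = run.ms1.scan(i)
        series.append((1, i, run.ms1.times[i], mz, inten, None))
    for w, ser in sorted(run.ms2.items()):
        for i in range(ser.n_scans):
            mz, inten = ser.scan(i)
            series.append((2, i, ser.times[i], mz, inten, w))
    series.sort(key=lambda s: (s[2], s[0]))
    speclist = etree.SubElement(runel, "spectrumList", count=str(len(series)))
    for j, (level, _i, t, mz, inten, w) in enumerate(series):
        spec = etree.SubElement(
            speclist, "spectrum", index=str(j), id=f"scan={j}", defaultArrayLength=str(len(mz))
        )
        _cv(spec, "MS:1000511", "ms level", str(level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        scanlist = etree.SubElement(spec, "scanList", count="1")
        scan = etree.SubElement(scanlist, "scan")
        _cv(scan, "MS:1000016", "scan start time", f"{t:.6f}", ("UO", "UO:0000031", "minute"))
        if level == 2 and w is not None and run.swath_windows:
            low, high = run.swath_windows[w]
            pl = etree.SubElement(spec, "precursorList", count="1")
            prec = etree.SubElement(pl, "precursor")
            iso = etree.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", f"{(low + high) / 2:.4f}")
            _cv(iso, "MS:1000828", "isolation window lower offset", f"{(high - low) / 2:.4f}")
            _cv(iso, "MS:1000829", "isolation window upper offset", f"{(high - low) / 2:.4f}")
        bal = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for acc, name, vals in (
            ("MS:1000514", "m/z array", mz),
            ("MS:1000515", "intensity array", inten),
        ):
            enc = _encode_array(vals)
            bda = etree.SubElement(bal, "binaryDataArray", encodedLength=str(len(enc)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000574", "zlib compression")
            _cv(bda, acc, name)
            etree.SubElement(bda, "binary").text = enc
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=False)


def _decode_array(text: str) -> np.ndarray:
    return np.frombuffer(zlib.decompress(base64.b64decode(text)), dtype="<f8").copy()


def read_mzml(path: str | Path) -> Run:
    """Read a centroided DIA mzML run (64-bit zlib arrays, minute time units).

    SWATH windows are reconstructed from the MS2 isolation windows in order of
    ascending lower bound.
    """
    ms1_times: list[float] = []
    ms1_peaks: list[tuple[np.ndarray, np.ndarray]] = []
    ms2_by_window: dict[tuple[float, float], tuple[list, list]] = {}
    run_id = Path(path).stem
    ns = f"{{{_MZML_NS}}}"
    for _event, spec in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        params = {
            cv.get("name"): cv.get("value")
            for cv in spec.iterdescendants(f"{ns}cvParam")
        }
        level = int(params["ms level"])
        t = float(params["scan start time"])
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iterdescendants(f"{ns}binaryDataArray"):
            names = {cv.get("name") for cv in bda.iterfind(f"{ns}cvParam")}
            kind = "m/z array" if "m/z array" in names else "intensity array"
            node = bda.find(f"{ns}binary")
            arrays[kind] = _decode_array(node.text or "")
        mz = arrays.get("m/z array", np.empty(0))
        inten = arrays.get("intensity array", np.empty(0))
        if level == 1:
            ms1_times.append(t)
            ms1_peaks.append((mz, inten))
        else:
            target = float(params["isolation window target m/z"])
            lo = target - float(params["isolation window lower offset"])
            hi = target + float(params["isolation window upper offset"])
            times, peaks = ms2_by_window.setdefault((round(lo, 6), round(hi, 6)), ([], []))
            times.append(t)
            peaks.append((mz, inten))
        spec.clear(keep_tail=True)
    windows = sorted(ms2_by_window)
    ms2 = {
        w: ScanSeries.from_scan_lists(np.array(ms2_by_window[win][0]), ms2_by_window[win][1])
        for w, win in enumerate(windows)
    }
    return Run(
        run_id=run_id,
        mode="unknown",
        column_mode="unknown",
        gradient_id="unknown",
        sample_id=None,
        ms1=ScanSeries.from_scan_lists(np.array(ms1_times), ms1_peaks),
        ms2=ms2,
        swath_windows=[(lo, hi) for lo, hi in windows],
    )


# ---------------------------------------------------------------------------
# MSP (delegated to matchms)
# ---------------------------------------------------------------------------

def write_msp(records, path: str | Path) -> None:
    """Write spectra to MSP. ``records`` are matchms ``Spectrum`` objects."""
    from matchms.exporting import save_as_msp

    p = Path(path)
    if p.exists():
        p.unlink()
    save_as_msp(list(records), str(p))


def read_msp(path: str | Path):
    """Load MSP spectra as a list of matchms ``Spectrum`` objects."""
    from matchms.importing import load_from_msp

    return list(load_from_msp(str(path)))
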