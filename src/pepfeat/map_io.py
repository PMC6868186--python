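"""Reading MS1 spectra and rasterising them into the RT x m/z grid.

An LC-MS run is consumed as its MS1 spectra only and rendered as a sparse
2-D greyscale image: rows are MS scans (the RT axis, one row per scan),
columns are m/z bins of fixed width (0.01 m/z by default), and the grey
value encodes intensity on a 0-255 scale. The networks downstream consume
rectangular frames cut from this image.

Intensity-to-grey scaling is per-map ``round(255 * log1p(I) / log1p(I_max))``
by default; MS intensities span several orders of magnitude, and a log scale
keeps low-abundance isotopes visible next to intense ones. A linear scaling
is available via ``scaling="linear"``. Non-zero cells are floored at grey 1
so that zero grey means exactly "no signal".
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp
from pyteomics import ms1 as _ms1
from pyteomics import mzml as _mzml

__all__ = [
    "SpectrumScan", "LCMSMap", "FrameSpec",
    "read_ms1", "rasterize", "extract_frame", "save_map", "load_map",
]


@dataclass
class SpectrumScan:
    """One MS1 spectrum: acquisition order, retention time (minutes), peaks."""

    scan_index: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity in scan")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self):
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass(frozen=True)
class FrameSpec:
    """Window geometry: ``m`` scans (rows) by ``n`` m/z bins (columns)."""

    m: int = 15
    n: int = 211

    def __post_init__(self):
        if self.m < 1 or self.n < 1:
            raise ValueError("frame dimensions must be >= 1")

    @property
    def mz_span(self) -> float:
        return self.n * 0.01


@dataclass
class LCMSMap:
    """Sparse RT-scan x m/z-bin grid of raw intensities and grey values.

    Bin ``b`` covers the half-open m/z interval
    ``[mz_min + b*w, mz_min + (b+1)*w)``.
    """

    mz_min: float
    mz_bin_width: float
    rt_of_scan: np.ndarray
    raw: sp.csr_matrix
    grey: sp.csr_matrix
    scaling: str = "log"
    _grey_dense: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_scans(self) -> int:
        return self.raw.shape[0]

    @property
    def n_bins(self) -> int:
        return self.raw.shape[1]

    @property
    def mz_max(self) -> float:
        return self.mz_min + self.n_bins * self.mz_bin_width

    def bin_of_mz(self, mz: float) -> int:
        return int(np.floor((mz - self.mz_min) / self.mz_bin_width))

    def mz_center(self, b) -> float | np.ndarray:
        return self.mz_min + (np.asarray(b) + 0.5) * self.mz_bin_width

    def grey_dense(self) -> np.ndarray:
        """Dense uint8 grey image, cached (used by the frame scanners)."""
        if self._grey_dense is None:
            self._grey_dense = np.asarray(self.grey.todense(), dtype=np.uint8)
        return self._grey_dense

    def scan_spacing(self, scan: int) -> float:
        """Local RT spacing (minutes) around one scan."""
        rt = self.rt_of_scan
        if len(rt) < 2:
            return 0.01
        if scan <= 0:
            return float(rt[1] - rt[0])
        if scan >= len(rt) - 1:
            return float(rt[-1] - rt[-2])
        return float((rt[scan + 1] - rt[scan - 1]) / 2.0)


# ---------------------------------------------------------------------------
# reading


def _read_ms1_text(path: str) -> list[SpectrumScan]:
    scans = []
    try:
        with _ms1.read(path) as reader:
            for i, spec in enumerate(reader):
                rt = spec["params"].get("RTime")
                if rt is None:
                    raise ValueError(f"{path}: scan {i} has no RTime header")
                scans.append(SpectrumScan(i, float(rt),
                                          spec["m/z array"], spec["intensity array"]))
    except ValueError:
        raise
    except Exception as exc:  # locate the offending line for the message
        lineno = _first_bad_line(path)
        raise ValueError(f"{path}: unparseable MS1 content at line {lineno}: {exc}") from exc
    return scans


def _first_bad_line(path: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s[0] in "HSIZD":
                continue
            parts = s.split()
            try:
                float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                return lineno
    return 0


def _read_mzml(path: str) -> list[SpectrumScan]:
    scans = []
    i = 0
    with _mzml.read(path) as reader:
        for spec in reader:
            if spec.get("ms level") != 1:
                continue
            rt = spec["scanList"]["scan"][0]["scan start time"]
            unit = getattr(rt, "unit_info", "minute")
            rt_min = float(rt) / 60.0 if unit in ("second", "seconds") else float(rt)
            scans.append(SpectrumScan(i, rt_min, spec["m/z array"], spec["intensity array"]))
            i += 1
    return scans


def read_ms1(path: str) -> list[SpectrumScan]:
    """Read MS1-level spectra from an ``.ms1`` text file or an mzML file.

    Spectra are returned ordered by retention time with 0-based scan indices;
    MS2 (and higher) spectra in mzML input are skipped.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty file")
    if path.lower().endswith((".mzml", ".mzml.gz")):
        scans = _read_mzml(path)
    else:
        scans = _read_ms1_text(path)
    if not scans:
        raise ValueError(f"{path}: no MS1 spectra found")
    scans.sort(key=lambda s: s.rt)
    for i, s in enumerate(scans):
        s.scan_index = i
    return scans


def write_ms1(scans: list[SpectrumScan], path: str) -> None:
    """Write scans in the simple S/I-line MS1 text dialect (6-decimal peaks)."""
    with open(path, "w") as fh:
        fh.write("H\tExtractor\tpepfeat\n")
        for s in scans:
            fh.write(f"S\t{s.scan_index + 1}\t{s.scan_index + 1}\n")
            fh.write(f"I\tRTime\t{s.rt:.6f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.6f}\n")


# ---------------------------------------------------------------------------
# rasterisation


def _grey_from_raw(values: np.ndarray, raw_max: float, scaling: str) -> np.ndarray:
    if raw_max <= 0:
        raw_max = 1.0
    if scaling == "log":
        g = np.round(255.0 * np.log1p(values) / np.log1p(raw_max))
    elif scaling == "linear":
        g = np.round(255.0 * values / raw_max)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    g = np.clip(g, 0, 255)
    g[(values > 0) & (g < 1)] = 1.0  # grey 0 must mean "no signal"
    return g.astype(np.uint8)


def rasterize(scans: list[SpectrumScan], mz_bin_width: float = 0.01,
              mz_min: float | None = None, mz_max: float | None = None,
              scaling: str = "log") -> LCMSMap:
    """Bin peaks into the sparse RT x m/z grid and grey-scale it.

    Peaks falling into the same cell are summed (abundance is additive).
    """
    if not scans:
        raise ValueError("need at least one scan")
    if mz_bin_width <= 0:
        raise ValueError("bin width must be positive")
    all_mz = np.concatenate([s.mz for s in scans]) if any(len(s.mz) for s in scans) \
        else np.array([0.0])
    if mz_min is None:
        mz_min = float(np.floor(all_mz.min() / mz_bin_width) * mz_bin_width) if all_mz.size else 0.0
    if mz_max is None:
        mz_max = float(all_mz.max()) + mz_bin_width if all_mz.size else mz_bin_width
    n_bins = max(int(np.ceil((mz_max - mz_min) / mz_bin_width)), 1)
    rows, cols, vals = [], [], []
    rts = np.empty(len(scans))
    for i, s in enumerate(scans):
        rts[i] = s.rt
        if len(s.mz) == 0:
            continue
        b = np.floor((s.mz - mz_min) / mz_bin_width).astype(np.int64)
        ok = (b >= 0) & (b < n_bins) & (s.intensity > 0)
        rows.append(np.full(int(ok.sum()), i, dtype=np.int64))
        cols.append(b[ok])
        vals.append(s.intensity[ok])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:
        rows = cols = np.empty(0, dtype=np.int64)
        vals = np.empty(0)
    raw = sp.coo_matrix((vals, (rows, cols)), shape=(len(scans), n_bins)).tocsr()
    raw.sum_duplicates()
    raw_max = float(raw.data.max()) if raw.nnz else 0.0
    grey = raw.copy()
    grey.data = _grey_from_raw(raw.data, raw_max, scaling).astype(np.float64)
    grey = grey.astype(np.uint8)
    return LCMSMap(mz_min=mz_min, mz_bin_width=mz_bin_width, rt_of_scan=rts,
                   raw=raw, grey=grey, scaling=scaling)


def extract_frame(lcms_map: LCMSMap, scan_start: int, bin_start: int,
                  spec: FrameSpec) -> np.ndarray:
    """Grey-value frame of ``spec.m`` scans x ``spec.n`` bins, zero-padded
    wherever the window leaves the map."""
    out = np.zeros((spec.m, spec.n), dtype=np.uint8)
    g = lcms_map.grey_dense()
    r0, r1 = max(scan_start, 0), min(scan_start + spec.m, g.shape[0])
    c0, c1 = max(bin_start, 0), min(bin_start + spec.n, g.shape[1])
    if r1 > r0 and c1 > c0:
        out[r0 - scan_start:r1 - scan_start, c0 - bin_start:c1 - bin_start] = g[r0:r1, c0:c1]
    return out


# ---------------------------------------------------------------------------
# map cache


def save_map(lcms_map: LCMSMap, path: str) -> None:
    coo = lcms_map.raw.tocoo()
    grey = lcms_map.grey.tocoo()
    with h5py.File(path, "w") as f:
        f.attrs["mz_min"] = lcms_map.mz_min
        f.attrs["mz_bin_width"] = lcms_map.mz_bin_width
        f.attrs["n_scans"] = lcms_map.n_scans
        f.attrs["n_bins"] = lcms_map.n_bins
        f.attrs["scaling"] = lcms_map.scaling
        f.create_dataset("rt_of_scan", data=lcms_map.rt_of_scan)
        f.create_dataset("scan_idx", data=coo.row)
        f.create_dataset("bin_idx", data=coo.col)
        f.create_dataset("raw", data=coo.data)
        f.create_dataset("grey", data=grey.data.astype(np.uint8))


def load_map(path: str) -> LCMSMap:
    with h5py.File(path, "r") as f:
        shape = (int(f.attrs["n_scans"]), int(f.attrs["n_bins"]))
        row = f["scan_idx"][:]
        col = f["bin_idx"][:]
        raw = sp.coo_matrix((f["raw"][:], (row, col)), shape=shape).tocsr()
        grey = sp.coo_matrix((f["grey"][:].astype(np.uint8), (row, col)),
                             shape=shape).tocsr()
        return LCMSMap(mz_min=float(f.attrs["mz_min"]),
                       mz_bin_width=float(f.attrs["mz_bin_width"]),
                       rt_of_scan=f["rt_of_scan"][:], raw=raw, grey=grey,
                       scaling=str(f.attrs["scaling"]))
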