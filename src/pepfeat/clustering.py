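"""From per-pixel detections to isotope records and equidistant clusters.

Detections are condensed per m/z column into RT runs, merged across
adjacent columns (a wide isotope spans several bins; the merged record is
keyed by its intensity-weighted m/z centroid), and filed into nine
per-charge hash tables. Records in one table that sit ``1.00335/z`` apart
with overlapping elution are then grouped into clusters — the batched unit
of work for the grouping model. A cluster may hold several features; where
one feature ends and the next begins is decided downstream, not here.

Clusters are the connected components of the pairwise join predicate
(spacing within tolerance and RT overlap), so the result is exactly the
transitive closure of the join relation, with no cap on cluster size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotopes import MAX_CHARGE, MIN_CHARGE, isotope_spacing
from .map_io import LCMSMap

__all__ = [
    "IsotopeRecord", "IsotopeHashTables", "IsotopeCluster",
    "record_detections", "build_clusters", "batch_clusters",
]


@dataclass
class IsotopeRecord:
    """One detected isotope trace: charge, centroid m/z, elution extent."""

    charge: int
    mz: float                    # intensity-weighted centroid, Da
    scan_first: int
    scan_last: int               # inclusive
    intensities: np.ndarray      # raw per-scan intensity, scan_first..scan_last
    apex_scan: int
    bins: tuple = ()             # contributing m/z bins

    def __post_init__(self):
        if not self.scan_first <= self.apex_scan <= self.scan_last:
            raise ValueError("apex must lie inside the scan range")

    @property
    def rt_scan_range(self):
        return (self.scan_first, self.scan_last)

    def overlaps(self, other: "IsotopeRecord", min_scans: int = 1) -> bool:
        lo = max(self.scan_first, other.scan_first)
        hi = min(self.scan_last, other.scan_last)
        return hi - lo + 1 >= min_scans


class IsotopeHashTables:
    """Nine per-charge maps from m/z key to isotope records."""

    def __init__(self):
        self.tables: dict[int, dict[float, list]] = {z: {} for z in
                                                     range(MIN_CHARGE, MAX_CHARGE + 1)}

    def insert(self, record: IsotopeRecord) -> None:
        self.tables[record.charge].setdefault(record.mz, []).append(record)

    def records(self, charge: int) -> list:
        out = []
        for recs in self.tables[charge].values():
            out.extend(recs)
        out.sort(key=lambda r: (r.mz, r.scan_first))
        return out

    def all_records(self) -> list:
        out = []
        for z in self.tables:
            out.extend(self.records(z))
        return out

    def __len__(self):
        return sum(len(v) for t in self.tables.values() for v in t.values())


@dataclass
class IsotopeCluster:
    """Equidistant, charge-consistent isotope group, ordered by m/z."""

    charge: int
    isotopes: list = field(default_factory=list)

    def __len__(self):
        return len(self.isotopes)

    def __iter__(self):
        return iter(self.isotopes)


# ---------------------------------------------------------------------------
# step-1 output -> hash tables


def _runs(labels: dict[int, int]):
    """Maximal runs of consecutive scans with identical class."""
    if not labels:
        return
    scans = sorted(labels)
    start = prev = scans[0]
    cls = labels[start]
    for s in scans[1:]:
        if s == prev + 1 and labels[s] == cls:
            prev = s
            continue
        yield cls, start, prev
        start = prev = s
        cls = labels[s]
    yield cls, start, prev


def record_detections(table, lcms_map: LCMSMap) -> IsotopeHashTables:
    """Condense the detection table into per-charge isotope records.

    Per column, maximal same-class scan runs become provisional isotopes;
    provisional isotopes in adjacent bins with equal charge and overlapping
    RT runs are merged, with centroid m/z = sum(raw*mz)/sum(raw) over the
    contributing cells.
    """
    provisional = []  # (charge, bin, s0, s1)
    for b in table.columns():
        for cls, s0, s1 in _runs(table.column(b)):
            provisional.append((cls, b, s0, s1))
    # union-find over adjacent-bin same-charge overlapping runs
    parent = list(range(len(provisional)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_key = {}
    for i, (z, b, s0, s1) in enumerate(provisional):
        by_key.setdefault((z, b), []).append(i)
    for i, (z, b, s0, s1) in enumerate(provisional):
        for j in by_key.get((z, b + 1), ()):
            _, _, t0, t1 = provisional[j]
            if min(s1, t1) >= max(s0, t0):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list] = {}
    for i in range(len(provisional)):
        groups.setdefault(find(i), []).append(i)

    raw = lcms_map.raw.tocsc()
    tables = IsotopeHashTables()
    for members in groups.values():
        z = provisional[members[0]][0]
        s0 = min(provisional[i][2] for i in members)
        s1 = max(provisional[i][3] for i in members)
        bins = sorted({provisional[i][1] for i in members})
        inten = np.zeros(s1 - s0 + 1)
        num = 0.0
        den = 0.0
        for i in members:
            _, b, t0, t1 = provisional[i]
            col = np.asarray(raw[t0:t1 + 1, b].todense()).ravel()
            inten[t0 - s0:t1 - s0 + 1] += col
            num += float(col.sum()) * lcms_map.mz_center(b)
            den += float(col.sum())
        mz = num / den if den > 0 else float(np.mean([lcms_map.mz_center(b) for b in bins]))
        apex = s0 + int(np.argmax(inten))
        tables.insert(IsotopeRecord(charge=z, mz=mz, scan_first=s0, scan_last=s1,
                                    intensities=inten, apex_scan=apex,
                                    bins=tuple(bins)))
    return tables


# ---------------------------------------------------------------------------
# hash tables -> clusters


def _joined(r1: IsotopeRecord, r2: IsotopeRecord, spacing: float,
            mz_tol: float, min_overlap: int) -> bool:
    """Join predicate: r2 continues r1's ladder (r1.mz < r2.mz)."""
    return (abs(r2.mz - r1.mz - spacing) <= mz_tol
            and r1.overlaps(r2, min_overlap))


def build_clusters(tables: IsotopeHashTables, mz_tol: float = 0.01,
                   min_overlap_scans: int = 1) -> list:
    """Group equidistant, RT-overlapping records of each charge table.

    Implemented as connected components of the pairwise join predicate
    (equivalent to its transitive closure); singleton records form
    singleton clusters and are weeded out downstream. No limit is placed on
    cluster size.
    """
    clusters = []
    for z in range(MIN_CHARGE, MAX_CHARGE + 1):
        recs = tables.records(z)
        if not recs:
            continue
        spacing = isotope_spacing(z)
        mzs = np.array([r.mz for r in recs])
        parent = list(range(len(recs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, r in enumerate(recs):
            lo = np.searchsorted(mzs, r.mz + spacing - mz_tol, side="left")
            hi = np.searchsorted(mzs, r.mz + spacing + mz_tol, side="right")
            for j in range(int(lo), int(hi)):
                if _joined(r, recs[j], spacing, mz_tol, min_overlap_scans):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        comp: dict[int, list] = {}
        for i in range(len(recs)):
            comp.setdefault(find(i), []).append(recs[i])
        for members in comp.values():
            members.sort(key=lambda r: r.mz)
            clusters.append(IsotopeCluster(charge=z, isotopes=members))
    clusters.sort(key=lambda c: (c.charge, c.isotopes[0].mz))
    return clusters


def batch_clusters(clusters: list, batch_size: int = 500) -> list:
    """Order-preserving partition into batches of ``batch_size`` clusters."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    return [clusters[i:i + batch_size] for i in range(0, len(clusters), batch_size)]


def clusters_to_frame(clusters: list) -> pd.DataFrame:
    """Debug dump: one row per record with its cluster id."""
    rows = []
    for cid, cl in enumerate(clusters):
        for r in cl:
            rows.append({"cluster": cid, "charge": r.charge, "mz": r.mz,
                         "rt_start_scan": r.scan_first, "rt_end_scan": r.scan_last})
    return pd.DataFrame(rows, columns=["cluster", "charge", "mz",
                                       "rt_start_scan", "rt_end_scan"])
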