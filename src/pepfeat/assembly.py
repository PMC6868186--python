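"""Assembling grouped isotopes into the final feature table.

A reported feature carries the monoisotope m/z (centroid of its first
isotope), the charge, each isotope's RT range, and an intensity equal to
the sum of the isotopes' areas under their elution curves. Areas are
trapezoidal integrals of the observed per-scan intensities against RT in
minutes — assumption-free and robust; a single-scan trace contributes its
point intensity times the local scan spacing instead of the zero a bare
trapezoid would give.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .clustering import IsotopeCluster, IsotopeRecord
from .isotopes import isotope_spacing
from .map_io import LCMSMap

__all__ = [
    "PeptideFeature", "FeatureTable", "compute_isotope_auc",
    "assemble_features", "write_feature_table", "read_feature_table",
]

from dataclasses import dataclass, field


@dataclass
class IsotopeEntry:
    mz: float
    rt_start: float   # minutes
    rt_end: float
    auc: float


@dataclass
class PeptideFeature:
    mono_mz: float
    charge: int
    isotopes: list              # of IsotopeEntry, ascending m/z
    rt_apex: float              # minutes, monoisotope apex
    intensity: float = None

    def __post_init__(self):
        if len(self.isotopes) < 2:
            raise ValueError("a feature needs at least 2 isotopes")
        total = float(sum(i.auc for i in self.isotopes))
        if self.intensity is None:
            self.intensity = total
        self.isotopes.sort(key=lambda i: i.mz)

    @property
    def n_isotopes(self) -> int:
        return len(self.isotopes)

    @property
    def rt_start(self) -> float:
        return min(i.rt_start for i in self.isotopes)

    @property
    def rt_end(self) -> float:
        return max(i.rt_end for i in self.isotopes)


@dataclass
class FeatureTable:
    features: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "mono_mz": f.mono_mz, "charge": f.charge, "rt_start": f.rt_start,
            "rt_end": f.rt_end, "rt_apex": f.rt_apex,
            "n_isotopes": f.n_isotopes, "intensity": f.intensity,
            "isotopes": json.dumps([[i.mz, i.rt_start, i.rt_end, i.auc]
                                    for i in f.isotopes]),
        } for f in self.features]
        return pd.DataFrame(rows, columns=["mono_mz", "charge", "rt_start",
                                           "rt_end", "rt_apex", "n_isotopes",
                                           "intensity", "isotopes"])


def compute_isotope_auc(record: IsotopeRecord, rt_of_scan: np.ndarray) -> float:
    """Trapezoidal area (intensity x minutes) of a record's elution profile.

    Single-scan records get point intensity x local scan spacing so real
    one-scan signal is not erased.
    """
    s0, s1 = record.scan_first, record.scan_last
    if record.intensities.size == 0:
        raise ValueError("empty isotope record")
    if s0 == s1:
        if len(rt_of_scan) < 2:
            spacing = 0.01
        elif s0 >= len(rt_of_scan) - 1:
            spacing = float(rt_of_scan[-1] - rt_of_scan[-2])
        elif s0 <= 0:
            spacing = float(rt_of_scan[1] - rt_of_scan[0])
        else:
            spacing = float((rt_of_scan[s0 + 1] - rt_of_scan[s0 - 1]) / 2.0)
        return float(record.intensities[0]) * spacing
    return float(np.trapezoid(record.intensities, rt_of_scan[s0:s1 + 1]))


def _tail_record(cluster: IsotopeCluster, lcms_map: LCMSMap, idx: int,
                 anchor: IsotopeRecord) -> IsotopeRecord | None:
    """Materialise an isotope the detection stage could not record.

    The last isotope of a feature has nothing to its right confirming the
    charge, so it never enters the hash tables; when the grouping stage
    decides a feature extends past the cluster's records, its trace is
    read directly from the map at the extrapolated ladder position, over
    the anchor isotope's elution range. Returns None when the map holds no
    signal there.
    """
    recs = cluster.isotopes
    d = isotope_spacing(cluster.charge)
    mz = recs[-1].mz + (idx - (len(recs) - 1)) * d
    b = lcms_map.bin_of_mz(mz)
    if not 1 <= b < lcms_map.n_bins - 1:
        return None
    s0, s1 = anchor.scan_first, anchor.scan_last
    sub = np.asarray(lcms_map.raw[s0:s1 + 1, b - 1:b + 2].todense())
    col = sub.sum(axis=1)
    if col.max() <= 0:
        return None
    nz = np.nonzero(col)[0]
    t0, t1 = int(nz[0]), int(nz[-1])
    inten = col[t0:t1 + 1]
    w = sub.sum(axis=0)
    centers = np.asarray(lcms_map.mz_center(np.array([b - 1, b, b + 1])))
    return IsotopeRecord(charge=cluster.charge,
                         mz=float((w * centers).sum() / w.sum()),
                         scan_first=s0 + t0, scan_last=s0 + t1,
                         intensities=inten,
                         apex_scan=s0 + t0 + int(np.argmax(inten)),
                         bins=(b - 1, b, b + 1))


def assemble_features(clusters: list, decisions: list, lcms_map: LCMSMap,
                      metadata: dict | None = None) -> FeatureTable:
    """Turn per-cluster feature spans into a deduplicated feature table.

    ``decisions[i]`` is the list of (start, end) isotope-index spans that
    the grouping stage reported for ``clusters[i]``; an end past the
    cluster's records pulls the missing tail isotopes from the map (see
    :func:`_tail_record`). Spans shorter than two isotopes are skipped.
    Duplicates — same charge, monoisotope within one m/z bin, overlapping
    monoisotope RT range — keep the higher-intensity entry.
    """
    rt = lcms_map.rt_of_scan
    candidates = []
    for cluster, spans in zip(clusters, decisions):
        for start, end in spans:
            recs = list(cluster.isotopes)
            for idx in range(len(recs), end + 1):
                r = _tail_record(cluster, lcms_map, idx, recs[start])
                if r is None:
                    break
                # isotope envelopes decay towards the tail: a materialised
                # "tail" clearly brighter than its predecessor is the next
                # feature's monoisotope, not part of this one (1.3 bounds
                # within-envelope ratios incl. bin-capture noise)
                prev_apex = float(recs[idx - 1].intensities.max())
                if float(r.intensities.max()) > 1.3 * prev_apex:
                    break
                recs.append(r)
            end = min(end, len(recs) - 1)
            if end - start + 1 < 2:
                continue
            entries = []
            for r in recs[start:end + 1]:
                entries.append(IsotopeEntry(mz=r.mz,
                                            rt_start=float(rt[r.scan_first]),
                                            rt_end=float(rt[r.scan_last]),
                                            auc=compute_isotope_auc(r, rt)))
            mono = recs[start]
            candidates.append((PeptideFeature(
                mono_mz=mono.mz, charge=cluster.charge, isotopes=entries,
                rt_apex=float(rt[mono.apex_scan])),
                float(rt[mono.scan_first]), float(rt[mono.scan_last])))

    candidates.sort(key=lambda c: -c[0].intensity)
    kept: list = []
    tol = lcms_map.mz_bin_width
    for feat, r0, r1 in candidates:
        dup = any(k.charge == feat.charge
                  and abs(k.mono_mz - feat.mono_mz) <= tol
                  and min(r1, kr1) >= max(r0, kr0)
                  for k, kr0, kr1 in kept)
        if not dup:
            kept.append((feat, r0, r1))
    table = FeatureTable([k[0] for k in kept], metadata or {})
    table.features.sort(key=lambda f: (f.mono_mz, f.charge))
    return table


# ---------------------------------------------------------------------------
# persistence


def write_feature_table(table: FeatureTable, path: str,
                        mztab: bool = False) -> None:
    """Write the feature CSV; with ``mztab=True`` write a minimal
    mzTab-like small-molecule section instead (SMH/SML rows)."""
    if not mztab:
        table.to_frame().to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        fh.write("MTD\tmzTab-version\t1.0\n")
        fh.write("SMH\tSML_ID\texp_mass_to_charge\tcharge\t"
                 "retention_time\tabundance_assay[1]\n")
        for i, f in enumerate(table, start=1):
            fh.write(f"SML\t{i}\t{f.mono_mz:.5f}\t{f.charge}\t"
                     f"{f.rt_apex * 60.0:.3f}\t{f.intensity:.4f}\n")


def read_feature_table(path: str) -> FeatureTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed feature table: {exc}") from exc
    feats = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            iso = [IsotopeEntry(*vals) for vals in json.loads(row.isotopes)]
            feats.append(PeptideFeature(mono_mz=float(row.mono_mz),
                                        charge=int(row.charge), isotopes=iso,
                                        rt_apex=float(row.rt_apex),
                                        intensity=float(row.intensity)))
        except (ValueError, TypeError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: bad feature at line {lineno}: {exc}") from exc
    return FeatureTable(feats)
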