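"""Isotope records, hash tables and equidistant clustering."""
import numpy as np
import pytest

from pepfeat.clustering import (IsotopeHashTables, IsotopeRecord,
                                batch_clusters, build_clusters,
                                record_detections)
from pepfeat.detector import DetectionTable
from pepfeat.isotopes import isotope_spacing
from pepfeat.map_io import SpectrumScan, rasterize


def _rec(z, mz, s0, s1, inten=1.0):
    n = s1 - s0 + 1
    return IsotopeRecord(charge=z, mz=mz, scan_first=s0, scan_last=s1,
                         intensities=np.full(n, inten), apex_scan=s0)


def _map_with(peaks, n_scans=30):
    """peaks: list of (scan, mz, intensity)."""
    per = {}
    for s, mz, inten in peaks:
        per.setdefault(s, []).append((mz, inten))
    scans = []
    for i in range(n_scans):
        pk = sorted(per.get(i, []))
        scans.append(SpectrumScan(i, 0.01 * i, np.array([p[0] for p in pk]),
                                  np.array([p[1] for p in pk])))
    return rasterize(scans, 0.01, mz_min=400.0, mz_max=410.0)


def test_record_detections_single_run():
    table = DetectionTable()
    for s in range(10, 21):
        table.add(s, 5, 2)
    m = _map_with([(s, 400.055, 100.0) for s in range(10, 21)])
    tables = record_detections(table, m)
    recs = tables.records(2)
    assert len(recs) == 1 and len(tables) == 1
    r = recs[0]
    assert (r.scan_first, r.scan_last) == (10, 20)
    assert r.mz == pytest.approx(400.055)


def test_record_detections_merges_adjacent_bins_weighted():
    table = DetectionTable()
    for s in range(5, 10):
        table.add(s, 0, 2)
        table.add(s, 1, 2)
    # intensities 100 in bin of 500.00... use map bins 0 (400.005) / 1 (400.015)
    peaks = [(s, 400.005, 100.0) for s in range(5, 10)]
    peaks += [(s, 400.015, 300.0) for s in range(5, 10)]
    m = _map_with(peaks)
    recs = record_detections(table, m).records(2)
    assert len(recs) == 1
    # weighted centroid: (100*400.005 + 300*400.015)/400
    assert recs[0].mz == pytest.approx(400.0125)
    np.testing.assert_allclose(recs[0].intensities, 400.0)


def test_record_detections_keeps_charges_separate():
    table = DetectionTable()
    for s in range(5, 10):
        table.add(s, 0, 2)
        table.add(s, 1, 3)
    m = _map_with([(s, 400.005, 10.0) for s in range(5, 10)]
                  + [(s, 400.015, 10.0) for s in range(5, 10)])
    tables = record_detections(table, m)
    assert len(tables.records(2)) == 1
    assert len(tables.records(3)) == 1


def test_build_clusters_chains_equidistant_overlapping_records():
    t = IsotopeHashTables()
    d = isotope_spacing(2)
    for i in range(3):
        t.insert(_rec(2, 500.0 + i * d, 10, 30))
    clusters = build_clusters(t, mz_tol=0.01)
    assert len(clusters) == 1 and len(clusters[0]) == 3


def test_build_clusters_splits_disjoint_rt():
    t = IsotopeHashTables()
    d = isotope_spacing(2)
    t.insert(_rec(2, 500.0, 10, 20))
    t.insert(_rec(2, 500.0 + d, 25, 35))  # same spacing, no RT overlap
    clusters = build_clusters(t, mz_tol=0.01)
    assert len(clusters) == 2


def test_cluster_may_span_multiple_features():
    # two 3-isotope ladders continuing each other end up in one cluster
    t = IsotopeHashTables()
    d = isotope_spacing(2)
    for i in range(6):
        t.insert(_rec(2, 500.0 + i * d, 10, 30))
    clusters = build_clusters(t, mz_tol=0.01)
    assert len(clusters) == 1 and len(clusters[0]) == 6


def _brute_force_clusters(records, z, mz_tol):
    """Independent oracle: transitive closure of the pairwise join predicate."""
    d = isotope_spacing(z)
    n = len(records)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lo, hi = records[i], records[j]
            if lo.mz > hi.mz:
                lo, hi = hi, lo
            if (abs(hi.mz - lo.mz - d) <= mz_tol
                    and min(lo.scan_last, hi.scan_last)
                    >= max(lo.scan_first, hi.scan_first)):
                adj[i][j] = adj[j][i] = True
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for j in range(n):
                if adj[k][j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("trial", range(20))
def test_build_clusters_equals_brute_force_closure(trial):
    rng = np.random.default_rng(1000 + trial)
    z = int(rng.integers(1, 5))
    d = isotope_spacing(z)
    n = int(rng.integers(2, 31))
    base = 500.0
    recs = []
    for _ in range(n):
        # mixture of ladder-aligned and arbitrary positions
        if rng.random() < 0.7:
            mz = base + int(rng.integers(0, 8)) * d + rng.normal(0, 0.004)
        else:
            mz = base + rng.uniform(-0.5, 4.5)
        s0 = int(rng.integers(0, 40))
        s1 = s0 + int(rng.integers(0, 15))
        recs.append(_rec(z, mz, s0, s1))
    t = IsotopeHashTables()
    for r in recs:
        t.insert(r)
    got = build_clusters(t, mz_tol=0.01)
    got_sets = {frozenset(recs.index(r) for r in c.isotopes) for c in got}
    assert got_sets == _brute_force_clusters(recs, z, 0.01)


def test_clustering_conserves_records_and_is_idempotent(small_sim, rng):
    _, lcms_map, truth = small_sim
    t = IsotopeHashTables()
    recs = []
    for i in range(25):
        r = _rec(int(rng.integers(1, 5)), 400 + rng.uniform(0, 8),
                 int(rng.integers(0, 30)), int(rng.integers(30, 40)))
        recs.append(r)
        t.insert(r)
    clusters = build_clusters(t)
    flat = [r for c in clusters for r in c.isotopes]
    assert len(flat) == len(recs) and set(map(id, flat)) == set(map(id, recs))
    # idempotence: reclustering the clustered records changes nothing
    t2 = IsotopeHashTables()
    for r in flat:
        t2.insert(r)
    again = build_clusters(t2)
    assert {frozenset(map(id, c.isotopes)) for c in again} == \
        {frozenset(map(id, c.isotopes)) for c in clusters}


def test_batch_clusters_partitions_in_order():
    clusters = list(range(1200))  # partitioning is type-agnostic
    batches = batch_clusters(clusters, 500)
    assert [len(b) for b in batches] == [500, 500, 200]
    assert sum(batches, []) == clusters
    assert batch_clusters([], 500) == []
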