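"""End-to-end orchestration: map -> detections -> clusters -> features.

The full inference pass: the detection model deep-scans every m/z column,
detections become per-charge isotope records and equidistant clusters, and
the grouping model (usually a soft-voting ensemble) resolves each cluster
into feature spans which are assembled into the final feature table with
AUC intensities.
"""
from __future__ import annotations

import logging
import time

from .assembly import FeatureTable, assemble_features
from .clustering import batch_clusters, build_clusters, record_detections
from .config import PipelineConfig
from .detector import DetectorNet, scan_map
from .grouper import scan_cluster
from .map_io import FrameSpec, LCMSMap

log = logging.getLogger("pepfeat")

__all__ = ["detect_features"]


def detect_features(lcms_map: LCMSMap, detector_net: DetectorNet, grouper,
                    config: PipelineConfig | None = None) -> FeatureTable:
    """Run the two-stage pipeline on one map and return its feature table.

    ``grouper`` is anything with ``predict(X, charge)`` — a single fitted
    grouping model or a soft-voting ensemble. Inference is deterministic
    for fixed weights.
    """
    cfg = config or PipelineConfig()
    t0 = time.time()
    table = scan_map(lcms_map, detector_net,
                     FrameSpec(cfg.detect_frame_m, cfg.detect_frame_n),
                     batch_size=cfg.scan_batch_size,
                     anchor_bins=cfg.anchor_bins)
    t1 = time.time()
    log.info("scan_map: %d detections in %.1fs", len(table), t1 - t0)
    tables = record_detections(table, lcms_map)
    clusters = build_clusters(tables, mz_tol=cfg.cluster_mz_tol)
    t2 = time.time()
    log.info("clustering: %d records -> %d clusters in %.1fs",
             len(tables), len(clusters), t2 - t1)
    gframe = FrameSpec(cfg.group_frame_m, cfg.group_frame_n)
    decisions = []
    for batch in batch_clusters(clusters, cfg.cluster_batch_size):
        for cluster in batch:
            decisions.append(scan_cluster(cluster, lcms_map, grouper, gframe))
    t3 = time.time()
    log.info("grouping: %d spans in %.1fs",
             sum(len(d) for d in decisions), t3 - t2)
    feats = assemble_features(clusters, decisions, lcms_map,
                              metadata={"config_hash": cfg.hash(),
                                        "n_clusters": len(clusters),
                                        "timings_s": {"scan": t1 - t0,
                                                      "cluster": t2 - t1,
                                                      "group": t3 - t2}})
    log.info("assembled %d features", len(feats))
    return feats
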