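"""Evaluation: tolerance matching, consensus labeling, intensity correlation.

A feature list is scored by how many reference identifications (m/z, RT,
optional charge/score) it explains: an identification matches a feature
when its m/z is within ``mz_tol`` of the feature's monoisotope m/z and its
RT falls inside the feature's RT range expanded by ``rt_tol`` (defaults
0.01 m/z and 0.2 min). Consensus labeling intersects two feature lists at
ppm-scaled tolerances to manufacture training labels from two independent
detectors. Intensity agreement between two matched lists is the Pearson
product-moment correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import FeatureTable

__all__ = [
    "IdentificationRecord", "MatchReport", "read_ids",
    "match_features_to_ids", "consensus_features",
    "intensity_correlation", "top_k_eval",
]


@dataclass
class IdentificationRecord:
    """One reference identification (e.g. an MS/MS hit)."""

    mz: float
    rt: float                 # minutes
    charge: int | None = None
    score: float | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("mz must be positive")


@dataclass
class MatchReport:
    n_ids: int
    n_matched: int
    pairs: list = field(default_factory=list)  # (id_index, feature_index)
    tolerances: dict = field(default_factory=dict)

    @property
    def fraction_matched(self) -> float | None:
        """Percent of identifications matched; None when there are no ids."""
        if self.n_ids == 0:
            return None
        return 100.0 * self.n_matched / self.n_ids


def read_ids(path: str, min_score: float | None = None) -> list:
    """Read identifications from delimited text with columns mz, rt
    (minutes) and optional charge / score; ``min_score`` filters on the
    score column when present."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    ids = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        rec = IdentificationRecord(
            mz=float(d[cols["mz"]]), rt=float(d[cols["rt"]]),
            charge=int(d[cols["charge"]]) if "charge" in cols and
            not pd.isna(d[cols["charge"]]) else None,
            score=float(d[cols["score"]]) if "score" in cols and
            not pd.isna(d[cols["score"]]) else None)
        if min_score is not None and rec.score is not None and rec.score <= min_score:
            continue
        ids.append(rec)
    return ids


def match_features_to_ids(features: FeatureTable, ids: list,
                          mz_tol: float = 0.01, rt_tol: float = 0.2) -> MatchReport:
    """Match each identification to its nearest-m/z qualifying feature.

    Qualifying: |id.mz - mono_mz| <= mz_tol, id RT inside the feature RT
    range widened by rt_tol, and equal charge when both sides carry one.
    Ties on m/z distance break on RT-apex distance, then feature index.
    """
    pairs = []
    feats = list(features)
    for i, rec in enumerate(ids):
        best = None
        for j, f in enumerate(feats):
            if rec.charge is not None and rec.charge != f.charge:
                continue
            dmz = abs(rec.mz - f.mono_mz)
            if dmz > mz_tol:
                continue
            if not (f.rt_start - rt_tol <= rec.rt <= f.rt_end + rt_tol):
                continue
            key = (dmz, abs(rec.rt - f.rt_apex), j)
            if best is None or key < best[0]:
                best = (key, j)
        if best is not None:
            pairs.append((i, best[1]))
    return MatchReport(n_ids=len(ids), n_matched=len(pairs), pairs=pairs,
                       tolerances={"mz_tol": mz_tol, "rt_tol": rt_tol})


def consensus_features(list_a: FeatureTable, list_b: FeatureTable,
                       ppm_tol: float = 10.0, rt_tol_min: float = 0.03) -> FeatureTable:
    """Features of A confirmed by B within ppm-scaled m/z tolerance, RT
    tolerance (on the apex) and equal charge — the intersection used to
    label training data from two independent detectors."""
    kept = []
    for f in list_a:
        tol = ppm_tol * 1e-6 * f.mono_mz
        for g in list_b:
            if (g.charge == f.charge and abs(g.mono_mz - f.mono_mz) <= tol
                    and abs(g.rt_apex - f.rt_apex) <= rt_tol_min):
                kept.append(f)
                break
    return FeatureTable(kept, dict(list_a.metadata))


def intensity_correlation(table_a: FeatureTable, table_b: FeatureTable,
                          report: MatchReport | None = None,
                          pairs: list | None = None,
                          log: bool = False) -> float | None:
    """Pearson r between matched features' intensities (None if undefined).

    ``pairs`` (or ``report.pairs``) hold (index_in_a, index_in_b); with
    ``log=True`` the correlation is computed on log10 intensities.
    """
    if pairs is None:
        pairs = report.pairs if report is not None else None
    if pairs is None:
        raise ValueError("need matched pairs")
    if len(pairs) < 3:
        return None
    fa, fb = list(table_a), list(table_b)
    x = np.array([fa[i].intensity for i, _ in pairs], dtype=float)
    y = np.array([fb[j].intensity for _, j in pairs], dtype=float)
    if log:
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def top_k_eval(features: FeatureTable, ids: list, k: int = 10000,
               mz_tol: float = 0.01, rt_tol: float = 0.2) -> MatchReport:
    """Match only the k most intense features (the high-confidence list)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(features, key=lambda f: -f.intensity)[:k]
    return match_features_to_ids(FeatureTable(order, dict(features.metadata)),
                                 ids, mz_tol=mz_tol, rt_tol=rt_tol)
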