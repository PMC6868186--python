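"""Synthetic LC-MS map generator with known ground truth.

Emulates the signal structure a feature detector must cope with:

* multi-isotope features whose isotopes sit exactly ``1.00335/z`` m/z apart,
* bell-shaped (Gaussian) elution profiles sharing one RT apex,
* isotope envelopes that decay with isotope index (Poisson/averagine-like,
  with the monoisotope usually the tallest peak),
* overlapping features, "adjacent" features continuing each other's isotope
  ladder, random noise traces, per-scan m/z jitter, and randomly dropped
  scans (broken signals).

The generator also cuts the two kinds of labeled training sequences the
networks consume, and writes maps as ``.ms1`` text so they round-trip
through :mod:`pepfeat.map_io`.

Ground-truth isotope areas are the *analytic* Gaussian integral
``h * sigma * sqrt(2*pi)``, not the integral of the rendered (possibly
scan-dropped) trace, so recovery error downstream measures the pipeline
rather than the simulator.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotopes import PROTON_MASS, isotope_spacing
from .map_io import FrameSpec, LCMSMap, SpectrumScan, extract_frame, rasterize, write_ms1

__all__ = [
    "SyntheticFeatureSpec", "SimulationConfig", "GroundTruthFeature",
    "GroundTruthTable", "DetectingSample", "GroupingSample",
    "sample_feature_specs", "render_map", "simulate_map",
    "make_detecting_samples", "make_grouping_samples", "augment_rare_charges",
    "write_truth_csv", "read_truth_csv", "simulate_to_files",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class SyntheticFeatureSpec:
    """Parameters of one simulated peptide feature."""

    mono_mz: float
    charge: int
    n_isotopes: int
    rt_apex: float            # minutes
    rt_sigma: float           # minutes
    apex_intensity: float     # abundance units of the monoisotope apex
    envelope: np.ndarray      # per-isotope relative heights, envelope[0] == 1

    def __post_init__(self):
        self.envelope = np.asarray(self.envelope, dtype=np.float64)
        if self.n_isotopes != len(self.envelope):
            raise ValueError("n_isotopes must equal len(envelope)")
        if self.n_isotopes < 2:
            raise ValueError("a feature needs at least 2 isotopes")
        if np.any(self.envelope <= 0):
            raise ValueError("envelope heights must be positive")

    def isotope_mz(self, i: int) -> float:
        return self.mono_mz + i * isotope_spacing(self.charge)


@dataclass
class SimulationConfig:
    """Map extent, feature population and corruption model for one run."""

    rt_start: float = 0.0
    rt_span: float = 3.0               # minutes
    scan_spacing: float = 0.01         # minutes per MS scan
    mz_min: float = 400.0
    mz_max: float = 440.0
    mz_bin_width: float = 0.01
    n_features: int = 100
    charge_probs: dict = field(default_factory=lambda: {1: 0.110, 2: 0.581,
                                                        3: 0.289, 4: 0.020})
    envelope_model: str = "averagine"  # or "mono_dominant"
    max_isotopes: int = 7
    min_envelope_frac: float = 0.05    # isotopes below this fraction of mono are dropped
    apex_intensity_range: tuple = (3e4, 1e6)   # log-uniform
    rt_sigma_range: tuple = (0.03, 0.07)
    noise_trace_density: float = 1.25  # traces per (Da * minute)
    noise_intensity_range: tuple = (1e2, 3e3)  # log-uniform
    noise_rt_sigma_range: tuple = (0.01, 0.03)
    missing_scan_probability: float = 0.05
    overlap_injection_rate: float = 0.10
    adjacent_feature_rate: float = 0.10
    mz_jitter_sigma: float = 0.002     # Da, per-scan centroid jitter
    truncation_frac: float = 0.01      # traces cut below this fraction of own apex
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("missing_scan_probability", "overlap_injection_rate",
                     "adjacent_feature_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rt_span <= 0 or self.mz_max <= self.mz_min:
            raise ValueError("map extent must be positive")
        total = sum(self.charge_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            self.charge_probs = {z: p / total for z, p in self.charge_probs.items()}

    @property
    def n_scans(self) -> int:
        return int(round(self.rt_span / self.scan_spacing))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class GroundTruthFeature:
    spec: SyntheticFeatureSpec
    isotope_scan_ranges: list          # [(first, last)] inclusive, per isotope
    isotope_auc: np.ndarray            # analytic, intensity*minutes
    total_intensity: float
    apex_scan: int


@dataclass
class GroundTruthTable:
    features: list
    noise_traces: list = field(default_factory=list)  # (mz, apex_scan, first, last)

    def __len__(self):
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


# ---------------------------------------------------------------------------
# feature sampling


def _envelope(cfg: SimulationConfig, mono_mz: float, charge: int,
              rng: np.random.Generator) -> np.ndarray:
    if cfg.envelope_model == "averagine":
        # Poisson-shaped heights with rate tied to the neutral mass, the
        # usual coarse model of peptide isotope distributions.
        neutral = mono_mz * charge - charge * PROTON_MASS
        lam = max(neutral / 1800.0, 0.05)
        heights = [lam ** i / math.factorial(i) for i in range(cfg.max_isotopes)]
    elif cfg.envelope_model == "mono_dominant":
        r = rng.uniform(0.3, 0.7)
        heights = [r ** i for i in range(cfg.max_isotopes)]
    else:
        raise ValueError(f"unknown envelope model {cfg.envelope_model!r}")
    env = np.array(heights) / heights[0]
    keep = np.nonzero(env >= cfg.min_envelope_frac)[0]
    n = max(int(keep[-1]) + 1, 2) if keep.size else 2
    return env[:n]


def _one_spec(cfg: SimulationConfig, rng: np.random.Generator,
              mono_lo: float, mono_hi: float, rt_lo: float, rt_hi: float,
              charge: int) -> SyntheticFeatureSpec:
    mono = rng.uniform(mono_lo, mono_hi)
    env = _envelope(cfg, mono, charge, rng)
    lo, hi = cfg.apex_intensity_range
    return SyntheticFeatureSpec(
        mono_mz=mono, charge=charge, n_isotopes=len(env),
        rt_apex=rng.uniform(rt_lo, rt_hi),
        rt_sigma=rng.uniform(*cfg.rt_sigma_range),
        apex_intensity=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        envelope=env)


def sample_feature_specs(cfg: SimulationConfig,
                         rng: np.random.Generator | None = None) -> list:
    """Draw feature specs honouring the configured charge distribution and
    the requested overlap/adjacency fractions."""
    rng = cfg.rng() if rng is None else rng
    if cfg.n_features == 0:
        return []
    widest = cfg.max_isotopes * isotope_spacing(min(cfg.charge_probs))
    mono_lo = cfg.mz_min + 0.5
    mono_hi = cfg.mz_max - widest - 0.5
    rt_margin = 3.1 * cfg.rt_sigma_range[1]
    rt_lo = cfg.rt_start + rt_margin
    rt_hi = cfg.rt_start + cfg.rt_span - rt_margin
    if mono_hi <= mono_lo or rt_hi <= rt_lo:
        raise ValueError("map extent too small to place features")

    zs = np.array(sorted(cfg.charge_probs))
    ps = np.array([cfg.charge_probs[z] for z in zs])
    charges = rng.choice(zs, size=cfg.n_features, p=ps)

    n_adj = int(round(cfg.adjacent_feature_rate * cfg.n_features))
    n_olap = int(round(cfg.overlap_injection_rate * cfg.n_features))
    n_free = cfg.n_features - n_adj - n_olap
    if n_free < 1:
        raise ValueError("overlap and adjacency rates leave no free features")

    specs = [_one_spec(cfg, rng, mono_lo, mono_hi, rt_lo, rt_hi, int(z))
             for z in charges[:n_free]]
    for z in charges[n_free:n_free + n_olap]:
        # placed within one detection-frame width of an existing feature,
        # with overlapping elution
        partner = specs[rng.integers(len(specs))]
        s = _one_spec(cfg, rng, mono_lo, mono_hi, rt_lo, rt_hi, int(z))
        s.mono_mz = float(np.clip(partner.mono_mz + rng.uniform(-2.0, 2.0),
                                  mono_lo, mono_hi))
        s.rt_apex = float(np.clip(partner.rt_apex + rng.uniform(-1, 1) * partner.rt_sigma,
                                  rt_lo, rt_hi))
        specs.append(s)
    for _ in range(n_adj):
        # continues the partner's isotope ladder at the same charge: the
        # hard case where one cluster holds two features
        partner = specs[rng.integers(len(specs))]
        z = partner.charge
        d = isotope_spacing(z)
        s = _one_spec(cfg, rng, mono_lo, mono_hi, rt_lo, rt_hi, z)
        s.mono_mz = partner.mono_mz + partner.n_isotopes * d
        if s.mono_mz > mono_hi:
            s.mono_mz = partner.mono_mz - s.n_isotopes * d
        s.rt_apex = float(np.clip(partner.rt_apex + rng.uniform(-0.5, 0.5) * partner.rt_sigma,
                                  rt_lo, rt_hi))
        specs.append(s)
    return specs


# ---------------------------------------------------------------------------
# rendering


def _paint_trace(peaks_per_scan, rt, mz0, height, apex_rt, sigma, trunc,
                 jitter_sigma, rng):
    """Add a Gaussian-in-RT trace; returns (first_scan, last_scan) or None."""
    half = sigma * math.sqrt(2.0 * math.log(1.0 / trunc))
    s0 = int(np.searchsorted(rt, apex_rt - half, side="left"))
    s1 = int(np.searchsorted(rt, apex_rt + half, side="right")) - 1
    s0 = max(s0, 0)
    s1 = min(s1, len(rt) - 1)
    if s1 < s0:
        return None
    t = rt[s0:s1 + 1]
    inten = height * np.exp(-0.5 * ((t - apex_rt) / sigma) ** 2)
    keep = inten >= trunc * height
    if not keep.any():
        return None
    idx = np.nonzero(keep)[0]
    jit = rng.normal(0.0, jitter_sigma, size=idx.size) if jitter_sigma > 0 else 0.0
    for k, scan in enumerate(idx):
        peaks_per_scan[s0 + scan].append((mz0 + (jit[k] if jitter_sigma > 0 else 0.0),
                                          inten[scan]))
    return int(s0 + idx[0]), int(s0 + idx[-1])


def render_map(specs: list, cfg: SimulationConfig,
               rng: np.random.Generator | None = None):
    """Paint features and noise onto scans, drop scans, rasterize.

    Returns ``(LCMSMap, GroundTruthTable)``. Dropped scans keep their RT row
    but lose every peak, emulating broken signals; truth is computed from the
    un-dropped traces.
    """
    rng = cfg.rng() if rng is None else rng
    n_scans = cfg.n_scans
    rt = cfg.rt_start + np.arange(n_scans) * cfg.scan_spacing
    peaks_per_scan: list[list] = [[] for _ in range(n_scans)]

    truth_features = []
    for spec in specs:
        ranges, aucs = [], []
        for i in range(spec.n_isotopes):
            h = spec.apex_intensity * spec.envelope[i]
            rng_i = _paint_trace(peaks_per_scan, rt, spec.isotope_mz(i), h,
                                 spec.rt_apex, spec.rt_sigma, cfg.truncation_frac,
                                 cfg.mz_jitter_sigma, rng)
            if rng_i is None:
                rng_i = (0, -1)
            ranges.append(rng_i)
            aucs.append(h * spec.rt_sigma * SQRT_2PI)
        aucs = np.asarray(aucs)
        apex_scan = int(np.clip(round((spec.rt_apex - cfg.rt_start) / cfg.scan_spacing),
                                0, n_scans - 1))
        truth_features.append(GroundTruthFeature(
            spec=spec, isotope_scan_ranges=ranges, isotope_auc=aucs,
            total_intensity=float(aucs.sum()), apex_scan=apex_scan))

    noise_traces = []
    area = (cfg.mz_max - cfg.mz_min) * cfg.rt_span
    n_noise = int(rng.poisson(cfg.noise_trace_density * area))
    lo, hi = cfg.noise_intensity_range
    for _ in range(n_noise):
        mz0 = rng.uniform(cfg.mz_min + 0.2, cfg.mz_max - 0.2)
        apex_rt = rng.uniform(cfg.rt_start, cfg.rt_start + cfg.rt_span)
        h = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        sigma = rng.uniform(*cfg.noise_rt_sigma_range)
        r = _paint_trace(peaks_per_scan, rt, mz0, h, apex_rt, sigma,
                         cfg.truncation_frac, cfg.mz_jitter_sigma, rng)
        if r is not None:
            apex_scan = int(np.clip(round((apex_rt - cfg.rt_start) / cfg.scan_spacing),
                                    0, n_scans - 1))
            noise_traces.append((mz0, apex_scan, r[0], r[1]))

    dropped = rng.random(n_scans) < cfg.missing_scan_probability
    scans = []
    for i in range(n_scans):
        pk = [] if dropped[i] else peaks_per_scan[i]
        mz = np.array([p[0] for p in pk])
        inten = np.array([p[1] for p in pk])
        scans.append(SpectrumScan(i, float(rt[i]), mz, inten))
    lcms_map = rasterize(scans, cfg.mz_bin_width, mz_min=cfg.mz_min, mz_max=cfg.mz_max)
    return lcms_map, GroundTruthTable(truth_features, noise_traces)


def simulate_map(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    rng = cfg.rng() if rng is None else rng
    specs = sample_feature_specs(cfg, rng)
    return render_map(specs, cfg, rng)


# ---------------------------------------------------------------------------
# training samples


@dataclass
class DetectingSample:
    """One charge-labeling training sequence for the detection model."""

    frames: np.ndarray   # (T, M, N) uint8 grey
    labels: np.ndarray   # (T,) int8, 0-9
    mask: np.ndarray     # (T,) bool, False on padded frames
    charge: int          # 0 for negatives


@dataclass
class GroupingSample:
    """One 5-frame grouping sequence with its last-isotope label."""

    frames: np.ndarray   # (5, 15, 10) uint8 grey
    charge: int          # 1-9 (context charge fed to the network)
    label: int           # 0-4


def _feature_bins(lcms_map: LCMSMap, truth: GroundTruthTable) -> np.ndarray:
    bins = [lcms_map.bin_of_mz(f.spec.isotope_mz(i))
            for f in truth for i in range(f.spec.n_isotopes)]
    return np.unique(np.asarray(bins, dtype=np.int64)) if bins else np.empty(0, np.int64)


def make_detecting_samples(lcms_map: LCMSMap, truth: GroundTruthTable,
                           frame_spec: FrameSpec, n_negative: int,
                           rng: np.random.Generator, seq_len: int = 20) -> list:
    """Cut labeled 20-frame sequences.

    Positives are m/z-aligned so the monoisotope sits at the frame's
    left-edge bin (the wide frame then shows the second isotope to the
    right); frames advance one scan per step, labeled with the charge while
    the frame's first scan lies inside the feature's elution range and 0
    outside it. Negatives are drawn from noise traces and from areas at
    least one frame-width away from every feature.
    """
    samples: list[DetectingSample] = []
    n_scans = lcms_map.n_scans
    for f in truth:
        z = f.spec.charge
        col = lcms_map.bin_of_mz(f.spec.mono_mz)
        first = min(r[0] for r in f.isotope_scan_ranges if r[1] >= r[0])
        last = max(r[1] for r in f.isotope_scan_ranges if r[1] >= r[0])
        start = first - int(rng.integers(2, 6))
        frames = np.stack([extract_frame(lcms_map, start + t, col, frame_spec)
                           for t in range(seq_len)])
        scans = start + np.arange(seq_len)
        labels = np.where((scans >= first) & (scans <= last), z, 0).astype(np.int8)
        mask = (scans >= 0) & (scans < n_scans)
        labels[~mask] = 0
        samples.append(DetectingSample(frames, labels, mask, z))

    if n_negative > 0:
        fbins = _feature_bins(lcms_map, truth)
        zeros = np.zeros(seq_len, dtype=np.int8)
        ones = np.ones(seq_len, dtype=bool)
        n_noise_anchored = min(n_negative // 2, len(truth.noise_traces))
        order = rng.permutation(len(truth.noise_traces))[:n_noise_anchored]
        for j in order:
            mz0, apex_scan, first, last = truth.noise_traces[j]
            col = lcms_map.bin_of_mz(mz0)
            start = first - int(rng.integers(2, 6))
            frames = np.stack([extract_frame(lcms_map, start + t, col, frame_spec)
                               for t in range(seq_len)])
            samples.append(DetectingSample(frames, zeros.copy(), ones.copy(), 0))
        n_blank = n_negative - n_noise_anchored
        tries = 0
        made = 0
        while made < n_blank and tries < 50 * n_blank:
            tries += 1
            col = int(rng.integers(0, lcms_map.n_bins))
            if fbins.size and np.abs(fbins - col).min() < frame_spec.n:
                continue
            start = int(rng.integers(0, max(n_scans - seq_len, 1)))
            frames = np.stack([extract_frame(lcms_map, start + t, col, frame_spec)
                               for t in range(seq_len)])
            samples.append(DetectingSample(frames, zeros.copy(), ones.copy(), 0))
            made += 1
    return samples


def _grouping_frames(lcms_map: LCMSMap, start_mz: float, spacing: float,
                     apex_scan: int, frame: FrameSpec) -> np.ndarray:
    out = np.empty((5, frame.m, frame.n), dtype=np.uint8)
    for j in range(5):
        center = lcms_map.bin_of_mz(start_mz + j * spacing)
        out[j] = extract_frame(lcms_map, apex_scan - frame.m // 2,
                               center - frame.n // 2 + 1, frame)
    return out


def make_grouping_samples(lcms_map: LCMSMap, truth: GroundTruthTable,
                          rng: np.random.Generator,
                          frame: FrameSpec = FrameSpec(15, 10),
                          negatives_per_positive: float = 0.55) -> list:
    """Cut 5-frame grouping sequences.

    Positives start at the monoisotope, frames RT-centered on its apex scan
    and m/z-centered on successive expected isotope positions; the label is
    the frame index of the last isotope (capped at 4). Negatives (label 0)
    are noise-trace starts, feature sequences starting at the *second*
    isotope, and blank areas; the default negative fraction mirrors the
    roughly 2:1 positive:negative mix used to train the grouping stage.
    """
    w = lcms_map.mz_bin_width

    def jit():
        # +/- one-bin centering jitter: at inference windows are centered
        # on detected centroids, which can round into a neighbouring bin
        return int(rng.integers(-1, 2)) * w

    samples: list[GroupingSample] = []
    for f in truth:
        z = f.spec.charge
        d = isotope_spacing(z)
        frames = _grouping_frames(lcms_map, f.spec.mono_mz + jit(), d,
                                  f.apex_scan, frame)
        samples.append(GroupingSample(frames, z, min(f.spec.n_isotopes - 1, 4)))

    n_pos = len(samples)
    n_neg = int(round(negatives_per_positive * n_pos))
    if n_neg == 0 or n_pos == 0:
        return samples
    n_shift = n_neg * 3 // 10
    n_pre = n_neg * 3 // 10
    n_noise = n_neg * 2 // 10
    n_blank = n_neg - n_shift - n_pre - n_noise

    feats = truth.features
    for _ in range(n_shift):
        f = feats[rng.integers(len(feats))]
        z = f.spec.charge
        d = isotope_spacing(z)
        frames = _grouping_frames(lcms_map, f.spec.mono_mz + d + jit(), d,
                                  f.apex_scan, frame)
        samples.append(GroupingSample(frames, z, 0))
    for _ in range(n_pre):
        # window one spacing below the monoisotope: the feature starts at
        # frame 1, not frame 0, so the answer must be "no feature here" —
        # the case of a stray record chained in front of a real feature
        f = feats[rng.integers(len(feats))]
        z = f.spec.charge
        d = isotope_spacing(z)
        frames = _grouping_frames(lcms_map, f.spec.mono_mz - d + jit(), d,
                                  f.apex_scan, frame)
        samples.append(GroupingSample(frames, z, 0))
    for _ in range(min(n_noise, len(truth.noise_traces)) if truth.noise_traces else 0):
        mz0, apex_scan, _, _ = truth.noise_traces[rng.integers(len(truth.noise_traces))]
        z = int(rng.integers(1, 5))
        frames = _grouping_frames(lcms_map, mz0, isotope_spacing(z), apex_scan, frame)
        samples.append(GroupingSample(frames, z, 0))
    fbins = _feature_bins(lcms_map, truth)
    made, tries = 0, 0
    while made < n_blank and tries < 50 * n_blank:
        tries += 1
        col = int(rng.integers(5, lcms_map.n_bins - 60))
        if fbins.size and np.abs(fbins - col).min() < 70:
            continue
        z = int(rng.integers(1, 5))
        frames = _grouping_frames(lcms_map, lcms_map.mz_center(col), isotope_spacing(z),
                                  int(rng.integers(8, max(lcms_map.n_scans - 8, 9))), frame)
        samples.append(GroupingSample(frames, z, 0))
        made += 1
    return samples


def augment_rare_charges(samples: list, charges: set, duplication: int,
                         rng: np.random.Generator) -> list:
    """Oversample rare-charge detection sequences with jittered duplicates.

    Each listed-charge sample gains ``duplication`` copies, each with
    intensity rescaling (x U(0.5, 2)), a vertical (RT) shift of up to
    +/-2 scans inside every frame, and sparse low-level additive noise.
    Labels are copied unchanged.
    """
    if not samples:
        raise ValueError("samples must be nonempty")
    out = list(samples)
    for s in samples:
        if s.charge not in charges:
            continue
        for _ in range(duplication):
            scale = rng.uniform(0.5, 2.0)
            shift = int(rng.integers(-2, 3))
            frames = np.roll(s.frames, shift, axis=1)
            if shift > 0:
                frames[:, :shift, :] = 0
            elif shift < 0:
                frames[:, shift:, :] = 0
            frames = np.clip(np.round(frames.astype(np.float32) * scale), 0, 255)
            noise = (rng.random(frames.shape) < 0.002) * rng.integers(1, 8, frames.shape)
            frames = np.clip(frames + noise, 0, 255).astype(np.uint8)
            out.append(DetectingSample(frames, s.labels.copy(), s.mask.copy(), s.charge))
    return out


# ---------------------------------------------------------------------------
# persistence


def write_truth_csv(truth: GroundTruthTable, path: str,
                    rt_of_scan: np.ndarray | None = None) -> None:
    rows = []
    for f in truth:
        s0 = min(r[0] for r in f.isotope_scan_ranges)
        s1 = max(r[1] for r in f.isotope_scan_ranges)
        rt0, rt1 = (float(rt_of_scan[s0]), float(rt_of_scan[s1])) \
            if rt_of_scan is not None else (float(s0), float(s1))
        rows.append({
            "mono_mz": f.spec.mono_mz, "z": f.spec.charge,
            "n_isotopes": f.spec.n_isotopes,
            "rt_apex": f.spec.rt_apex, "rt_sigma": f.spec.rt_sigma,
            "rt_start": rt0, "rt_end": rt1,
            "intensity": f.total_intensity,
            "isotope_auc": json.dumps(list(f.isotope_auc)),
        })
    pd.DataFrame(rows, columns=["mono_mz", "z", "n_isotopes", "rt_apex", "rt_sigma",
                                "rt_start", "rt_end", "intensity", "isotope_auc"]
                 ).to_csv(path, index=False)


def read_truth_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def simulate_to_files(cfg: SimulationConfig, outdir: str, stem: str = "map"):
    """Simulate one map; write it as ``.ms1`` text plus a truth CSV."""
    os.makedirs(outdir, exist_ok=True)
    lcms_map, truth = simulate_map(cfg)
    scans = []
    raw = lcms_map.raw.tocoo()
    per_scan: dict[int, list] = {}
    for r, c, v in zip(raw.row, raw.col, raw.data):
        per_scan.setdefault(int(r), []).append((lcms_map.mz_center(int(c)), float(v)))
    for i in range(lcms_map.n_scans):
        pk = sorted(per_scan.get(i, []))
        scans.append(SpectrumScan(i, float(lcms_map.rt_of_scan[i]),
                                  np.array([p[0] for p in pk]),
                                  np.array([p[1] for p in pk])))
    ms1_path = os.path.join(outdir, f"{stem}.ms1")
    truth_path = os.path.join(outdir, f"{stem}_truth.csv")
    write_ms1(scans, ms1_path)
    write_truth_csv(truth, truth_path, rt_of_scan=lcms_map.rt_of_scan)
    return ms1_path, truth_path
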