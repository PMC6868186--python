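"""Detection model: recurrence contract, scanning invariances, training."""
import numpy as np
import pytest

from pepfeat import nn
from pepfeat.detector import (DetectionTable, DetectorNet, DetectorNetConfig,
                              IsotopeDetector, class_metrics, deep_scan,
                              forward_step, scan_map, train_detecting)
from pepfeat.map_io import FrameSpec
from pepfeat.simulate import (SimulationConfig, make_detecting_samples,
                              simulate_map)

TINY = dict(frame_m=15, frame_n=31, channels=(2, 3, 3),
            kernels=((3, 5), (3, 3), (3, 3)), strides=((1, 2), (1, 1), (1, 1)),
            fc_units=8)


def _tiny_net(seed=0):
    return DetectorNet(DetectorNetConfig(**TINY), np.random.default_rng(seed))


def test_forward_step_distribution_and_state():
    net = _tiny_net()
    rng = np.random.default_rng(1)
    frame = rng.integers(0, 255, (15, 31)).astype(np.uint8)
    dist, state = forward_step(frame, net.initial_state(1)[0], net)
    assert dist.shape == (10,) and abs(dist.sum() - 1.0) < 1e-6
    assert state.shape == (4,) and np.all(np.abs(state) <= 1.0)
    with pytest.raises(ValueError):
        forward_step(np.zeros((15, 30)), net.initial_state(1)[0], net)


def test_forward_step_zero_weights_gives_uniform():
    net = _tiny_net()
    for p, _ in net.variables():
        p[...] = 0.0
    dist, _ = forward_step(np.zeros((15, 31), dtype=np.uint8),
                           net.initial_state(1)[0], net)
    np.testing.assert_allclose(dist, 0.1, atol=1e-7)


def _toy_map(peaks, n_scans=40, mz_min=400.0, mz_max=403.0):
    from pepfeat.map_io import SpectrumScan, rasterize
    per = {}
    for s, mz, inten in peaks:
        per.setdefault(s, []).append((mz, inten))
    scans = []
    for i in range(n_scans):
        pk = sorted(per.get(i, []))
        scans.append(SpectrumScan(i, 0.01 * i, np.array([p[0] for p in pk]),
                                  np.array([p[1] for p in pk])))
    return rasterize(scans, 0.01, mz_min=mz_min, mz_max=mz_max)


def test_deep_scan_state_passes_through_empty_frames():
    net = _tiny_net()
    # two separated blobs in one column; nothing elsewhere
    peaks = [(s, 400.505, 100.0) for s in range(5, 10)]
    peaks += [(s, 400.505, 80.0) for s in range(30, 34)]
    m = _toy_map(peaks)
    b = m.bin_of_mz(400.505)
    labels = deep_scan(m, b, net)
    assert labels.shape == (40,)
    # frames whose span is empty are never evaluated -> label 0 there
    empty_span = [t for t in range(40)
                  if not m.grey_dense()[t:t + 15, b:b + 31].any()]
    assert all(labels[t] == 0 for t in empty_span)
    with pytest.raises(ValueError):
        deep_scan(m, 10**6, net)


def test_scan_map_batching_invariance():
    net = _tiny_net()
    peaks = [(s, 400.2 + 0.3 * k, 50.0 * (k + 1))
             for k in range(5) for s in range(10, 25)]
    m = _toy_map(peaks)
    t1 = scan_map(m, net, batch_size=1)
    t64 = scan_map(m, net, batch_size=64)
    assert t1 == t64
    assert len(scan_map(_toy_map([]), net)) == 0


def test_scan_map_matches_independent_deep_scans():
    # with span-activity (anchor_bins=None) every column equals its own
    # independent deep scan; column order cannot matter
    net = _tiny_net()
    peaks = [(s, 400.505, 100.0) for s in range(5, 20)]
    peaks += [(s, 401.105, 60.0) for s in range(8, 22)]
    m = _toy_map(peaks)
    table = scan_map(m, net, anchor_bins=None)
    for b in range(m.n_bins):
        labels = deep_scan(m, b, net)
        col = table.column(b)
        for t in range(m.n_scans):
            assert col.get(t, 0) == labels[t]


def test_translation_equivariance_without_pooling():
    # stride-1 valid conv stack: shifting a feature by k bins shifts its
    # detections by exactly k bins
    cfg = DetectorNetConfig(frame_m=15, frame_n=31, channels=(2, 3, 3),
                            kernels=((3, 5), (3, 3), (3, 3)),
                            strides=((1, 1), (1, 1), (1, 1)), fc_units=8)
    net = DetectorNet(cfg, np.random.default_rng(3))
    k = 7
    peaks = [(s, 400.505, 100.0) for s in range(5, 20)]
    shifted = [(s, 400.505 + 0.01 * k, 100.0) for s in range(5, 20)]
    m1, m2 = _toy_map(peaks), _toy_map(shifted)
    b = m1.bin_of_mz(400.505)
    np.testing.assert_array_equal(deep_scan(m1, b, net),
                                  deep_scan(m2, b + k, net))


def test_train_rejects_single_class():
    X = np.zeros((4, 5, 15, 31), dtype=np.uint8)
    y = np.zeros((4, 5), dtype=np.int64)
    with pytest.raises(ValueError, match="two classes"):
        IsotopeDetector(**TINY).fit(X, y)


def test_class_metrics_hand_counts():
    out = class_metrics([2, 3, 3], [2, 2, 3])
    assert out[2]["sensitivity"] == pytest.approx(50.0)
    assert out[3]["sensitivity"] == pytest.approx(100.0)
    assert out[3]["precision"] == pytest.approx(50.0)
    perfect = class_metrics([1, 2, 3], [1, 2, 3])
    assert all(v["sensitivity"] == 100.0 for v in perfect.values())
    # class absent from truth: sensitivity undefined, not 0
    out = class_metrics([4, 4], [1, 1])
    assert out[4]["sensitivity"] is None
    assert out[1]["precision"] is None


def test_detector_defaults_match_training_recipe():
    det = IsotopeDetector()
    assert det.learning_rate == 0.01
    assert det.batch_size == 128
    assert det.patience == 5
    assert det.val_every == 10
    assert det.state_size == 4


def test_smoke_training_learns_blank_vs_charge2():
    """A tiny single-charge corpus trains to high frame accuracy quickly."""
    samples = []
    for i in range(2):
        cfg = SimulationConfig(rt_span=1.5, mz_min=400.0, mz_max=406.0,
                               n_features=50, charge_probs={2: 1.0},
                               noise_trace_density=0.5,
                               missing_scan_probability=0.02, rng_seed=50 + i)
        rng = cfg.rng()
        m, truth = simulate_map(cfg, rng)
        samples += make_detecting_samples(m, truth, FrameSpec(15, 211),
                                          n_negative=50, rng=rng)
    samples = samples[:200]
    det = train_detecting(samples, channels=(3, 4, 6),
                          kernels=((3, 5), (3, 3), (3, 3)),
                          strides=((1, 5), (1, 1), (1, 1)), fc_units=16,
                          max_epochs=15, patience=5, random_state=0)
    X = np.stack([s.frames for s in samples])
    y = np.stack([s.labels for s in samples]).astype(np.int64)
    pred = det.predict(X)
    # the exact scan where an elution "starts" is ambiguous by a scan or
    # two; frames away from label transitions must be read almost
    # perfectly, overall accuracy includes the fuzzy boundaries
    stable = np.ones_like(y, dtype=bool)
    for i in range(len(y)):
        trans = np.nonzero(np.diff(y[i]) != 0)[0]
        for tr in trans:
            lo, hi = max(tr - 2, 0), min(tr + 4, y.shape[1])
            stable[i, lo:hi] = False
    assert (pred[stable] == y[stable]).mean() >= 0.95
    assert (pred == y).mean() >= 0.85
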