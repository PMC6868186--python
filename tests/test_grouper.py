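"""Grouping model: gate contract, ensemble voting, cluster rounds, training."""
import numpy as np
import pytest

from pepfeat.clustering import IsotopeCluster, IsotopeRecord
from pepfeat.grouper import (GrouperEnsemble, GrouperNet, GrouperNetConfig,
                             IsotopeGrouper, attention_step, classify_sequence,
                             confusion_matrix, ensemble_predict, scan_cluster,
                             train_grouping)
from pepfeat.isotopes import isotope_spacing
from pepfeat.map_io import FrameSpec, SpectrumScan, rasterize
from pepfeat.simulate import (GroupingSample, SimulationConfig,
                              make_grouping_samples, simulate_map)

SMALL = dict(channels=(3, 4, 4, 4), fc1_units=8, fc2_units=12, state_size=6)


def _net(seed=0, **kw):
    cfg = GrouperNetConfig(**{**SMALL, **kw})
    return GrouperNet(cfg, np.random.default_rng(seed))


def test_attention_step_shapes_and_gate_range(rng):
    net = _net()
    frame = rng.integers(0, 255, (15, 10)).astype(np.uint8)
    a, state = attention_step(frame, 2, net.initial_state(1)[0], net)
    assert 0.0 < a < 1.0
    assert state.shape == (6,)
    with pytest.raises(ValueError):
        attention_step(frame, 0, net.initial_state(1)[0], net)
    with pytest.raises(ValueError):
        attention_step(np.zeros((15, 9)), 2, net.initial_state(1)[0], net)


def test_gate_closed_keeps_state_gate_open_replaces_it(rng):
    net = _net()
    frame = rng.integers(0, 255, (15, 10)).astype(np.uint8)
    f0 = rng.uniform(-0.5, 0.5, 6).astype(np.float32)
    net.b_a[...] = -40.0  # a -> 0: state frozen
    _, f_closed = attention_step(frame, 2, f0, net)
    np.testing.assert_allclose(f_closed, f0, atol=1e-6)
    net.b_a[...] = 40.0   # a -> 1: plain recurrent update
    x_o, _ = net.embed(frame[None], np.array([2]))
    expect = np.tanh(f0 @ net.W_hh + x_o[0] @ net.W_oh + net.b_h)
    _, f_open = attention_step(frame, 2, f0, net)
    np.testing.assert_allclose(f_open, expect, atol=1e-5)


def test_gate_closed_output_ignores_all_frames(rng):
    net = _net()
    net.b_a[...] = -40.0
    a = classify_sequence(rng.integers(0, 255, (5, 15, 10)).astype(np.uint8), 2, net)
    b = classify_sequence(rng.integers(0, 255, (5, 15, 10)).astype(np.uint8), 2, net)
    np.testing.assert_allclose(a.distribution, b.distribution, atol=1e-6)


def test_classify_sequence_contract(rng):
    net = _net()
    frames = rng.integers(0, 255, (5, 15, 10)).astype(np.uint8)
    dec = classify_sequence(frames, 3, net)
    assert abs(dec.distribution.sum() - 1.0) < 1e-6
    assert dec.attention.shape == (5,)
    with pytest.raises(ValueError):
        classify_sequence(frames[:4], 3, net)


def test_bptt_gradients_match_finite_differences(rng):
    from pepfeat import nn
    from pepfeat.grouper import _backward_sequences, _forward_sequences
    net = _net(seed=5)
    X = rng.integers(0, 200, (3, 5, 15, 10)).astype(np.uint8)
    charge = np.array([1, 2, 3])
    y = np.array([0, 2, 4])

    def loss_of():
        logits, _, _ = _forward_sequences(net, X, charge)
        return nn.softmax_xent(logits, y)[0]

    logits, _, fwd = _forward_sequences(net, X, charge, cache=True)
    _, dlogits = nn.softmax_xent(logits, y)
    _backward_sequences(net, dlogits, fwd)
    eps = 1e-2
    checked = 0
    # only parameters downstream of the max-pools: perturbing earlier
    # weights can flip a pooling argmax, which a finite difference sees as
    # a kink (the conv/pool layers have their own gradient tests)
    skip = {id(v) for layer in net.convs[:2] for v, _ in layer.variables()}
    for p, g in net.variables():
        if id(p) in skip:
            continue
        flat = p.ravel()
        gflat = g.ravel()
        for idx in range(0, flat.size, max(flat.size // 3, 1)):
            w0 = flat[idx]
            flat[idx] = w0 + eps
            lp = loss_of()
            flat[idx] = w0 - eps
            lm = loss_of()
            flat[idx] = w0
            num = (lp - lm) / (2 * eps)
            assert abs(num - gflat[idx]) < 2e-3, (p.shape, idx)
            checked += 1
    assert checked > 10


def test_single_member_vote_equals_member(rng):
    net = _net()
    frames = rng.integers(0, 255, (5, 15, 10)).astype(np.uint8)
    solo = classify_sequence(frames, 2, net)
    voted = ensemble_predict(frames, 2, [net])
    np.testing.assert_allclose(voted.distribution, solo.distribution)
    # identical members vote exactly like one member
    trip = ensemble_predict(frames, 2, [net, net, net])
    np.testing.assert_allclose(trip.distribution, solo.distribution, atol=1e-7)


def test_ensemble_mean_arithmetic():
    class Fake:
        def __init__(self, dist):
            self.dist = np.asarray(dist, dtype=np.float32)

        def predict_proba(self, X, charge):
            return np.tile(self.dist, (len(X), 1))

        def predict(self, X, charge):
            return self.predict_proba(X, charge).argmax(axis=1)

    a = Fake([0.6, 0.4, 0.0, 0.0, 0.0])
    b = Fake([0.2, 0.8, 0.0, 0.0, 0.0])
    # soft vote by hand: mean of distributions, argmax class 1
    mean = (a.dist + b.dist) / 2
    assert mean[1] == pytest.approx(0.6) and mean.argmax() == 1
    with pytest.raises(ValueError):
        GrouperEnsemble([])


def test_train_rejects_single_class(rng):
    X = rng.integers(0, 255, (10, 5, 15, 10)).astype(np.uint8)
    with pytest.raises(ValueError, match="two classes"):
        IsotopeGrouper(**SMALL).fit(X, np.zeros(10, dtype=int),
                                    charge=np.full(10, 2))


def test_grouper_defaults_match_training_recipe():
    g = IsotopeGrouper()
    assert g.learning_rate == 0.07
    assert g.optimizer == "adagrad"
    assert g.batch_size == 128
    assert g.patience == 5
    assert g.state_size == 8


def test_confusion_matrix_hand_counts():
    # truth {B,B,C} -> classes {1,1,2}; pred {B,C,C}
    m = confusion_matrix([1, 2, 2], [1, 1, 2])
    np.testing.assert_allclose(m[1], [0, 50, 50, 0, 0])
    np.testing.assert_allclose(m[2], [0, 0, 100, 0, 0])
    perfect = confusion_matrix([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
    np.testing.assert_allclose(np.diag(perfect), 100.0)
    rows = confusion_matrix([0, 1, 2, 3, 4], [0, 1, 2, 3, 4]).sum(axis=1)
    np.testing.assert_allclose(rows, 100.0, atol=1e-9)


def _cluster_map_and_records(n_iso=3, z=2, gap_record=False):
    d = isotope_spacing(z)
    peaks, recs = [], []
    positions = list(range(n_iso))
    for i in positions:
        mz = 402.0 + i * d
        for s in range(10, 26):
            peaks.append((s, mz, 300.0 * 0.8 ** i
                          * np.exp(-0.5 * ((s - 18) / 4) ** 2)))
    per = {}
    for s, mz, inten in peaks:
        per.setdefault(s, []).append((mz, inten))
    scans = []
    for i in range(40):
        pk = sorted(per.get(i, []))
        scans.append(SpectrumScan(i, 0.01 * i, np.array([p[0] for p in pk]),
                                  np.array([p[1] for p in pk])))
    m = rasterize(scans, 0.01, mz_min=400.0, mz_max=406.0)
    for i in positions:
        mz = 402.0 + i * d
        b = m.bin_of_mz(mz)
        inten = np.asarray(m.raw[10:26, b].todense()).ravel()
        recs.append(IsotopeRecord(charge=z, mz=mz, scan_first=10, scan_last=25,
                                  intensities=inten,
                                  apex_scan=10 + int(np.argmax(inten))))
    return m, IsotopeCluster(charge=z, isotopes=recs)


class _Queue:
    """Deterministic grouping stand-in answering from a fixed script."""

    def __init__(self, seq):
        self.seq = list(seq)

    def predict(self, X, charge):
        return np.array([self.seq.pop(0)])


def test_scan_cluster_singleton_noise_returns_nothing():
    # a singleton record still gets one round (a 2-isotope feature reaches
    # this stage as a single record); answering 0 yields no feature
    m, cluster = _cluster_map_and_records(n_iso=2)
    singleton = IsotopeCluster(charge=2, isotopes=cluster.isotopes[:1])
    assert scan_cluster(singleton, m, _Queue([0])) == []
    # answering 1 claims the undetected tail isotope: span past the records
    assert scan_cluster(singleton, m, _Queue([1])) == [(0, 1)]


def test_scan_cluster_simple_feature_span():
    m, cluster = _cluster_map_and_records(n_iso=3)
    # one round answering class 2 -> span (0, 2)
    assert scan_cluster(cluster, m, _Queue([2])) == [(0, 2)]


def test_scan_cluster_two_features_split_by_zero_round():
    m, cluster = _cluster_map_and_records(n_iso=5)
    # round@0 -> 1 (span 0-1); round@2 -> 0 (no feature at 2); round@3 -> 1
    assert scan_cluster(cluster, m, _Queue([1, 0, 1])) == [(0, 1), (3, 4)]


def test_scan_cluster_class4_continuation_extends():
    m, cluster = _cluster_map_and_records(n_iso=8)
    # round@0 -> 4 (>=5 isotopes); continuation@4 -> 3 -> end at 7
    assert scan_cluster(cluster, m, _Queue([4, 3])) == [(0, 7)]
    # continuation answering 0 ends the feature at index 4; later rounds
    # over the remaining tail isotopes see nothing
    assert scan_cluster(cluster, m, _Queue([4, 0, 0, 0, 0])) == [(0, 4)]


def test_smoke_training_separates_noise_from_small_features():
    """500 sequences of classes {0,1,2} reach high training accuracy fast."""
    samples = []
    for i in range(4):
        cfg = SimulationConfig(rt_span=1.5, mz_min=400.0, mz_max=410.0,
                               n_features=60, charge_probs={1: 0.5, 2: 0.5},
                               max_isotopes=3, rng_seed=70 + i)
        rng = cfg.rng()
        m, truth = simulate_map(cfg, rng)
        samples += make_grouping_samples(m, truth, rng,
                                         negatives_per_positive=1.0)
    samples = [s for s in samples if s.label <= 2][:500]
    g = train_grouping(samples, channels=(4, 8, 8, 8), fc1_units=16,
                       fc2_units=32, state_size=8, max_epochs=60, patience=15,
                       random_state=0)
    X = np.stack([s.frames for s in samples])
    y = np.array([s.label for s in samples])
    charge = np.array([s.charge for s in samples])
    assert g.score(X, y, charge=charge) >= 0.90
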