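"""Grouping isotopes into features with an attention-gated recurrent net.

The grouping model looks at five consecutive 15 x 10 frames, each centered
on one expected isotope position of a cluster, and emits a single class:
0 = "no feature starts at the first frame" (noise, or a window that starts
mid-feature), k in {1..4} = "the feature's last isotope sits in frame k"
(k = 4 also covers features with more than five isotopes). The charge
determined by the detection stage is injected as a one-hot vector
concatenated to the first dense layer's output.

State update per frame (H = tanh, sigma = logistic):

    f'_t = H(W_hh . f_{t-1} + W_oh . X_ot + b_h)
    a_t  = sigma(W_a . f'_t + b_a)
    f_t  = (1 - a_t) . f_{t-1} + a_t . f'_t

so the scalar gate ``a_t`` decides how much each frame matters; the
classifier reads the state after the fifth frame. Clusters are consumed in
multiple, possibly overlapping rounds whose starting isotope depends on the
previous round's output, which is how features with more than five isotopes
and clusters holding several features are resolved. An ensemble of
independently trained instances is combined by soft voting (averaging the
class distributions).
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .clustering import IsotopeCluster
from .isotopes import MAX_CHARGE, MIN_CHARGE, isotope_spacing
from .map_io import FrameSpec, LCMSMap, extract_frame

__all__ = [
    "GrouperNet", "IsotopeGrouper", "GrouperEnsemble", "GroupingDecision",
    "attention_step", "classify_sequence", "scan_cluster", "ensemble_predict",
    "confusion_matrix", "train_grouping", "small_grouper_config",
]

N_GROUP_CLASSES = 5
SEQ_LEN = 5


@dataclass
class GroupingDecision:
    """Soft-voted class distribution plus the per-step attention trace."""

    distribution: np.ndarray   # (5,)
    label: int
    attention: np.ndarray      # (5,) gate values a_1..a_5


@dataclass
class GrouperNetConfig:
    frame_m: int = 15
    frame_n: int = 10
    channels: tuple = (8, 16, 16, 16)
    kernel: tuple = (3, 3)
    fc1_units: int = 64
    fc2_units: int = 128
    state_size: int = 8
    dropout: float = 0.5

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "GrouperNetConfig":
        d = json.loads(s)
        d["channels"] = tuple(d["channels"])
        d["kernel"] = tuple(d["kernel"])
        return cls(**d)


def small_grouper_config(state_size: int = 8, fc2_units: int = 32) -> GrouperNetConfig:
    """Reduced-width configuration for desk-scale (CPU) training."""
    return GrouperNetConfig(channels=(4, 8, 8, 8), fc1_units=16,
                            fc2_units=fc2_units, state_size=state_size)


class GrouperNet:
    """Four same-padded conv layers (2x2 max pool after the first two),
    two dense layers with dropout, charge injection, attention-gated state,
    and a 5-way linear classifier."""

    def __init__(self, cfg: GrouperNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        in_ch = 1
        self.convs = []
        for ch in cfg.channels:
            self.convs.append(nn.Conv2D(rng, in_ch, ch, kernel=cfg.kernel,
                                        stride=(1, 1), padding="same"))
            in_ch = ch
        self.pools = [nn.MaxPool2D(2), nn.MaxPool2D(2)]
        h, w = cfg.frame_m, cfg.frame_n
        h, w = h // 2, w // 2
        h, w = h // 2, w // 2
        self.flat_dim = h * w * cfg.channels[-1]
        self.fc1 = nn.Dense(rng, self.flat_dim, cfg.fc1_units)
        self.fc2 = nn.Dense(rng, cfg.fc1_units + MAX_CHARGE, cfg.fc2_units)
        s = cfg.state_size
        self.W_hh = nn.glorot_uniform(rng, (s, s), s, s)
        self.W_oh = nn.glorot_uniform(rng, (cfg.fc2_units, s), cfg.fc2_units, s)
        self.b_h = np.zeros(s, dtype=np.float32)
        self.W_a = nn.glorot_uniform(rng, (s, 1), s, 1)
        self.b_a = np.zeros(1, dtype=np.float32)
        self.gW_hh = np.zeros_like(self.W_hh)
        self.gW_oh = np.zeros_like(self.W_oh)
        self.gb_h = np.zeros_like(self.b_h)
        self.gW_a = np.zeros_like(self.W_a)
        self.gb_a = np.zeros_like(self.b_a)
        self.classifier = nn.Dense(rng, s, N_GROUP_CLASSES, activation=None)

    def variables(self):
        out = []
        for c in self.convs:
            out += c.variables()
        out += self.fc1.variables() + self.fc2.variables()
        out += [(self.W_hh, self.gW_hh), (self.W_oh, self.gW_oh),
                (self.b_h, self.gb_h), (self.W_a, self.gW_a), (self.b_a, self.gb_a)]
        out += self.classifier.variables()
        return out

    def initial_state(self, batch: int) -> np.ndarray:
        return np.zeros((batch, self.cfg.state_size), dtype=np.float32)

    @staticmethod
    def _onehot_charge(charge: np.ndarray) -> np.ndarray:
        charge = np.asarray(charge, dtype=np.int64).ravel()
        if np.any((charge < MIN_CHARGE) | (charge > MAX_CHARGE)):
            raise ValueError("charge outside 1-9")
        out = np.zeros((charge.size, MAX_CHARGE), dtype=np.float32)
        out[np.arange(charge.size), charge - 1] = 1.0
        return out

    def embed(self, frames: np.ndarray, charge: np.ndarray,
              training: bool = False, rng: np.random.Generator | None = None,
              cache: bool = False):
        """frames: (B, 15, 10) grey; charge: (B,). Returns (X_o, caches)."""
        x = frames.astype(np.float32) / 255.0
        x = x[..., None]
        caches = []
        h = x
        for idx, conv in enumerate(self.convs):
            h, c = conv.forward(h, cache=cache)
            caches.append(("layer", conv, c))
            if idx < 2:
                h, c = self.pools[idx].forward(h, cache=cache)
                caches.append(("layer", self.pools[idx], c))
        b = h.shape[0]
        hs = h.shape
        h = h.reshape(b, -1)
        caches.append(("reshape", None, hs))
        h, c = self.fc1.forward(h, cache=cache)
        caches.append(("layer", self.fc1, c))
        h, m = nn.dropout_forward(h, self.cfg.dropout, rng, training)
        caches.append(("drop", None, m))
        h = np.concatenate([h, self._onehot_charge(charge)], axis=1)
        caches.append(("concat", None, self.cfg.fc1_units))
        h, c = self.fc2.forward(h, cache=cache)
        caches.append(("layer", self.fc2, c))
        h, m = nn.dropout_forward(h, self.cfg.dropout, rng, training)
        caches.append(("drop", None, m))
        return h, caches

    def embed_backward(self, d_xo: np.ndarray, caches) -> None:
        d = d_xo
        for kind, layer, c in reversed(caches):
            if kind == "drop":
                d = nn.dropout_backward(d, c)
            elif kind == "concat":
                d = d[:, :c]
            elif kind == "reshape":
                d = d.reshape(c)
            else:
                d = layer.backward(d, c)

    def step(self, x_o: np.ndarray, f_prev: np.ndarray):
        return nn.attention_gate_state(x_o, f_prev, self.W_hh, self.W_oh,
                                       self.b_h, self.W_a, self.b_a)

    def logits(self, f: np.ndarray, cache: bool = False):
        return self.classifier.forward(f, cache=cache)

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        d = {}
        for i, c in enumerate(self.convs):
            d[f"conv{i}_W"] = c.W
            d[f"conv{i}_b"] = c.b
        for name, layer in (("fc1", self.fc1), ("fc2", self.fc2),
                            ("cls", self.classifier)):
            d[f"{name}_W"] = layer.W
            d[f"{name}_b"] = layer.b
        for name in ("W_hh", "W_oh", "b_h", "W_a", "b_a"):
            d[name] = getattr(self, name)
        return d

    def copy_weights(self) -> dict:
        return {k: v.copy() for k, v in self.state_dict().items()}

    def load_weights(self, d: dict) -> None:
        for k, v in self.state_dict().items():
            v[...] = d[k]

    def save(self, path: str, seed: int | None = None) -> None:
        meta = {"kind": "grouper", "config": self.cfg.to_json(), "seed": seed,
                "version": 1}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "GrouperNet":
        with np.load(path if path.endswith(".npz") else path + ".npz") as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = GrouperNetConfig.from_json(meta["config"])
            net = cls(cfg, np.random.default_rng(0))
            net.load_weights({k: z[k] for k in z.files if k != "__meta__"})
        return net


# ---------------------------------------------------------------------------
# public single-step / sequence API


def attention_step(frame: np.ndarray, charge: int, prev_state: np.ndarray,
                   net: GrouperNet, training: bool = False,
                   rng: np.random.Generator | None = None):
    """One gated step on one frame; returns ``(a_t, new_state)``."""
    if frame.shape != (net.cfg.frame_m, net.cfg.frame_n):
        raise ValueError(f"frame shape {frame.shape} != "
                         f"{(net.cfg.frame_m, net.cfg.frame_n)}")
    x_o, _ = net.embed(frame[None], np.array([charge]), training=training, rng=rng)
    f_prev = np.asarray(prev_state, dtype=np.float32).reshape(1, -1)
    f_t, a, _ = net.step(x_o, f_prev)
    return float(a[0, 0]), f_t[0]


def _forward_sequences(net: GrouperNet, X: np.ndarray, charge: np.ndarray,
                       training: bool = False, rng=None, cache: bool = False):
    """X: (B, 5, M, N). Returns (logits, attention (B,5), forward cache)."""
    b, t = X.shape[:2]
    x_o, caches = net.embed(X.reshape(b * t, *X.shape[2:]),
                            np.repeat(np.asarray(charge), t),
                            training=training, rng=rng, cache=cache)
    d = x_o.shape[1]
    x_o = x_o.reshape(b, t, d)
    f = net.initial_state(b)
    fs, fps, gates, prevs = [], [], [], []
    for step in range(t):
        prevs.append(f)
        f, a, fp = net.step(x_o[:, step], f)
        fs.append(f)
        fps.append(fp)
        gates.append(a)
    logits, ccache = net.logits(f, cache=cache)
    attn = np.stack([g[:, 0] for g in gates], axis=1)
    fwd = (x_o, caches, fs, fps, gates, prevs, ccache)
    return logits, attn, fwd


def _backward_sequences(net: GrouperNet, dlogits: np.ndarray, fwd) -> None:
    x_o, caches, fs, fps, gates, prevs, ccache = fwd
    b, t, d = x_o.shape
    df = net.classifier.backward(dlogits, ccache)
    d_xo = np.empty((b, t, d), dtype=np.float32)
    for step in reversed(range(t)):
        f_prev, fp, a = prevs[step], fps[step], gates[step]
        da = (df * (fp - f_prev)).sum(axis=1, keepdims=True)
        dpre_a = da * a * (1.0 - a)
        net.gW_a += fp.T @ dpre_a
        net.gb_a += dpre_a.sum(axis=0)
        dfp = df * a + dpre_a @ net.W_a.T
        dpre = dfp * nn.dtanh_from_out(fp)
        net.gW_hh += f_prev.T @ dpre
        net.gW_oh += x_o[:, step].T @ dpre
        net.gb_h += dpre.sum(axis=0)
        d_xo[:, step] = dpre @ net.W_oh.T
        df = df * (1.0 - a) + dpre @ net.W_hh.T
    net.embed_backward(d_xo.reshape(b * t, d), caches)


def classify_sequence(frames: np.ndarray, charge: int,
                      net: GrouperNet) -> GroupingDecision:
    """Chain five gated steps and classify the final state."""
    frames = np.asarray(frames)
    if frames.shape[0] != SEQ_LEN:
        raise ValueError(f"expected {SEQ_LEN} frames, got {frames.shape[0]}")
    logits, attn, _ = _forward_sequences(net, frames[None], np.array([charge]))
    dist = nn.softmax(logits)[0]
    return GroupingDecision(distribution=dist, label=int(dist.argmax()),
                           attention=attn[0])


# ---------------------------------------------------------------------------
# estimator


class IsotopeGrouper(BaseEstimator, ClassifierMixin):
    """5-frame sequence classifier with attention-gated recurrence.

    Trained with Adagrad (initial learning rate 0.07), softmax
    cross-entropy at the final step, minibatches of 128, validation every
    10 minibatches, shuffling per epoch, and early stop after ``patience``
    stagnant epochs. Model selection maximises a feature-level match score
    (monoisotope and high-intensity isotopes right) on the validation set
    rather than raw class accuracy: a prediction is accepted when it agrees
    with the truth about whether a feature starts at the first frame and,
    for real features, misplaces the last isotope by at most one frame.
    """

    def __init__(self, frame_m=15, frame_n=10, channels=(8, 16, 16, 16),
                 kernel=(3, 3), fc1_units=64, fc2_units=128, state_size=8,
                 dropout=0.5, learning_rate=0.07, optimizer="adagrad",
                 batch_size=128, max_epochs=100, patience=5, val_every=10,
                 validation_fraction=0.1, grad_clip=5.0, n_init=1,
                 random_state=0):
        self.frame_m = frame_m
        self.frame_n = frame_n
        self.channels = channels
        self.kernel = kernel
        self.fc1_units = fc1_units
        self.fc2_units = fc2_units
        self.state_size = state_size
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_every = val_every
        self.validation_fraction = validation_fraction
        self.grad_clip = grad_clip
        self.n_init = n_init
        self.random_state = random_state

    def _net_config(self) -> GrouperNetConfig:
        return GrouperNetConfig(frame_m=self.frame_m, frame_n=self.frame_n,
                                channels=tuple(self.channels),
                                kernel=tuple(self.kernel),
                                fc1_units=self.fc1_units,
                                fc2_units=self.fc2_units,
                                state_size=self.state_size, dropout=self.dropout)

    @staticmethod
    def _feature_match_score(pred: np.ndarray, true: np.ndarray) -> float:
        """Accepted: noise called noise; features get a start (pred>0) and a
        last isotope within one frame of truth."""
        noise = true == 0
        ok_noise = (pred[noise] == 0) if noise.any() else np.empty(0, bool)
        feat = ~noise
        ok_feat = ((pred[feat] > 0) & (np.abs(pred[feat] - true[feat]) <= 1)) \
            if feat.any() else np.empty(0, bool)
        return float(np.concatenate([ok_noise, ok_feat]).mean())

    def _make_optimizer(self, net):
        if self.optimizer == "adagrad":
            return nn.Adagrad(net.variables(), lr=self.learning_rate,
                              clip=self.grad_clip)
        if self.optimizer == "adam":
            return nn.Adam(net.variables(), lr=self.learning_rate,
                           clip=self.grad_clip)
        raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def fit(self, X, y, charge=None, X_val=None, y_val=None, charge_val=None):
        X = np.asarray(X)
        y = np.asarray(y, dtype=np.int64)
        if charge is None:
            raise ValueError("charge (per-sequence, 1-9) is required")
        charge = np.asarray(charge, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain at least two classes")
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            n_val = max(int(round(self.validation_fraction * len(X))), 1)
            order = rng.permutation(len(X))
            vi, ti = order[:n_val], order[n_val:]
            X_val, y_val, charge_val = X[vi], y[vi], charge[vi]
            X, y, charge = X[ti], y[ti], charge[ti]

        overall = None
        history = []
        total_epochs = 0
        for attempt in range(max(self.n_init, 1)):
            seed = int((self.random_state + 1000003 * attempt) % (2 ** 31))
            arng = np.random.default_rng(seed)
            net = GrouperNet(self._net_config(), arng)
            opt = self._make_optimizer(net)
            best = {"score": -np.inf, "weights": net.copy_weights(),
                    "epoch": 0, "net": net}
            first_val = None
            stale = 0
            mb = 0
            stalled = False
            for epoch in range(self.max_epochs):
                order = arng.permutation(len(X))
                epoch_best = -np.inf
                for i in range(0, len(order), self.batch_size):
                    idx = order[i:i + self.batch_size]
                    logits, _, fwd = _forward_sequences(net, X[idx],
                                                        charge[idx],
                                                        training=True,
                                                        rng=arng, cache=True)
                    loss, dlogits = nn.softmax_xent(logits, y[idx])
                    _backward_sequences(net, dlogits, fwd)
                    opt.step()
                    mb += 1
                    if mb % self.val_every == 0:
                        score = self._feature_match_score(
                            self._predict_net(net, X_val, charge_val), y_val)
                        history.append({"attempt": attempt, "epoch": epoch,
                                        "minibatch": mb, "loss": loss,
                                        "val_feature_match": score})
                        epoch_best = max(epoch_best, score)
                        if score > best["score"] + 1e-6:
                            best.update(score=score,
                                        weights=net.copy_weights(),
                                        epoch=epoch)
                score = self._feature_match_score(
                    self._predict_net(net, X_val, charge_val), y_val)
                history.append({"attempt": attempt, "epoch": epoch,
                                "minibatch": mb, "loss": loss,
                                "val_feature_match": score})
                epoch_best = max(epoch_best, score)
                if score > best["score"] + 1e-6:
                    best.update(score=score, weights=net.copy_weights(),
                                epoch=epoch)
                if first_val is None:
                    first_val = score
                stale = 0 if epoch_best >= best["score"] - 1e-9 else stale + 1
                total_epochs += 1
                if stale >= self.patience:
                    break
                # abandon an initialisation stuck far below the scores a
                # healthy run reaches within a few epochs, and reseed
                if (self.n_init > 1 and attempt < self.n_init - 1
                        and epoch + 1 >= 6 and best["score"] < 0.85
                        and best["score"] - first_val < 0.05):
                    stalled = True
                    break
            # a run that early-stopped while still far below the scores a
            # healthy run reaches is also a failed basin
            if (self.n_init > 1 and attempt < self.n_init - 1
                    and best["score"] < 0.85):
                stalled = True
            if overall is None or best["score"] > overall["score"]:
                overall = best
            if not stalled:
                break
        net = overall["net"]
        net.load_weights(overall["weights"])
        self.net_ = net
        self.classes_ = np.arange(N_GROUP_CLASSES)
        self.best_val_score_ = overall["score"]
        self.n_epochs_ = total_epochs
        self.history_ = history
        return self

    def retrain(self, X, y, charge, max_epochs: int = 10):
        """Continue training on additional (hard) cases, e.g. adjacent
        features the model failed to separate; keeps the current weights as
        the starting point."""
        check_is_fitted(self, "net_")
        net = self.net_
        # a fresh optimiser at the full initial rate would wreck the
        # fitted weights; continue with a much smaller step instead
        saved_lr = self.learning_rate
        self.learning_rate = saved_lr * 0.1
        try:
            opt = self._make_optimizer(net)
        finally:
            self.learning_rate = saved_lr
        rng = np.random.default_rng(self.random_state + 1)
        X = np.asarray(X)
        y = np.asarray(y, dtype=np.int64)
        charge = np.asarray(charge, dtype=np.int64)
        for _ in range(max_epochs):
            order = rng.permutation(len(X))
            for i in range(0, len(order), self.batch_size):
                idx = order[i:i + self.batch_size]
                logits, _, fwd = _forward_sequences(net, X[idx], charge[idx],
                                                    training=True, rng=rng,
                                                    cache=True)
                _, dlogits = nn.softmax_xent(logits, y[idx])
                _backward_sequences(net, dlogits, fwd)
                opt.step()
        return self

    @staticmethod
    def _predict_net(net, X, charge, batch: int = 256) -> np.ndarray:
        out = np.empty(len(X), dtype=np.int64)
        for i in range(0, len(X), batch):
            logits, _, _ = _forward_sequences(net, X[i:i + batch],
                                              charge[i:i + batch])
            out[i:i + batch] = logits.argmax(axis=1)
        return out

    def predict(self, X, charge=None) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self._predict_net(self.net_, np.asarray(X), np.asarray(charge))

    def predict_proba(self, X, charge=None) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = np.asarray(X)
        charge = np.asarray(charge)
        out = np.empty((len(X), N_GROUP_CLASSES), dtype=np.float32)
        for i in range(0, len(X), 256):
            logits, _, _ = _forward_sequences(self.net_, X[i:i + 256],
                                              charge[i:i + 256])
            out[i:i + 256] = nn.softmax(logits)
        return out

    def score(self, X, y, charge=None) -> float:
        return float((self.predict(X, charge=charge) == np.asarray(y)).mean())


def train_grouping(samples, hard_samples=None, **hyper) -> IsotopeGrouper:
    """Thin wrapper: stack GroupingSamples and fit an IsotopeGrouper.

    ``hard_samples`` (e.g. adjacent-feature cases collected from earlier
    mistakes) trigger a retraining pass after the main fit.
    """
    X = np.stack([s.frames for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    charge = np.array([s.charge for s in samples], dtype=np.int64)
    g = IsotopeGrouper(**hyper).fit(X, y, charge=charge)
    if hard_samples:
        Xh = np.stack([s.frames for s in hard_samples])
        yh = np.array([s.label for s in hard_samples], dtype=np.int64)
        ch = np.array([s.charge for s in hard_samples], dtype=np.int64)
        g.retrain(Xh, yh, ch)
    return g


# ---------------------------------------------------------------------------
# ensemble


class GrouperEnsemble:
    """Soft-voting ensemble of grouping models (arithmetic mean of
    distributions; argmax of the mean)."""

    def __init__(self, members: list):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)

    def _nets(self):
        return [m.net_ if isinstance(m, IsotopeGrouper) else m for m in self.members]

    def predict_proba(self, X, charge) -> np.ndarray:
        X = np.asarray(X)
        charge = np.asarray(charge)
        dists = []
        for net in self._nets():
            logits, _, _ = _forward_sequences(net, X, charge)
            dists.append(nn.softmax(logits))
        return np.mean(dists, axis=0)

    def predict(self, X, charge) -> np.ndarray:
        return self.predict_proba(X, charge).argmax(axis=1)

    def decide(self, frames: np.ndarray, charge: int) -> GroupingDecision:
        frames = np.asarray(frames)
        dists, attns = [], []
        for net in self._nets():
            logits, attn, _ = _forward_sequences(net, frames[None],
                                                 np.array([charge]))
            dists.append(nn.softmax(logits)[0])
            attns.append(attn[0])
        dist = np.mean(dists, axis=0)
        return GroupingDecision(distribution=dist, label=int(dist.argmax()),
                               attention=np.mean(attns, axis=0))

    def save(self, dirpath: str) -> None:
        os.makedirs(dirpath, exist_ok=True)
        names = []
        for i, net in enumerate(self._nets()):
            name = f"member_{i}.npz"
            net.save(os.path.join(dirpath, name))
            names.append(name)
        with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
            json.dump({"members": names, "vote": "soft", "version": 1}, fh)

    @classmethod
    def load(cls, dirpath: str) -> "GrouperEnsemble":
        with open(os.path.join(dirpath, "manifest.json")) as fh:
            manifest = json.load(fh)
        return cls([GrouperNet.load(os.path.join(dirpath, n))
                    for n in manifest["members"]])


def ensemble_predict(frames: np.ndarray, charge: int,
                     members: list) -> GroupingDecision:
    """Soft vote of several grouping models on one 5-frame sequence."""
    return GrouperEnsemble(members).decide(frames, charge)


# ---------------------------------------------------------------------------
# multi-round cluster scanning


def _round_frames(cluster: IsotopeCluster, lcms_map: LCMSMap, start: int,
                  frame: FrameSpec) -> np.ndarray:
    """Five frames read from the *map* at the expected isotope ladder.

    Frames past the cluster's last record still look at the map at the
    extrapolated position: the detection stage cannot see a feature's last
    isotope (no companion to its right), so the signal deciding where the
    feature ends often exists only in the map, not in the record list.
    """
    recs = cluster.isotopes
    d = isotope_spacing(cluster.charge)
    apex = recs[start].apex_scan
    out = np.zeros((SEQ_LEN, frame.m, frame.n), dtype=np.uint8)
    for j in range(SEQ_LEN):
        # expected ladder position from the round's anchor: per-record
        # centroids can round into the neighbouring bin and shift a frame
        mz = recs[start].mz + j * d
        center = lcms_map.bin_of_mz(mz)
        out[j] = extract_frame(lcms_map, apex - frame.m // 2,
                               center - frame.n // 2 + 1, frame)
    return out


def scan_cluster(cluster: IsotopeCluster, lcms_map: LCMSMap, model,
                 frame: FrameSpec = FrameSpec(15, 10)) -> list:
    """Resolve a cluster into feature spans in rounds.

    Each round classifies the 5-frame window starting at isotope ``s``
    (frames RT-centered on that isotope's apex). Class 0 advances one
    isotope; class k in {1..3} emits the span (s, s+k) and continues after
    it; class 4 means the feature has at least five isotopes, so an
    overlapping continuation round starts at the provisional last isotope
    and keeps extending while it answers 4 (continuations need a record to
    re-anchor on, so they stop at the cluster tail).

    A span's end may point past the cluster's last record: the detection
    stage cannot record a feature's final isotope (nothing to its right
    confirms the charge), so the window frames read the map beyond the
    records and the assembly stage materialises the tail from map
    evidence. Rounds run even on singleton clusters for the same reason —
    a two-isotope feature reaches this stage as a single record.

    Spans are additionally truncated at envelope resets: isotope heights
    decay along a feature, so a recorded isotope noticeably brighter than
    its predecessor marks the monoisotope of the *next* feature in a
    shared ladder, and the next round starts exactly there.
    """
    recs = cluster.isotopes
    n = len(recs)
    spans = []
    s = 0
    while s < n:
        frames = _round_frames(cluster, lcms_map, s, frame)
        k = int(model.predict(frames[None], np.array([cluster.charge]))[0])
        if k == 0:
            s += 1
            continue
        end = s + k
        while k == 4 and end < n:
            cont = _round_frames(cluster, lcms_map, end, frame)
            k2 = int(model.predict(cont[None], np.array([cluster.charge]))[0])
            if k2 == 0:
                break
            end = end + k2
            k = k2
        # envelope-reset check: isotope heights decay towards the tail, so
        # a recorded isotope clearly brighter than its predecessor is the
        # *next* feature's monoisotope (adjacent features sharing one
        # ladder); truncate the span there and start the next round on it.
        # The 1.3 factor must exceed any within-envelope ratio (heavy ions
        # approach iso1/mono ~ 1, plus bin-capture noise) while true
        # resets are far larger
        split = None
        for j in range(s + 1, min(end, n - 1) + 1):
            if (float(recs[j].intensities.max())
                    > 1.3 * float(recs[j - 1].intensities.max())):
                split = j
                break
        if split is not None:
            end = split - 1
        if end > s:
            spans.append((s, end))
        s = split if split is not None else end + 1
    return spans


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(pred, true, n_classes: int = N_GROUP_CLASSES) -> np.ndarray:
    """Row-normalised confusion matrix in percent (rows = truth).

    Row class 0 collects features misread as noise (monoisotope or all
    isotopes missed); diagonal entries are per-class sensitivities. Rows
    with no truth samples are NaN.
    """
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError("label arrays must align")
    mat = np.zeros((n_classes, n_classes))
    for t, p in zip(true, pred):
        mat[t, p] += 1
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * mat / sums
    out[sums.ravel() == 0] = np.nan
    return out
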