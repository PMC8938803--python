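"""A compact, deterministic numpy CNN scoring hybrid pre/post ROIs.

The network is a configurable stack of 3x3 'same' convolutions (ReLU) and
2x2 max-pools followed by a single dense logistic unit, trained with Adam on
binary cross-entropy.  The default (conv8-pool-conv16-pool-dense) is sized
for 32x32 hybrids; the pipeline contract — per-case leave-one-case-out
scores with a hard leakage guarantee — is what matters, not the
architecture.  All randomness (weight init, batch order) flows from the
config seed, so identical configs give bit-identical scores.

Per-case scores are the arithmetic mean of the trained scorer over all
hybrids of the case; cross-validation leaves out one case at a time (LOCO)
or, as a faster approximation, grouped class-balanced folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import CasePair, HybridROI, InputError
from . import roi_hybrid

__all__ = [
    "DlConfig",
    "TrainingError",
    "FoldError",
    "CnnScorer",
    "train_cnn",
    "score_case",
    "loco_dl_scores",
]


class TrainingError(ValueError):
    """Training set does not support fitting (e.g. one class missing)."""


class FoldError(ValueError):
    """A cross-validation fold is degenerate."""


@dataclass
class DlConfig:
    """Architecture and training settings for the hybrid-ROI CNN."""

    layers: tuple = (("conv", 8, 3), ("pool", 2), ("conv", 16, 3), ("pool", 2))
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise InputError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise InputError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv:
    def __init__(self, in_ch: int, filters: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0.0, scale, size=(filters, in_ch * k * k))
        self.b = np.zeros(filters)
        self.k = k
        self.in_ch = in_ch
        self.filters = filters

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * self.k**2)
        out = cols @ self.W.T + self.b
        self._cache = (cols, (n, c, h, w))
        return out.transpose(0, 2, 1).reshape(n, self.filters, h, w)

    def backward(self, dout: np.ndarray, grads: dict, key: str) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        d = dout.reshape(n, self.filters, h * w).transpose(0, 2, 1)
        grads[key + ".W"] = np.einsum("npf,npc->fc", d, cols)
        grads[key + ".b"] = d.sum(axis=(0, 1))
        dcols = d @ self.W
        pad = self.k // 2
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        d6 = dcols.reshape(n, h, w, c, self.k, self.k)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + h, dj : dj + w] += d6[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, pad : pad + h, pad : pad + w]

    def params(self):
        return {"W": self.W, "b": self.b}


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Pool:
    def __init__(self, size: int = 2):
        self.s = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.s
        ho, wo = h // s, w // s
        xc = x[:, :, : ho * s, : wo * s]
        r = (
            xc.reshape(n, c, ho, s, wo, s)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho, wo, s * s)
        )
        self._idx = r.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        s = self.s
        ho, wo = h // s, w // s
        dr = np.zeros((n, c, ho, wo, s * s))
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : ho * s, : wo * s] = (
            dr.reshape(n, c, ho, wo, s, s)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * s, wo * s)
        )
        return dx


class _Net:
    """Conv/pool stack plus a dense logistic output."""

    def __init__(self, input_hw: tuple[int, int], layers: tuple, rng):
        self.layers = []
        c, (h, w) = 1, input_hw
        for spec in layers:
            if spec[0] == "conv":
                _, filters, k = spec
                self.layers.append(("conv", _Conv(c, filters, k, rng)))
                self.layers.append(("relu", _ReLU()))
                c = filters
            elif spec[0] == "pool":
                s = spec[1]
                self.layers.append(("pool", _Pool(s)))
                h, w = h // s, w // s
            else:
                raise InputError(f"unknown layer spec {spec!r}")
        if h < 1 or w < 1:
            raise InputError("architecture pools the input away")
        self.flat_dim = c * h * w
        self.wd = rng.normal(0.0, 1.0 / np.sqrt(self.flat_dim), size=self.flat_dim)
        self.bd = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x[:, None, :, :]
        for _, layer in self.layers:
            h = layer.forward(h)
        self._flat = h.reshape(h.shape[0], -1)
        z = self._flat @ self.wd + self.bd
        return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))

    def backward(self, p: np.ndarray, y: np.ndarray) -> dict:
        n = p.size
        grads: dict[str, np.ndarray] = {}
        dz = (p - y) / n
        grads["dense.W"] = self._flat.T @ dz
        grads["dense.b"] = np.array(dz.sum())
        dh = np.outer(dz, self.wd).reshape(
            (n,) + self._pre_flat_shape()
        )
        for i in range(len(self.layers) - 1, -1, -1):
            kind, layer = self.layers[i]
            if kind == "conv":
                dh = layer.backward(dh, grads, f"layer{i}")
            else:
                dh = layer.backward(dh)
        return grads

    def _pre_flat_shape(self):
        # shape of the last feature map, recovered from the cached flat array
        for kind, layer in reversed(self.layers):
            if kind == "pool":
                n, c, h, w = layer._shape
                s = layer.s
                return (c, h // s, w // s)
            if kind == "conv":
                _, (n, c, h, w) = layer._cache
                return (layer.filters, h, w)
        return (self.flat_dim,)

    def parameters(self) -> dict:
        params = {"dense.W": self.wd, "dense.b": np.array(self.bd)}
        for i, (kind, layer) in enumerate(self.layers):
            if kind == "conv":
                params[f"layer{i}.W"] = layer.W
                params[f"layer{i}.b"] = layer.b
        return params

    def apply_update(self, updates: dict) -> None:
        for i, (kind, layer) in enumerate(self.layers):
            if kind == "conv":
                layer.W += updates[f"layer{i}.W"]
                layer.b += updates[f"layer{i}.b"]
        self.wd += updates["dense.W"]
        self.bd += float(updates["dense.b"])


class _Adam:
    def __init__(self, keys, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, grads: dict) -> dict:
        self.t += 1
        updates = {}
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            updates[k] = -self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return updates


# ---------------------------------------------------------------------------
# training and scoring
# ---------------------------------------------------------------------------


class CnnScorer:
    """A trained CNN plus the training fold's normalization constants."""

    def __init__(self, net: _Net, mean: float, sd: float):
        self._net = net
        self._mean = mean
        self._sd = sd

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Map patches (n, h, w) or a single (h, w) patch to [0, 1] scores."""
        patches = np.asarray(patches, dtype=float)
        single = patches.ndim == 2
        if single:
            patches = patches[None]
        x = (patches - self._mean) / self._sd
        p = self._net.forward(x)
        return float(p[0]) if single else p


def train_cnn(hybrids: list[HybridROI], config: DlConfig) -> CnnScorer:
    """Train the CNN on labeled hybrids; deterministic for a fixed seed."""
    if not hybrids:
        raise TrainingError("empty training set")
    X = np.stack([h.pixels for h in hybrids]).astype(float)
    y = np.array([h.label for h in hybrids], dtype=float)
    if y.min() == y.max():
        missing = "T0" if y.max() == 0 else ">T0"
        raise TrainingError(f"training set contains no {missing} hybrids")
    mean = float(X.mean())
    sd = float(X.std())
    if sd == 0:
        sd = 1.0
    Xn = (X - mean) / sd

    rng = np.random.default_rng(config.seed)
    net = _Net(X.shape[1:], config.layers, rng)
    opt = _Adam(net.parameters().keys(), config.learning_rate)
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            p = net.forward(Xn[idx])
            grads = net.backward(p, y[idx])
            net.apply_update(opt.step(grads))
    return CnnScorer(net, mean, sd)


def score_case(scorer: CnnScorer, hybrids_of_case: list[HybridROI]) -> float:
    """Per-case DL score: mean scorer output over the case's hybrids."""
    if not hybrids_of_case:
        raise InputError("empty hybrid list")
    case_ids = {h.case_id for h in hybrids_of_case}
    if len(case_ids) != 1:
        raise InputError(f"mixed case_ids in one scoring call: {sorted(case_ids)}")
    X = np.stack([h.pixels for h in hybrids_of_case]).astype(float)
    return float(np.mean(scorer.predict(X)))


def _make_folds(cases: list[CasePair], mode: str, n_folds: int | None):
    """Fold assignment: LOCO (one case per fold) or class-balanced grouped."""
    if mode == "loco":
        return [[i] for i in range(len(cases))]
    if mode != "grouped":
        raise InputError(f"unknown cv mode {mode!r}")
    if not n_folds or n_folds < 2:
        raise InputError("grouped mode needs n_folds >= 2")
    order = sorted(range(len(cases)), key=lambda i: (cases[i].responded, cases[i].case_id))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for pos, i in enumerate(order):
        folds[pos % n_folds].append(i)
    return [f for f in folds if f]


def loco_dl_scores(
    cases: list[CasePair],
    config: DlConfig,
    mode: str = "loco",
    n_folds: int | None = None,
    cap: int | None = 16,
    min_area: int = roi_hybrid.MIN_SLICE_AREA,
    roi_height: int = roi_hybrid.ROI_HEIGHT,
    roi_width: int = roi_hybrid.ROI_WIDTH,
) -> dict[str, float]:
    """Cross-validated per-case DL scores.

    For each fold the network is trained on all hybrids from the other
    cases only, then applied to the held-out cases' hybrids and averaged.
    A hard assertion guarantees no held-out hybrid enters its own training
    fold.  ``mode='grouped'`` with ``n_folds`` trades fold purity granularity
    for speed (documented approximation of case-level LOCO).
    """
    if len(cases) < 3:
        raise InputError("need at least 3 cases")
    labels = [c.responded for c in cases]
    if all(labels) or not any(labels):
        raise TrainingError("both classes must be represented")

    per_case = []
    for i, case in enumerate(cases):
        per_case.append(
            roi_hybrid.case_hybrids(
                case,
                roi_height=roi_height,
                roi_width=roi_width,
                min_area=min_area,
                cap=cap,
                seed=(config.seed * 100003 + i) % (2**31),
            )
        )

    scores: dict[str, float] = {}
    for fold in _make_folds(cases, mode, n_folds):
        held = {cases[i].case_id for i in fold}
        train_hybrids = [
            h
            for i, hybs in enumerate(per_case)
            if i not in fold
            for h in hybs
        ]
        # hard leakage guard: no held-out hybrid in this training fold
        assert all(h.case_id not in held for h in train_hybrids)
        train_labels = {h.label for h in train_hybrids}
        if len(train_labels) < 2:
            raise FoldError(
                "a class has fewer than the required cases after holding out "
                f"{sorted(held)}"
            )
        counts = [
            sum(1 for i in range(len(cases)) if i not in fold and labels[i]),
            sum(1 for i in range(len(cases)) if i not in fold and not labels[i]),
        ]
        if min(counts) < 2:
            raise FoldError(
                f"fewer than 2 training cases in a class after holding out "
                f"{sorted(held)}"
            )
        scorer = train_cnn(train_hybrids, config)
        for i in fold:
            scores[cases[i].case_id] = score_case(scorer, per_case[i])
    return scores
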