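"""Minimal NumPy CNN backend: tiny patch classifier, RAdam, weighted loss.

Implements exactly what the staging pipeline needs: a small convolutional
classifier over 256x256 RGB patches with a 512-dimensional penultimate
feature vector, the rectified-Adam optimizer, and the class-weighted
cross-entropy loss

    L = - sum_n w_{y_n} log softmax(x_n)_{y_n} / sum_n w_{y_n}

(weight-normalized mean over the minibatch).  Everything is float32,
fully seeded and single-threaded deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# loss

def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, weights: np.ndarray,
    return_grad: bool = False, reduction: str = "weighted_mean",
):
    """Class-weighted softmax cross-entropy.

    ``logits``: (N, C); ``y``: (N,) int class indices or (N, C) one-hot;
    ``weights``: (C,).  Per-sample loss is ``-w_y * log softmax(x)_y``;
    ``reduction`` is ``"weighted_mean"`` (sum of losses / sum of w_y, the
    training default -- keeps the loss scale stable across class mixes),
    ``"sum"`` or ``"none"``.  With all weights equal to 1 the weighted
    mean reduces exactly to the unweighted mean cross-entropy.
    """
    logits = np.asarray(logits, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if logits.ndim != 2 or weights.shape != (logits.shape[1],):
        raise ValueError("logits must be (N, C) and weights length C")
    y = np.asarray(y)
    if y.ndim == 2:
        if y.shape != logits.shape:
            raise ValueError("one-hot labels must match logits shape")
        y = np.argmax(y, axis=1)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    wy = weights[y]
    per_sample = -(wy * logp[np.arange(len(y)), y])
    if reduction == "none":
        if return_grad:
            raise ValueError("gradient only defined for a reduced loss")
        return per_sample
    if reduction == "sum":
        norm = 1.0
    elif reduction == "weighted_mean":
        norm = wy.sum()
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    loss = float(per_sample.sum() / norm)
    if not return_grad:
        return loss
    p = np.exp(logp)
    grad = p
    grad[np.arange(len(y)), y] -= 1.0
    grad *= wy[:, None] / norm
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# layer primitives (NCHW)

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution via nine shifted matmuls."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, w.shape[0], h, wd), dtype=np.float32)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di : di + h, dj : dj + wd]
            out += np.einsum("oc,nchw->nohw", w[:, :, di, dj], patch,
                             optimize=True)
    return out + b[None, :, None, None]


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di : di + h, dj : dj + wd]
            dw[:, :, di, dj] = np.einsum("nohw,nchw->oc", dy, patch,
                                         optimize=True)
            dxp[:, :, di : di + h, dj : dj + wd] += np.einsum(
                "oc,nohw->nchw", w[:, :, di, dj], dy, optimize=True
            )
    db = dy.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _maxpool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], idx


def _maxpool2_backward(dy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n, c, h2, w2 = dy.shape
    dwin = np.zeros((n, c, h2, w2, 4), dtype=dy.dtype)
    np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
    dwin = dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dwin.reshape(n, c, h2 * 2, w2 * 2)


def _avgpool_forward(x: np.ndarray, k: int) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))


def _avgpool_backward(dy: np.ndarray, k: int) -> np.ndarray:
    return np.repeat(np.repeat(dy, k, axis=2), k, axis=3) / (k * k)


_BN_EPS = 1e-5


def _bn_forward(x, gamma, beta, running, train, momentum=0.1):
    """Batch norm over all but the channel axis (axis 1 for NCHW, axis -1
    for dense activations).  ``running`` is a dict holding mean/var."""
    axes = (0, 2, 3) if x.ndim == 4 else (0,)
    shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
    if train:
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
    out = gamma.reshape(shape) * xhat + beta.reshape(shape)
    return out.astype(np.float32), (xhat, inv)


def _bn_backward(dy, gamma, cache):
    xhat, inv = cache
    axes = (0, 2, 3) if dy.ndim == 4 else (0,)
    shape = (1, -1, 1, 1) if dy.ndim == 4 else (1, -1)
    n = dy.size / dy.shape[1]
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    dxhat = dy * gamma.reshape(shape)
    dx = (
        inv.reshape(shape) / n
        * (n * dxhat - dxhat.sum(axis=axes).reshape(shape)
           - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape))
    )
    return dx.astype(np.float32), dgamma, dbeta


# ---------------------------------------------------------------------------
# tiny CNN

@dataclass
class TinyCNN:
    """Three batch-normed conv blocks -> 512-d feature -> C logits.

    Input 256x256x3 in [0, 1] is centered and average-pooled 4x (a fixed,
    parameter-free downsampling), then passed through three 3x3
    conv/BN/ReLU/maxpool blocks (16, 32, 64 channels), pooled to a 4x4
    map, and mapped through a batch-normed 512-unit hidden layer to the
    class logits.  Batch normalization keeps convergence fast at the
    fixed 1e-3 learning rate despite the few optimization steps a
    desk-scale epoch provides.
    """

    num_classes: int
    seed: int = 0
    input_px: int = 256
    pool_in: int = 4
    channels: tuple[int, int, int] = (16, 32, 64)
    feature_dim: int = 512

    def __post_init__(self) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([41, self.seed & 0x7FFFFFFF]))
        c1, c2, c3 = self.channels
        side = self.input_px // self.pool_in // 8  # three maxpools
        self.flat_side = side // 2                 # final 2x avgpool
        flat = c3 * self.flat_side**2

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(
                np.float32
            )

        self.params: dict[str, np.ndarray] = {
            "w1": he((c1, 3, 3, 3), 27),
            "w2": he((c2, c1, 3, 3), 9 * c1),
            "w3": he((c3, c2, 3, 3), 9 * c2),
            "wf1": he((self.feature_dim, flat), flat),
            "bf1": np.zeros(self.feature_dim, np.float32),
            "wf2": he((self.num_classes, self.feature_dim), self.feature_dim),
            "bf2": np.zeros(self.num_classes, np.float32),
        }
        for name, dim in (("1", c1), ("2", c2), ("3", c3),
                          ("f", self.feature_dim)):
            self.params[f"g{name}"] = np.ones(dim, np.float32)
            self.params[f"be{name}"] = np.zeros(dim, np.float32)
        self.running: dict[str, dict[str, np.ndarray]] = {
            name: {"mean": np.zeros(dim, np.float32),
                   "var": np.ones(dim, np.float32)}
            for name, dim in (("1", c1), ("2", c2), ("3", c3),
                              ("f", self.feature_dim))
        }
        self._zero_bias = {
            "1": np.zeros(c1, np.float32), "2": np.zeros(c2, np.float32),
            "3": np.zeros(c3, np.float32),
        }

    # x: (N, H, W, 3) float32 in [0, 1]
    def forward(self, x: np.ndarray, train: bool = False):
        p = self.params
        a0 = _avgpool_forward(
            np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32)
            - np.float32(0.5),
            self.pool_in,
        )
        z1 = _conv_forward(a0, p["w1"], self._zero_bias["1"])
        n1, c1 = _bn_forward(z1, p["g1"], p["be1"], self.running["1"], train)
        r1 = np.maximum(n1, 0)
        m1, i1 = _maxpool2_forward(r1)
        z2 = _conv_forward(m1, p["w2"], self._zero_bias["2"])
        n2, c2 = _bn_forward(z2, p["g2"], p["be2"], self.running["2"], train)
        r2 = np.maximum(n2, 0)
        m2, i2 = _maxpool2_forward(r2)
        z3 = _conv_forward(m2, p["w3"], self._zero_bias["3"])
        n3, c3 = _bn_forward(z3, p["g3"], p["be3"], self.running["3"], train)
        r3 = np.maximum(n3, 0)
        m3, i3 = _maxpool2_forward(r3)
        g = _avgpool_forward(m3, 2)
        flat = g.reshape(len(x), -1)
        h1 = flat @ p["wf1"].T + p["bf1"]
        nf, cf = _bn_forward(h1, p["gf"], p["bef"], self.running["f"], train)
        hr = np.maximum(nf, 0)
        logits = hr @ p["wf2"].T + p["bf2"]
        if not train:
            return logits
        cache = (a0, n1, c1, m1, i1, n2, c2, m2, i2, n3, c3, m3, i3,
                 g, flat, nf, cf, hr)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        (a0, n1, c1, m1, i1, n2, c2, m2, i2, n3, c3, m3, i3,
         g, flat, nf, cf, hr) = cache
        grads: dict[str, np.ndarray] = {}
        grads["wf2"] = dlogits.T @ hr
        grads["bf2"] = dlogits.sum(axis=0)
        dhr = dlogits @ p["wf2"]
        dnf = dhr * (nf > 0)
        dh1, grads["gf"], grads["bef"] = _bn_backward(dnf, p["gf"], cf)
        grads["wf1"] = dh1.T @ flat
        grads["bf1"] = dh1.sum(axis=0)
        dflat = dh1 @ p["wf1"]
        dg = dflat.reshape(g.shape)
        dm3 = _avgpool_backward(dg, 2)
        dn3 = _maxpool2_backward(dm3, i3) * (n3 > 0)
        dz3, grads["g3"], grads["be3"] = _bn_backward(dn3, p["g3"], c3)
        dm2, grads["w3"], _ = _conv_backward(m2, p["w3"], dz3)
        dn2 = _maxpool2_backward(dm2, i2) * (n2 > 0)
        dz2, grads["g2"], grads["be2"] = _bn_backward(dn2, p["g2"], c2)
        dm1, grads["w2"], _ = _conv_backward(m1, p["w2"], dz2)
        dn1 = _maxpool2_backward(dm1, i1) * (n1 > 0)
        dz1, grads["g1"], grads["be1"] = _bn_backward(dn1, p["g1"], c1)
        _, grads["w1"], _ = _conv_backward(a0, p["w1"], dz1)
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size]).astype(np.float64)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def save(self, path: str | Path) -> None:
        stats = {
            f"run_{name}_{stat}": arr
            for name, d in self.running.items()
            for stat, arr in d.items()
        }
        np.savez(
            path,
            num_classes=self.num_classes, seed=self.seed,
            input_px=self.input_px, pool_in=self.pool_in,
            channels=np.asarray(self.channels), feature_dim=self.feature_dim,
            **self.params, **stats,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TinyCNN":
        with np.load(path) as z:
            model = cls(
                num_classes=int(z["num_classes"]), seed=int(z["seed"]),
                input_px=int(z["input_px"]), pool_in=int(z["pool_in"]),
                channels=tuple(int(c) for c in z["channels"]),
                feature_dim=int(z["feature_dim"]),
            )
            for k in model.params:
                model.params[k] = z[k]
            for name, d in model.running.items():
                for stat in d:
                    d[stat] = z[f"run_{name}_{stat}"]
        return model


# ---------------------------------------------------------------------------
# RAdam

class RAdam:
    """Rectified Adam: warms up as momentum SGD while the adaptive-variance
    estimate is unreliable, then switches to variance-rectified Adam."""

    def __init__(
        self, params: dict[str, np.ndarray], lr: float = 1e-3,
        beta1: float = 0.9, beta2: float = 0.999, epsilon: float = 1e-8,
    ) -> None:
        if not (0 < lr and 0 < beta1 < 1 and 0 < beta2 < 1):
            raise ValueError("invalid RAdam hyperparameters")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, epsilon
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        t, b1, b2 = self.t, self.b1, self.b2
        rho = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        if rho > 4.0:
            r = np.sqrt(
                ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
            )
        for k, p in self.params.items():
            g = grads[k].astype(np.float32)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**t)
            if rho > 4.0:
                v_hat = np.sqrt(self.v[k] / (1 - b2**t))
                p -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p -= self.lr * m_hat
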