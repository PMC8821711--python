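"""Minimal numpy implementation of a small depthwise-separable 1-D CNN.

Three blocks of depthwise convolution (kernel 7, 'same' padding) followed
by pointwise channel mixing and ReLU, global average pooling over time and
a dense logit head.  Trained with Adam on a weighted binary cross-entropy.
Everything is plain numpy with explicit gradients, so training is exactly
reproducible from a seed and carries no framework dependency.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DepthwiseConvNet"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


class DepthwiseConvNet:
    """Depthwise-separable CNN: (B, C_in, T) -> (B,) logits."""

    def __init__(self, channels: tuple[int, ...] = (64, 48, 48, 48),
                 kernel_size: int = 7, seed: int = 0):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.channels = tuple(channels)
        self.k = kernel_size
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for i, (cin, cout) in enumerate(zip(channels[:-1], channels[1:])):
            self.params[f"dw{i}"] = rng.normal(0, 1.0 / np.sqrt(self.k), (cin, self.k))
            self.params[f"dwb{i}"] = np.zeros(cin)
            self.params[f"pw{i}"] = rng.normal(0, 1.0 / np.sqrt(cin), (cout, cin))
            self.params[f"pwb{i}"] = np.zeros(cout)
        self.params["head_w"] = rng.normal(0, 1.0 / np.sqrt(channels[-1]), channels[-1])
        self.params["head_b"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- architecture bookkeeping ------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.channels) - 1

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward / backward ------------------------------------------------
    def _dwconv(self, x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        t = x.shape[2]
        y = np.zeros_like(x)
        for j in range(self.k):
            y += w[None, :, j, None] * xp[:, :, j:j + t]
        return y + b[None, :, None]

    def _dwconv_grads(self, x, w, gy):
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        t = x.shape[2]
        gw = np.zeros_like(w)
        gxp = np.zeros_like(xp)
        for j in range(self.k):
            gw[:, j] = np.sum(gy * xp[:, :, j:j + t], axis=(0, 2))
            gxp[:, :, j:j + t] += w[None, :, j, None] * gy
        gb = gy.sum(axis=(0, 2))
        return gw, gb, gxp[:, :, pad:pad + t]

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        h = x
        for i in range(self.n_blocks):
            z1 = self._dwconv(h, self.params[f"dw{i}"], self.params[f"dwb{i}"])
            z2 = np.einsum("oi,bit->bot", self.params[f"pw{i}"], z1) \
                + self.params[f"pwb{i}"][None, :, None]
            a = np.maximum(z2, 0.0)
            if cache is not None:
                cache.append((h, z1, z2))
            h = a
        pooled = h.mean(axis=2)
        logit = pooled @ self.params["head_w"] + self.params["head_b"][0]
        if cache is not None:
            cache.append((h, pooled))
        return logit

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward(x))

    def _backward(self, cache, glogit):
        grads = {}
        h_last, pooled = cache[-1]
        grads["head_w"] = glogit @ pooled
        grads["head_b"] = np.array([glogit.sum()])
        gpooled = np.outer(glogit, self.params["head_w"])
        t = h_last.shape[2]
        ga = np.repeat(gpooled[:, :, None], t, axis=2) / t
        for i in range(self.n_blocks - 1, -1, -1):
            h, z1, z2 = cache[i]
            gz2 = ga * (z2 > 0)
            grads[f"pw{i}"] = np.einsum("bot,bit->oi", gz2, z1)
            grads[f"pwb{i}"] = gz2.sum(axis=(0, 2))
            gz1 = np.einsum("oi,bot->bit", self.params[f"pw{i}"], gz2)
            gw, gb, gx = self._dwconv_grads(h, self.params[f"dw{i}"], gz1)
            grads[f"dw{i}"] = gw
            grads[f"dwb{i}"] = gb
            ga = gx
        return grads

    # -- training ----------------------------------------------------------
    def train_step(self, x: np.ndarray, y: np.ndarray, sample_weight: np.ndarray,
                   lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> float:
        """One Adam step on weighted BCE; returns the batch loss."""
        cache: list = []
        logit = self.forward(x, cache)
        wsum = sample_weight.sum()
        loss = float(np.sum(sample_weight * (_softplus(logit) - y * logit)) / wsum)
        glogit = sample_weight * (_sigmoid(logit) - y) / wsum
        grads = self._backward(cache, glogit)

        self._adam_t += 1
        t = self._adam_t
        for k_, g in grads.items():
            m = self._adam_m[k_] = beta1 * self._adam_m[k_] + (1 - beta1) * g
            v = self._adam_v[k_] = beta2 * self._adam_v[k_] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k_] -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, channels=np.array(self.channels), kernel=self.k,
                 **self.params)

    @classmethod
    def load(cls, path) -> "DepthwiseConvNet":
        data = np.load(path)
        net = cls(tuple(int(c) for c in data["channels"]), int(data["kernel"]))
        for k_ in net.params:
            net.params[k_] = data[k_]
        return net
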