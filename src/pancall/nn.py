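"""Minimal seeded CNN engine (numpy).

Implements exactly what the genotyper needs: strided 2-D convolutions
(patch extraction via sliding_window_view + one matmul), ReLU, a
mean-over-rows pooling that keeps column localization (the candidate
always sits at the center column), dense layers, softmax cross-entropy,
and Adam. Everything is float32 and driven by a single numpy Generator,
so training is bit-reproducible for a given seed on a given platform.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet", "softmax"]


def _conv_out(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N*Ho*Wo, k*k*C) patch matrix."""
    n, h, w, c = x.shape
    ho, wo = _conv_out(h, k, stride, pad), _conv_out(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    swv = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H',W',C,k,k)
    sel = swv[:, ::stride, ::stride][:, :ho, :wo]
    cols = np.ascontiguousarray(sel.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * ho * wo, k * k * c)


def _col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Scatter-add patch gradients back onto the (padded) input."""
    n, h, w, c = x_shape
    ho, wo = _conv_out(h, k, stride, pad), _conv_out(w, k, stride, pad)
    dpatches = dcols.reshape(n, ho, wo, k, k, c)
    gxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            gxp[
                :, i : i + stride * ho : stride, j : j + stride * wo : stride, :
            ] += dpatches[:, :, :, i, j, :]
    return gxp[:, pad : pad + h, pad : pad + w, :]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """Conv stack -> mean over rows -> flatten(columns x filters) -> dense.

    Pooling over rows only (not columns) is deliberate: pileup rows are an
    unordered population of reads/haplotypes whose aggregate statistics
    matter, while the column axis carries the positional signal centered on
    the candidate, which must not be averaged away.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        conv_layers: tuple[tuple[int, int, int], ...],
        dense_units: tuple[int, ...],
        n_classes: int,
        seed: int,
        dropout: float = 0.0,
    ):
        self.input_shape = tuple(input_shape)
        self.conv_layers = tuple(tuple(l) for l in conv_layers)
        self.dense_units = tuple(dense_units)
        self.n_classes = n_classes
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        h, w, c = input_shape
        for li, (filters, k, stride) in enumerate(self.conv_layers):
            fan_in = k * k * c
            self.params[f"Wc{li}"] = (
                rng.standard_normal((k * k * c, filters)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"bc{li}"] = np.zeros(filters, dtype=np.float32)
            h, w, c = _conv_out(h, k, stride, 1), _conv_out(w, k, stride, 1), filters
        dim = w * c  # after mean over rows
        for di, units in enumerate(self.dense_units):
            self.params[f"Wd{di}"] = (
                rng.standard_normal((dim, units)) * np.sqrt(2.0 / dim)
            ).astype(np.float32)
            self.params[f"bd{di}"] = np.zeros(units, dtype=np.float32)
            dim = units
        self.params["Wout"] = (
            rng.standard_normal((dim, n_classes)) * np.sqrt(2.0 / dim)
        ).astype(np.float32)
        self.params["bout"] = np.zeros(n_classes, dtype=np.float32)
        # Adam state
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    # ---- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[np.ndarray, dict]:
        cache: dict = {"conv": [], "dense": []}
        a = x.astype(np.float32, copy=False)
        for li, (filters, k, stride) in enumerate(self.conv_layers):
            n, h, w, c = a.shape
            ho, wo = _conv_out(h, k, stride, 1), _conv_out(w, k, stride, 1)
            cols = _im2col(a, k, stride, 1)
            z = (cols @ self.params[f"Wc{li}"] + self.params[f"bc{li}"]).reshape(
                n, ho, wo, filters
            )
            out = np.maximum(z, 0.0)
            cache["conv"].append(((n, h, w, c), cols, z, k, stride))
            a = out
        cache["pre_pool_shape"] = a.shape
        n, ho, wo, c = a.shape
        pooled = a.mean(axis=1)  # mean over rows
        flat = pooled.reshape(n, wo * c)
        h_act = flat
        for di in range(len(self.dense_units)):
            z = h_act @ self.params[f"Wd{di}"] + self.params[f"bd{di}"]
            out = np.maximum(z, 0.0)
            mask = None
            if train and self.dropout > 0.0:
                assert rng is not None
                mask = (
                    rng.random(out.shape) >= self.dropout
                ).astype(np.float32) / (1.0 - self.dropout)
                out = out * mask
            cache["dense"].append((h_act, z, mask))
            h_act = out
        logits = h_act @ self.params["Wout"] + self.params["bout"]
        cache["last_hidden"] = h_act
        return logits, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size], train=False)
            out.append(softmax(logits))
        return (
            np.concatenate(out, axis=0)
            if out
            else np.zeros((0, self.n_classes), dtype=np.float32)
        )

    def loss_and_grads(
        self,
        x: np.ndarray,
        y: np.ndarray,
        sample_weight: Optional[np.ndarray] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        n = len(x)
        logits, cache = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        w = (
            sample_weight.astype(np.float32)
            if sample_weight is not None
            else np.ones(n, dtype=np.float32)
        )
        wsum = w.sum()
        eps = 1e-12
        loss = float(-(w * np.log(probs[np.arange(n), y] + eps)).sum() / wsum)

        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (w / wsum)[:, None]

        h_act = cache["last_hidden"]
        grads["Wout"] = h_act.T @ dlogits
        grads["bout"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["Wout"].T
        for di in reversed(range(len(self.dense_units))):
            h_in, z, mask = cache["dense"][di]
            if mask is not None:
                dh = dh * mask
            dz = dh * (z > 0)
            grads[f"Wd{di}"] = h_in.T @ dz
            grads[f"bd{di}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"Wd{di}"].T
        # un-flatten, un-pool
        n_, ho, wo, c = cache["pre_pool_shape"]
        dpooled = dh.reshape(n_, wo, c)
        da = np.broadcast_to(dpooled[:, None, :, :], (n_, ho, wo, c)) / ho
        da = np.ascontiguousarray(da, dtype=np.float32)
        for li in reversed(range(len(self.conv_layers))):
            x_shape, cols, z, k, stride = cache["conv"][li]
            dz = da * (z > 0)
            nb, ho_, wo_, f = dz.shape
            dz2 = dz.reshape(nb * ho_ * wo_, f)
            grads[f"Wc{li}"] = cols.T @ dz2
            grads[f"bc{li}"] = dz2.sum(axis=0)
            if li > 0:  # the input gradient of the first layer is never used
                dcols = dz2 @ self.params[f"Wc{li}"].T
                da = _col2im(dcols, x_shape, k, stride, 1)
        return loss, grads

    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._t += 1
        b1t = 1.0 - beta1 ** self._t
        b2t = 1.0 - beta2 ** self._t
        for key, g in grads.items():
            g = g.astype(np.float32)
            self._m[key] = beta1 * self._m[key] + (1 - beta1) * g
            self._v[key] = beta2 * self._v[key] + (1 - beta2) * g * g
            mhat = self._m[key] / b1t
            vhat = self._v[key] / b2t
            self.params[key] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(
                np.float32
            )

    # ---- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).copy()
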