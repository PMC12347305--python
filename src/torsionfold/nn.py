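"""A small self-contained 1-D convolutional network on numpy.

Architecture used by the fragment predictor: four 1-D convolutional layers
(kernel 4, same-length padding, ReLU, dropout 0.1), one max-pool of size 2,
two dense layers (128 and 256 units, ReLU) and a linear output layer of 18
units.  Trained with mean-squared-error loss and Adam.  Sized for
six-residue one-hot windows; everything runs comfortably on one CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TinyConvNet"]


def _relu(x):
    return np.maximum(x, 0.0)


class TinyConvNet:
    def __init__(self, in_channels: int = 20, seq_len: int = 6,
                 conv_channels: int = 32, n_conv: int = 4, kernel: int = 4,
                 dense: tuple[int, int] = (128, 256), out_dim: int = 18,
                 dropout: float = 0.1, seed: int = 0):
        self.seq_len = seq_len
        self.kernel = kernel
        self.n_conv = n_conv
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = in_channels
        for l in range(n_conv):
            fan_in = kernel * c_in
            self.params[f"Wc{l}"] = rng.normal(0, np.sqrt(2.0 / fan_in),
                                               (kernel * c_in, conv_channels))
            self.params[f"bc{l}"] = np.zeros(conv_channels)
            c_in = conv_channels
        flat = (seq_len // 2) * conv_channels
        dims = [flat, *dense, out_dim]
        for l in range(len(dims) - 1):
            self.params[f"Wd{l}"] = rng.normal(0, np.sqrt(2.0 / dims[l]),
                                               (dims[l], dims[l + 1]))
            self.params[f"bd{l}"] = np.zeros(dims[l + 1])
        self.n_dense = len(dims) - 1
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------
    def _im2col(self, x):
        # x: (B, L, C) -> padded columns (B, L, K*C)
        k = self.kernel
        pad = np.pad(x, ((0, 0), (k - 2, 1), (0, 0)))
        cols = np.stack([pad[:, t:t + k, :] for t in range(x.shape[1])], axis=1)
        return cols.reshape(x.shape[0], x.shape[1], -1)

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        """x: (B, L, C_in) -> (B, out_dim); returns (output, cache)."""
        cache = {"inputs": [], "cols": [], "zs": [], "masks": []}
        h = x
        for l in range(self.n_conv):
            cols = self._im2col(h)
            z = cols @ self.params[f"Wc{l}"] + self.params[f"bc{l}"]
            a = _relu(z)
            if train and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                a = a * mask
            else:
                mask = None
            cache["inputs"].append(h)
            cache["cols"].append(cols)
            cache["zs"].append(z)
            cache["masks"].append(mask)
            h = a
        # max pool, size 2
        b, L, c = h.shape
        hp = h.reshape(b, L // 2, 2, c)
        arg = hp.argmax(axis=2)
        pooled = hp.max(axis=2)
        cache["pool_in_shape"] = h.shape
        cache["pool_arg"] = arg
        f = pooled.reshape(b, -1)
        cache["dense_in"] = [f]
        cache["dense_z"] = []
        for l in range(self.n_dense):
            z = f @ self.params[f"Wd{l}"] + self.params[f"bd{l}"]
            cache["dense_z"].append(z)
            f = _relu(z) if l < self.n_dense - 1 else z
            cache["dense_in"].append(f)
        return f, cache

    def predict(self, x):
        return self.forward(x, train=False)[0]

    # -- backward ----------------------------------------------------------
    def _backward(self, cache, dout):
        grads = {}
        g = dout
        for l in range(self.n_dense - 1, -1, -1):
            if l < self.n_dense - 1:
                g = g * (cache["dense_z"][l] > 0)
            a_prev = cache["dense_in"][l]
            grads[f"Wd{l}"] = a_prev.T @ g
            grads[f"bd{l}"] = g.sum(axis=0)
            g = g @ self.params[f"Wd{l}"].T
        b, L, c = cache["pool_in_shape"]
        g = g.reshape(b, L // 2, c)
        gpool = np.zeros((b, L // 2, 2, c))
        np.put_along_axis(gpool, cache["pool_arg"][:, :, None, :],
                          g[:, :, None, :], axis=2)
        g = gpool.reshape(b, L, c)
        k = self.kernel
        for l in range(self.n_conv - 1, -1, -1):
            mask = cache["masks"][l]
            if mask is not None:
                g = g * mask
            g = g * (cache["zs"][l] > 0)
            cols = cache["cols"][l]
            grads[f"Wc{l}"] = cols.reshape(-1, cols.shape[-1]).T @ g.reshape(-1, g.shape[-1])
            grads[f"bc{l}"] = g.sum(axis=(0, 1))
            dcols = (g @ self.params[f"Wc{l}"].T).reshape(b, L, k, -1)
            h_prev = cache["inputs"][l]
            dpad = np.zeros((b, L + k - 1, h_prev.shape[-1]))
            for t in range(L):
                dpad[:, t:t + k, :] += dcols[:, t, :, :]
            g = dpad[:, k - 2:k - 2 + L, :]
        return grads

    def train_batch(self, x, y, lr: float, rng: np.random.Generator,
                    beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        """One Adam step on MSE loss; returns the batch loss."""
        out, cache = self.forward(x, train=True, rng=rng)
        diff = out - y
        loss = float(np.mean(diff**2))
        dout = 2.0 * diff / diff.size
        grads = self._backward(cache, dout)
        self._adam_t += 1
        t = self._adam_t
        for kname, gval in grads.items():
            m = self._adam_m[kname] = beta1 * self._adam_m[kname] + (1 - beta1) * gval
            v = self._adam_v[kname] = beta2 * self._adam_v[kname] + (1 - beta2) * gval**2
            mh = m / (1 - beta1**t)
            vh = v / (1 - beta2**t)
            self.params[kname] -= lr * mh / (np.sqrt(vh) + eps)
        return loss

    def mse(self, x, y) -> float:
        return float(np.mean((self.predict(x) - y)**2))

    # -- persistence -------------------------------------------------------
    def save(self, path):
        meta = np.array([self.seq_len, self.kernel, self.n_conv, self.n_dense])
        np.savez(path, __meta__=meta, __dropout__=np.array([self.dropout]),
                 **self.params)

    @classmethod
    def load(cls, path) -> "TinyConvNet":
        data = np.load(path)
        seq_len, kernel, n_conv, _ = (int(v) for v in data["__meta__"])
        c_in = data["Wc0"].shape[0] // kernel
        conv_channels = data["Wc0"].shape[1]
        dense = tuple(data[f"Wd{l}"].shape[1] for l in range(2))
        out_dim = data["Wd2"].shape[1]
        net = cls(in_channels=c_in, seq_len=seq_len, conv_channels=conv_channels,
                  n_conv=n_conv, kernel=kernel, dense=dense, out_dim=out_dim,
                  dropout=float(data["__dropout__"][0]))
        for k in net.params:
            net.params[k] = data[k]
        return net
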