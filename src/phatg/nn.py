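"""A compact feed-forward regression network in NumPy.

Architecture: ``input_dim -> width x hidden_layers -> 1`` with ReLU
activations and inverted dropout after every hidden layer. Training
minimises mean squared error with the Adam optimizer under a half-cosine
learning-rate schedule (annealed per step from the initial rate to ~0
over the full run, no restarts). All randomness — weight initialisation,
minibatch shuffling, dropout masks — flows from a single seed, so
training is bit-reproducible run-to-run on one platform.

Implementation notes: parameters live in one flat float32 buffer with
per-layer views, so the Adam update is a handful of vectorised passes;
GEMMs write into preallocated buffers. float32 doubles BLAS throughput
on one core and costs nothing at these scales. The second-moment
accumulator is floored at 1e-30 to keep decayed entries out of the
float32 denormal range, which x86 handles at a large slowdown.
"""

from __future__ import annotations

import math
from typing import List

import numpy as np


class MLPRegressorNet:
    """Fully-connected ReLU regressor with dropout, Adam and cosine LR."""

    def __init__(
        self,
        input_dim: int,
        hidden_layers: int = 7,
        width: int = 512,
        dropout_rate: float = 0.2,
        seed: int = 0,
    ) -> None:
        if input_dim < 1 or hidden_layers < 1 or width < 1:
            raise ValueError("input_dim, hidden_layers and width must be >= 1")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
        self.input_dim = input_dim
        self.hidden_layers = hidden_layers
        self.width = width
        self.dropout_rate = dropout_rate
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        dims = [input_dim] + [width] * hidden_layers + [1]
        self._dims = dims
        sizes = [dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1)]
        self._theta = np.empty(sum(sizes), dtype=np.float32)
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        off = 0
        for i in range(len(dims) - 1):
            nw = dims[i] * dims[i + 1]
            w = self._theta[off : off + nw].reshape(dims[i], dims[i + 1])
            # He (fan-in) init, appropriate for ReLU
            w[...] = (
                self._rng.standard_normal((dims[i], dims[i + 1]))
                * math.sqrt(2.0 / dims[i])
            ).astype(np.float32)
            off += nw
            bv = self._theta[off : off + dims[i + 1]]
            bv[...] = 0.0
            off += dims[i + 1]
            self.W.append(w)
            self.b.append(bv)

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 500,
        initial_lr: float = 2e-3,
        batch_size: int = 32,
        lr_schedule: str = "cosine",
    ) -> "MLPRegressorNet":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {X.shape[1]}")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training data")
        if lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr_schedule {lr_schedule!r}")

        n = X.shape[0]
        batch_size = min(batch_size, n)
        steps_per_epoch = math.ceil(n / batch_size)
        total_steps = epochs * steps_per_epoch
        theta = self._theta
        grad = np.zeros_like(theta)
        adam_m = np.zeros_like(theta)
        adam_v = np.zeros_like(theta)
        scratch = np.empty_like(theta)
        flush = np.empty(theta.shape, dtype=bool)
        beta1, beta2, eps = np.float32(0.9), np.float32(0.999), np.float32(1e-8)
        keep = np.float32(1.0 - self.dropout_rate)
        inv_keep = np.float32(1.0 / keep)
        L = self.hidden_layers
        dims = self._dims

        # per-layer gradient views into the flat gradient buffer
        gW: List[np.ndarray] = []
        gb: List[np.ndarray] = []
        off = 0
        for i in range(L + 1):
            nw = dims[i] * dims[i + 1]
            gW.append(grad[off : off + nw].reshape(dims[i], dims[i + 1]))
            off += nw
            gb.append(grad[off : off + dims[i + 1]])
            off += dims[i + 1]

        # activation / backprop buffers per distinct batch size
        def make_bufs(m: int):
            acts = [np.empty((m, dims[i + 1]), dtype=np.float32) for i in range(L)]
            back = [np.empty((m, dims[i + 1]), dtype=np.float32) for i in range(L)]
            out = np.empty((m, 1), dtype=np.float32)
            return acts, back, out

        bufs = {}
        t = 0
        for _ in range(epochs):
            order = self._rng.permutation(n)
            for s in range(0, n, batch_size):
                idx = order[s : s + batch_size]
                xb = X[idx]
                yb = y[idx]
                m = len(idx)
                if m not in bufs:
                    bufs[m] = make_bufs(m)
                acts, back, out = bufs[m]
                # forward with inverted dropout
                a = xb
                for i in range(L):
                    np.matmul(a, self.W[i], out=acts[i])
                    acts[i] += self.b[i]
                    np.maximum(acts[i], 0.0, out=acts[i])
                    if keep < 1.0:
                        mask = self._rng.random(acts[i].shape, dtype=np.float32)
                        acts[i] *= mask < keep
                        acts[i] *= inv_keep
                    a = acts[i]
                np.matmul(a, self.W[L], out=out)
                out += self.b[L]
                # backward (MSE)
                g = out.ravel() - yb
                g *= np.float32(2.0 / m)
                g2 = g[:, None]
                np.matmul(acts[L - 1].T, g2, out=gW[L])
                gb[L][...] = g2.sum(axis=0)
                ga = np.matmul(g2, self.W[L].T, out=back[L - 1])
                for i in range(L - 1, -1, -1):
                    ga *= acts[i] > 0
                    prev = xb if i == 0 else acts[i - 1]
                    np.matmul(prev.T, ga, out=gW[i])
                    np.sum(ga, axis=0, out=gb[i])
                    if i > 0:
                        ga = np.matmul(ga, self.W[i].T, out=back[i - 1])
                # LR schedule + Adam update (vectorised on the flat buffers)
                t += 1
                if lr_schedule == "cosine":
                    lr = 0.5 * initial_lr * (1.0 + math.cos(math.pi * t / total_steps))
                else:
                    lr = initial_lr
                np.multiply(adam_m, beta1, out=adam_m)
                np.multiply(grad, np.float32(1 - beta1), out=scratch)
                adam_m += scratch
                # dead units receive exactly-zero gradients, so their first
                # moment decays geometrically into float32 denormals, which
                # x86 processes at a large penalty; flush them to zero
                np.absolute(adam_m, out=scratch)
                np.greater(scratch, np.float32(1e-30), out=flush)
                adam_m *= flush
                np.multiply(adam_v, beta2, out=adam_v)
                np.multiply(grad, grad, out=scratch)
                scratch *= np.float32(1 - beta2)
                adam_v += scratch
                # floor keeps decayed second moments out of denormal range
                np.maximum(adam_v, np.float32(1e-30), out=adam_v)
                bc1 = np.float32(1.0 - beta1 ** t)
                bc2 = np.float32(1.0 - beta2 ** t)
                np.divide(adam_v, bc2, out=scratch)
                np.sqrt(scratch, out=scratch)
                scratch += eps
                np.divide(adam_m, scratch, out=scratch)
                scratch *= np.float32(lr / bc1)
                theta -= scratch
        return self

    # -------------------------------------------------------------- predict

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout disabled at inference)."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(f"expected (n, {self.input_dim}) input, got {X.shape}")
        a = X
        for i in range(self.hidden_layers):
            a = np.maximum(a @ self.W[i] + self.b[i], 0.0)
        out = a @ self.W[self.hidden_layers] + self.b[self.hidden_layers]
        return out.ravel().astype(np.float64)

    # ---------------------------------------------------------- persistence

    @property
    def n_parameters(self) -> int:
        return int(self._theta.size)

    def state_dict(self) -> dict:
        d = {f"W{i}": w for i, w in enumerate(self.W)}
        d.update({f"b{i}": b for i, b in enumerate(self.b)})
        return d

    def load_state_dict(self, state: dict) -> None:
        for i in range(self.hidden_layers + 1):
            np.copyto(self.W[i], np.asarray(state[f"W{i}"], dtype=np.float32))
            np.copyto(self.b[i], np.asarray(state[f"b{i}"], dtype=np.float32))


def lsq_training_mse(X: np.ndarray, y: np.ndarray) -> float:
    """Training MSE of the ordinary least-squares fit (with intercept).

    The attainable optimum for any model at least as expressive as a
    linear map; used as an independent yardstick for network training.
    """
    X1 = np.column_stack([np.asarray(X, dtype=float), np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(X1, np.asarray(y, dtype=float), rcond=None)
    resid = X1 @ coef - y
    return float(np.mean(resid**2))
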