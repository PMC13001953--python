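"""Feed-forward regression network in numpy.

Architecture: per hidden block ``linear -> batch-norm -> SiLU -> dropout``
with a residual connection around the block (identity skip when widths match,
otherwise a linear projection), followed by a final linear output of size 1.
Training minimizes mean squared error with AdamW (decoupled weight decay),
mini-batches, cosine-annealing warm restarts on the learning rate, and early
stopping on a held-out validation fraction.  Dropout and batch statistics are
only active during training; prediction is deterministic.

Implemented directly on numpy arrays (forward and backward passes are
hand-written), which keeps the model dependency-free and makes input
gradients — needed for integrated-gradients attribution — exact and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


@dataclass
class AnnArchitecture:
    """Layer sizes and training hyperparameters for the regression network."""

    input_dim: int
    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    dropout_rates: tuple[float, ...] = (0.4, 0.3, 0.2)
    learning_rate: float = 5e-4
    weight_decay: float = 5e-5
    lr_restart_interval: int = 20
    min_lr: float = 1e-6
    batch_size: int = 32
    epochs: int = 200
    val_fraction: float = 0.1
    patience: int = 25

    def __post_init__(self):
        if len(self.hidden_sizes) != len(self.dropout_rates):
            raise ValueError("hidden_sizes and dropout_rates must align")
        if any(not (0.0 <= p < 1.0) for p in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")


def silu(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s


def _silu_and_grad(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s, s * (1.0 + x * (1.0 - s))


@dataclass
class _Block:
    W: np.ndarray
    b: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    run_mean: np.ndarray
    run_var: np.ndarray
    P: np.ndarray | None          # projection skip; None means identity
    dropout: float


class NeuralNetRegressor:
    """Residual MLP regressor trained by hand-written backprop."""

    def __init__(self, arch: AnnArchitecture, seed: int = 0):
        self.arch = arch
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._build()
        self.history_: list[dict] = []

    # ------------------------------------------------------------------
    def _build(self):
        rng = self._rng
        self.blocks: list[_Block] = []
        fan_in = self.arch.input_dim
        for width, p in zip(self.arch.hidden_sizes, self.arch.dropout_rates):
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, width))
            P = None if fan_in == width else rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, width))
            self.blocks.append(_Block(
                W=W, b=np.zeros(width),
                gamma=np.ones(width), beta=np.zeros(width),
                run_mean=np.zeros(width), run_var=np.ones(width),
                P=P, dropout=p,
            ))
            fan_in = width
        self.W_out = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, 1))
        self.b_out = np.zeros(1)

    def _params(self):
        out = []
        for blk in self.blocks:
            out.extend([blk.W, blk.b, blk.gamma, blk.beta])
            if blk.P is not None:
                out.append(blk.P)
        out.extend([self.W_out, self.b_out])
        return out

    def _decayed(self):
        """Which parameter slots receive weight decay (weights, not biases/BN)."""
        flags = []
        for blk in self.blocks:
            flags.extend([True, False, False, False])
            if blk.P is not None:
                flags.append(True)
        flags.extend([True, False])
        return flags

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self._params()))

    # ------------------------------------------------------------------
    def _forward(self, X, training: bool, rng=None, cache=None):
        h = X
        for blk in self.blocks:
            z1 = h @ blk.W + blk.b
            if training:
                mu = z1.mean(axis=0)
                var = z1.var(axis=0)
                blk.run_mean = (1 - BN_MOMENTUM) * blk.run_mean + BN_MOMENTUM * mu
                blk.run_var = (1 - BN_MOMENTUM) * blk.run_var + BN_MOMENTUM * var
            else:
                mu, var = blk.run_mean, blk.run_var
            inv_std = 1.0 / np.sqrt(var + BN_EPS)
            xhat = (z1 - mu) * inv_std
            z2 = blk.gamma * xhat + blk.beta
            z3, dz3 = _silu_and_grad(z2)
            if training and blk.dropout > 0.0:
                mask = (rng.uniform(size=z3.shape) >= blk.dropout) / (1.0 - blk.dropout)
                z4 = z3 * mask
            else:
                mask = None
                z4 = z3
            skip = h if blk.P is None else h @ blk.P
            out = z4 + skip
            if cache is not None:
                cache.append((h, z1, xhat, inv_std, dz3, mask))
            h = out
        yhat = (h @ self.W_out + self.b_out).ravel()
        if cache is not None:
            cache.append(h)
        return yhat

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._forward(X, training=False)

    # ------------------------------------------------------------------
    def _backward(self, X, grad_yhat, cache, training=True):
        """Return (param_grads, input_grad) for d loss / d yhat = grad_yhat."""
        h_last = cache[-1]
        B = X.shape[0]
        g = grad_yhat.reshape(-1, 1)
        grads = {}
        grads["W_out"] = h_last.T @ g
        grads["b_out"] = g.sum(axis=0)
        delta = g @ self.W_out.T
        for idx in range(len(self.blocks) - 1, -1, -1):
            blk = self.blocks[idx]
            h_in, z1, xhat, inv_std, dz3, mask = cache[idx]
            d_skip = delta if blk.P is None else None
            if blk.P is not None:
                grads[f"P{idx}"] = h_in.T @ delta
            d4 = delta
            d3 = d4 * mask if mask is not None else d4
            d2 = d3 * dz3
            grads[f"gamma{idx}"] = (d2 * xhat).sum(axis=0)
            grads[f"beta{idx}"] = d2.sum(axis=0)
            dxhat = d2 * blk.gamma
            if training:
                # batch-norm backward through batch statistics
                d1 = inv_std / B * (
                    B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
                )
            else:
                d1 = dxhat * inv_std
            grads[f"W{idx}"] = h_in.T @ d1
            grads[f"b{idx}"] = d1.sum(axis=0)
            delta = d1 @ blk.W.T
            if blk.P is not None:
                delta = delta + d4 @ blk.P.T
            else:
                delta = delta + d_skip
        return grads, delta

    def input_gradients(self, X) -> np.ndarray:
        """d yhat / d x per row, in evaluation mode (deterministic)."""
        X = np.asarray(X, dtype=float)
        cache = []
        self._forward(X, training=False, cache=cache)
        _, dinput = self._backward(X, np.ones(X.shape[0]), cache, training=False)
        return dinput

    # ------------------------------------------------------------------
    def _lr_at(self, epoch: int) -> float:
        T = max(self.arch.lr_restart_interval, 1)
        t_cur = epoch % T
        lr0, lrmin = self.arch.learning_rate, self.arch.min_lr
        return lrmin + 0.5 * (lr0 - lrmin) * (1.0 + np.cos(np.pi * t_cur / T))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        arch = self.arch
        rng = self._rng
        n = X.shape[0]
        n_val = max(1, int(round(arch.val_fraction * n))) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        params = self._params()
        flags = self._decayed()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_state = None
        stale = 0

        order = [f"W{i}" for i in range(len(self.blocks))]
        def grad_list(grads):
            out = []
            for i, blk in enumerate(self.blocks):
                out.extend([grads[f"W{i}"], grads[f"b{i}"], grads[f"gamma{i}"], grads[f"beta{i}"]])
                if blk.P is not None:
                    out.append(grads[f"P{i}"])
            out.extend([grads["W_out"], grads["b_out"]])
            return out

        for epoch in range(arch.epochs):
            lr = self._lr_at(epoch)
            idx = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), arch.batch_size):
                batch = idx[start : start + arch.batch_size]
                if batch.size < 2:
                    continue  # batch-norm needs at least two rows
                xb, yb = Xtr[batch], ytr[batch]
                cache = []
                yhat = self._forward(xb, training=True, rng=rng, cache=cache)
                grad_yhat = 2.0 * (yhat - yb) / yb.size
                grads, _ = self._backward(xb, grad_yhat, cache)
                glist = grad_list(grads)
                step += 1
                for p, gp, mi, vi, decay in zip(params, glist, m, v, flags):
                    mi *= beta1
                    mi += (1 - beta1) * gp
                    vi *= beta2
                    vi += (1 - beta2) * gp * gp
                    mhat = mi / (1 - beta1**step)
                    vhat = vi / (1 - beta2**step)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
                    if decay:
                        p -= lr * arch.weight_decay * p
            if n_val:
                val_mse = float(np.mean((self.predict(Xval) - yval) ** 2))
                self.history_.append({"epoch": epoch, "lr": lr, "val_mse": val_mse})
                if val_mse < best_val - 1e-12:
                    best_val = val_mse
                    best_state = [p.copy() for p in params]
                    stale = 0
                else:
                    stale += 1
                    if stale >= arch.patience:
                        break
        if best_state is not None:
            for p, s in zip(params, best_state):
                p[:] = s
        return self


def ann_forward(network: NeuralNetRegressor, x) -> np.ndarray:
    """Deterministic forward pass (dropout off, running batch statistics)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return network.predict(x)
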