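"""A small 1D convolutional network for 7-class sequence classification.

Architecture: Conv1D(64, k=3) -> ReLU -> Conv1D(128, k=3) -> ReLU ->
dropout(0.2) -> flatten -> dense(256) -> ReLU -> dense(256) -> ReLU ->
dense(7) logits, trained with class-weighted softmax cross-entropy and Adam.
With the default input of 5 frames x 71 features the convolutions reduce the
temporal axis 5 -> 3 -> 1, so the network is deliberately tiny (~139k
parameters) and trains comfortably on a CPU.

Implemented directly on NumPy (im2col convolutions, manual backprop) so the
full train -> predict path is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


def _im2col(X: np.ndarray, k: int) -> np.ndarray:
    """(N, L, C) -> (N, L-k+1, k*C) sliding windows along the time axis."""
    N, L, C = X.shape
    Lo = L - k + 1
    cols = np.empty((N, Lo, k * C), dtype=X.dtype)
    for i in range(k):
        cols[:, :, i * C : (i + 1) * C] = X[:, i : i + Lo, :]
    return cols


def _col2im(dcols: np.ndarray, L: int, C: int, k: int) -> np.ndarray:
    N, Lo, _ = dcols.shape
    dX = np.zeros((N, L, C), dtype=dcols.dtype)
    for i in range(k):
        dX[:, i : i + Lo, :] += dcols[:, :, i * C : (i + 1) * C]
    return dX


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Conv1DNet:
    """Sequential Conv1D/dense network with weighted cross-entropy and Adam."""

    def __init__(
        self,
        input_shape: tuple[int, int] = (5, 71),
        conv_filters: tuple[int, int] = (64, 128),
        kernel_size: int = 3,
        dropout: float = 0.2,
        dense_sizes: tuple[int, ...] = (256, 256, 7),
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        L, C = input_shape
        k = kernel_size
        L1 = L - k + 1
        L2 = L1 - k + 1
        if L2 < 1:
            raise ShapeError(
                f"sequence length {L} too short for two k={k} convolutions"
            )
        self.input_shape = (L, C)
        self.kernel_size = k
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.n_classes = dense_sizes[-1]
        f1, f2 = conv_filters
        flat = L2 * f2
        rng = np.random.default_rng(seed)

        def he(n_in, shape):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=shape)

        sizes = [flat, *dense_sizes]
        self.params = {
            "W1": he(k * C, (k * C, f1)),
            "b1": np.zeros(f1),
            "W2": he(k * f1, (k * f1, f2)),
            "b2": np.zeros(f2),
        }
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:]), start=3):
            self.params[f"W{i}"] = he(a, (a, b))
            self.params[f"b{i}"] = np.zeros(b)
        self._n_dense = len(dense_sizes)
        self._conv_filters = conv_filters
        self._adam_state = None
        # per-feature input standardization, fitted on the training data;
        # raw inputs mix pixel coordinates (~10^2) with effort features of
        # very different magnitudes, which stalls gradient training otherwise
        self.norm_mu = np.zeros(C)
        self.norm_sd = np.ones(C)

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ------------------------------------------------------------------
    def _forward(self, X, train=False, rng=None):
        p = self.params
        k = self.kernel_size
        X = (X - self.norm_mu) / self.norm_sd
        cache = {"X": X}
        cols1 = _im2col(X, k)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        cols2 = _im2col(a1, k)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        if train and self.dropout > 0:
            mask = (rng.random(a2.shape) >= self.dropout) / (1.0 - self.dropout)
            a2 = a2 * mask
            cache["drop_mask"] = mask
        h = a2.reshape(len(X), -1)
        cache.update(cols1=cols1, z1=z1, a1=a1, cols2=cols2, z2=z2, a2=a2)
        acts = [h]
        for i in range(3, 3 + self._n_dense):
            z = acts[-1] @ p[f"W{i}"] + p[f"b{i}"]
            if i < 2 + self._n_dense:  # hidden dense layers get ReLU
                z = np.maximum(z, 0.0)
            acts.append(z)
        cache["dense_acts"] = acts
        return acts[-1], cache

    def _backward(self, cache, dlogits):
        p = self.params
        grads = {}
        acts = cache["dense_acts"]
        d = dlogits
        for i in reversed(range(3, 3 + self._n_dense)):
            a_prev = acts[i - 3]
            grads[f"W{i}"] = a_prev.T @ d
            grads[f"b{i}"] = d.sum(axis=0)
            d = d @ p[f"W{i}"].T
            if i > 3:
                d = d * (a_prev > 0)
        da2 = d.reshape(cache["a2"].shape)
        if "drop_mask" in cache:
            da2 = da2 * cache["drop_mask"]
        dz2 = da2 * (cache["z2"] > 0)
        N2, Lo2, _ = dz2.shape
        grads["W2"] = cache["cols2"].reshape(N2 * Lo2, -1).T @ dz2.reshape(N2 * Lo2, -1)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ p["W2"].T
        da1 = _col2im(dcols2, cache["a1"].shape[1], cache["a1"].shape[2], self.kernel_size)
        dz1 = da1 * (cache["z1"] > 0)
        N1, Lo1, _ = dz1.shape
        grads["W1"] = cache["cols1"].reshape(N1 * Lo1, -1).T @ dz1.reshape(N1 * Lo1, -1)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads

    def _adam_step(self, grads):
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                "v": {k: np.zeros_like(v) for k, v in self.params.items()},
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        for k, g in grads.items():
            st["m"][k] = b1 * st["m"][k] + (1 - b1) * g
            st["v"][k] = b2 * st["v"][k] + (1 - b2) * g * g
            mhat = st["m"][k] / (1 - b1 ** st["t"])
            vhat = st["v"][k] / (1 - b2 ** st["t"])
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------------
    def loss_and_accuracy(self, X, y, class_weights=None):
        """Mean weighted cross-entropy and plain accuracy over a dataset."""
        proba = self.predict_proba(X)
        n = len(y)
        w = np.ones(n) if class_weights is None else class_weights[y]
        ll = -np.log(np.clip(proba[np.arange(n), y], 1e-12, None))
        loss = float(np.sum(w * ll) / np.sum(w))
        acc = float(np.mean(proba.argmax(axis=1) == y))
        return loss, acc

    def fit(
        self,
        X,
        y,
        X_val=None,
        y_val=None,
        epochs: int = 100,
        batch_size: int = 64,
        class_weights: np.ndarray | None = None,
        early_stopping_patience: int | None = 12,
        seed: int = 0,
    ):
        """Train with Adam; returns the per-epoch history dict.

        Early stopping watches validation accuracy (the weighted validation
        loss is too noisy a signal when rare classes carry large weights) and
        restores the best parameters; disabled when no validation data or
        patience is None.
        """
        self._check_shape(X)
        flat = X.reshape(-1, X.shape[-1])
        self.norm_mu = flat.mean(axis=0)
        sd = flat.std(axis=0)
        sd[sd == 0] = 1.0
        self.norm_sd = sd
        rng = np.random.default_rng(seed)
        history = {"epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
        has_val = X_val is not None and len(X_val) > 0
        best_val, best_params, since_best = -np.inf, None, 0
        n = len(X)
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                Xb, yb = X[idx], y[idx]
                logits, cache = self._forward(Xb, train=True, rng=rng)
                proba = _softmax(logits)
                wb = np.ones(len(yb)) if class_weights is None else class_weights[yb]
                dlogits = proba.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits *= (wb / wb.sum())[:, None]
                self._adam_step(self._backward(cache, dlogits))
            tr_loss, tr_acc = self.loss_and_accuracy(X, y, class_weights)
            history["epoch"].append(epoch)
            history["train_loss"].append(tr_loss)
            history["train_acc"].append(tr_acc)
            if has_val:
                vl, va = self.loss_and_accuracy(X_val, y_val, class_weights)
            else:
                vl, va = np.nan, np.nan
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            if has_val and early_stopping_patience is not None:
                if va > best_val + 1e-9:
                    best_val, since_best = va, 0
                    best_params = {k: v.copy() for k, v in self.params.items()}
                else:
                    since_best += 1
                    if since_best >= early_stopping_patience:
                        break
        if best_params is not None:
            self.params = best_params
        return history

    def _check_shape(self, X):
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise ShapeError(
                f"expected input (N, {self.input_shape[0]}, {self.input_shape[1]}), "
                f"got {X.shape}"
            )

    def predict_proba(self, X, batch_size: int = 4096) -> np.ndarray:
        if len(X) == 0:
            return np.zeros((0, self.n_classes))
        self._check_shape(X)
        out = []
        for start in range(0, len(X), batch_size):
            logits, _ = self._forward(X[start : start + batch_size], train=False)
            out.append(_softmax(logits))
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        if len(X) == 0:
            return np.zeros(0, dtype=int)
        return self.predict_proba(X).argmax(axis=1)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "input_shape": np.array(self.input_shape),
            "kernel_size": np.array(self.kernel_size),
            "dropout": np.array(self.dropout),
            "learning_rate": np.array(self.learning_rate),
            "conv_filters": np.array(self._conv_filters),
            "n_dense": np.array(self._n_dense),
            "norm_mu": self.norm_mu,
            "norm_sd": self.norm_sd,
        }
        np.savez(path, **meta, **self.params)

    @classmethod
    def load(cls, path) -> "Conv1DNet":
        with np.load(path) as z:
            net = cls(
                input_shape=tuple(int(v) for v in z["input_shape"]),
                conv_filters=tuple(int(v) for v in z["conv_filters"]),
                kernel_size=int(z["kernel_size"]),
                dropout=float(z["dropout"]),
                learning_rate=float(z["learning_rate"]),
            )
            for k in list(net.params):
                net.params[k] = z[k]
            net.norm_mu = z["norm_mu"]
            net.norm_sd = z["norm_sd"]
        return net
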