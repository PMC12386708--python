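"""A compact NumPy 1D-CNN for multi-class SNP classification.

Architecture: repeated [conv1d -> ReLU -> batch-norm -> max-pool] blocks, a
flatten, three ReLU dense layers and a softmax output, trained with Adam on
the class-balanced focal loss  FL_i = alpha_b (1 - p_ib)^2 CE_i. Forward and
backward passes are implemented explicitly, which also gives exact
gradient-of-output attributions for gradient x input feature scoring.

The estimator follows the scikit-learn API (fit / predict / predict_proba)
and composes with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import focal_alpha

__all__ = ["FocalCNNClassifier", "aggregate_attributions"]


class _Layer:
    params: list  # [(param, grad), ...] filled by subclasses

    def __init__(self):
        self.params = []

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class _Conv1D(_Layer):
    def __init__(self, c_in, c_out, k, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [(self.w, self.dw), (self.b, self.db)]
        self.k = k

    def forward(self, x, train):
        self._win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        # windows: (N, C_in, L_out, k) -> (N, C_out, L_out)
        y = np.einsum("nilk,oik->nol", self._win, self.w, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, dy):
        self.dw[...] = np.einsum("nol,nilk->oik", dy, self._win, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2))
        n, c_in, l_in = self._win.shape[0], self.w.shape[1], 0
        l_out = dy.shape[2]
        l_in = l_out + self.k - 1
        dx = np.zeros((n, c_in, l_in))
        for t in range(self.k):
            dx[:, :, t : t + l_out] += np.einsum(
                "nol,oi->nil", dy, self.w[:, :, t], optimize=True
            )
        return dx


class _ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _BatchNorm1D(_Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.params = [(self.gamma, self.dgamma), (self.beta, self.dbeta)]
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        self._train = train
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dy):
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        g_over_std = (self.gamma / self._std)[None, :, None]
        if not self._train:
            return dy * g_over_std
        m = dy.shape[0] * dy.shape[2]
        return g_over_std * (
            dy
            - self.dbeta[None, :, None] / m
            - self._xhat * self.dgamma[None, :, None] / m
        )


class _MaxPool1D(_Layer):
    def __init__(self, pool):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        n, c, length = x.shape
        l_out = length // self.pool
        self._shape = x.shape
        xr = x[:, :, : l_out * self.pool].reshape(n, c, l_out, self.pool)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy):
        n, c, l_out = dy.shape
        dxr = np.zeros((n, c, l_out, self.pool))
        ni, ci, li = np.ogrid[:n, :c, :l_out]
        dxr[ni, ci, li, self._arg] = dy
        dx = np.zeros(self._shape)
        dx[:, :, : l_out * self.pool] = dxr.reshape(n, c, l_out * self.pool)
        return dx


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


class _ReLUFlat(_ReLU):
    pass


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _focal_grad(probs, y_idx, alphas, gamma):
    """Loss value and gradient w.r.t. logits of the mean focal loss."""
    n = probs.shape[0]
    u = np.clip(probs[np.arange(n), y_idx], 1e-15, 1.0)
    a = alphas[y_idx]
    loss = np.mean(a * (1.0 - u) ** gamma * (-np.log(u)))
    # dL/du for each sample
    dl_du = a * (gamma * (1.0 - u) ** (gamma - 1) * np.log(u) - (1.0 - u) ** gamma / u)
    # dp_t/dz_j = u (delta_tj - p_j)
    dz = -probs * (dl_du * u)[:, None]
    dz[np.arange(n), y_idx] += dl_du * u
    return loss, dz / n


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class FocalCNNClassifier(ClassifierMixin, BaseEstimator):
    """1D-CNN multi-class classifier trained with class-balanced focal loss.

    Parameters
    ----------
    n_conv_blocks : int
        Number of [conv -> ReLU -> batch-norm -> max-pool] blocks.
    kernels_per_conv, kernel_size : int
        Filters per conv layer and their width; the width is auto-capped at
        the current input length so short SNP panels work.
    pool_size : int
        Max-pooling window (and stride).
    dense_sizes : tuple of int
        Widths of the three hidden dense layers.
    learning_rate : float
        Adam learning rate.
    gamma : float
        Focal-loss focusing exponent.
    """

    def __init__(
        self,
        n_conv_blocks: int = 2,
        kernels_per_conv: int = 10,
        kernel_size: int = 150,
        pool_size: int = 5,
        dense_sizes: tuple = (128, 64, 32),
        learning_rate: float = 5.0e-5,
        epochs: int = 50,
        batch_size: int = 32,
        gamma: float = 2.0,
        random_state: int = 0,
    ):
        self.n_conv_blocks = n_conv_blocks
        self.kernels_per_conv = kernels_per_conv
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dense_sizes = dense_sizes
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.gamma = gamma
        self.random_state = random_state

    # -- construction -----------------------------------------------------
    def _build(self, input_len: int, n_classes: int, rng) -> list:
        layers: list[_Layer] = []
        c_in, length = 1, input_len
        for blk in range(self.n_conv_blocks):
            # cap the kernel so the conv output still admits one pool window
            k = min(self.kernel_size, length - self.pool_size + 1)
            if k < 1 or length < 1:
                raise ValueError(
                    f"input too short after pooling in block {blk}: "
                    f"length {length} admits no kernel + pool({self.pool_size})"
                )
            layers.append(_Conv1D(c_in, self.kernels_per_conv, k, rng))
            length = length - k + 1
            layers.append(_ReLU())
            layers.append(_BatchNorm1D(self.kernels_per_conv))
            pooled = length // self.pool_size
            if pooled < 1:
                raise ValueError(
                    f"input too short after pooling in block {blk}: "
                    f"conv output length {length} < pool size {self.pool_size}"
                )
            layers.append(_MaxPool1D(self.pool_size))
            length = pooled
            c_in = self.kernels_per_conv
        layers.append(_Flatten())
        width = c_in * length
        for d in self.dense_sizes:
            layers.append(_Dense(width, d, rng))
            layers.append(_ReLUFlat())
            width = d
        layers.append(_Dense(width, n_classes, rng))
        return layers

    def _forward(self, x, train):
        h = x[:, None, :]  # (N, 1, P) single input channel
        for layer in self.layers_:
            h = layer.forward(h, train)
        return h  # logits

    def _backward(self, dlogits):
        g = dlogits
        for layer in reversed(self.layers_):
            g = layer.backward(g)
        return g[:, 0, :]  # gradient w.r.t. the input panel

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (individuals x SNPs)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        counts = np.bincount(y_idx)
        self.alphas_ = focal_alpha(n, counts)
        rng = np.random.default_rng(self.random_state)
        self.layers_ = self._build(p, len(self.classes_), rng)
        params = [pg for layer in self.layers_ for pg in layer.params]
        opt = _Adam(params, self.learning_rate)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self._forward(X[idx], train=True)
                probs = _softmax(logits)
                loss, dz = _focal_grad(probs, y_idx[idx], self.alphas_, self.gamma)
                self._backward(dz)
                opt.step()
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / n)
        self.n_features_in_ = p
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        out = []
        for start in range(0, X.shape[0], 256):
            logits = self._forward(X[start : start + 256], train=False)
            out.append(_softmax(logits))
        return np.vstack(out)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- attribution -------------------------------------------------------
    def input_gradients(self, X) -> np.ndarray:
        """Per-class logit gradients w.r.t. the input: (N, B, P) tensor."""
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        b = len(self.classes_)
        grads = np.empty((n, b, p))
        for start in range(0, n, 256):
            xb = X[start : start + 256]
            for cls in range(b):
                self._forward(xb, train=False)
                dlogits = np.zeros((xb.shape[0], b))
                dlogits[:, cls] = 1.0
                grads[start : start + 256, cls] = self._backward(dlogits)
        return grads

    def attributions(self, X) -> np.ndarray:
        """Gradient x input attribution tensor (N, B, P)."""
        g = self.input_gradients(X)
        return g * np.asarray(X, dtype=float)[:, None, :]


def aggregate_attributions(per_sample_attr: np.ndarray) -> np.ndarray:
    """Per-SNP score: mean over individuals of the class-wise maximum."""
    a = np.asarray(per_sample_attr)
    if a.ndim != 3:
        raise ValueError("attribution tensor must be N x B x P")
    return a.max(axis=1).mean(axis=0)
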