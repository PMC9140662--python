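"""A compact feed-forward / convolutional / recurrent network core.

Implements exactly the building blocks the classifier search needs — dense
layers (tanh/ReLU), 1-D convolution with kernel size 2 and unit stride,
max-pooling, dropout, (bi)directional LSTM — with reverse-mode gradients and
an Adam optimizer, all in float64 numpy. Small by design: the models in this
pipeline have at most a few million parameters and train on one CPU.

Conventions: batches are the leading axis; convolutional/recurrent inputs
are ``(batch, length, channels)``; the loss is class-weighted soft-max
cross-entropy over two output units.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "Conv1D", "MaxPool1D", "Dropout", "Flatten", "LSTM",
    "Sequential", "Adam", "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class Layer:
    """Base class: stateless apart from parameters and forward caches."""

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def params(self):
        return []

    def grads(self):
        return []


class Dense(Layer):
    """Fully connected layer, weights drawn from a seeded normal."""

    def __init__(self, n_in, n_out, activation=None, rng=None):
        rng = rng or np.random.default_rng()
        scale = 1.0 / np.sqrt(n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        if activation not in (None, "tanh", "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self._x = self._z = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False, rng=None):
        self._x = x
        z = x @ self.w + self.b
        self._z = z
        if self.activation == "tanh":
            return np.tanh(z)
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "tanh":
            grad = grad * (1.0 - np.tanh(self._z) ** 2)
        elif self.activation == "relu":
            grad = grad * (self._z > 0)
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Conv1D(Layer):
    """1-D convolution, kernel size 2, unit stride, ReLU activation.

    Input (B, L, C_in) -> output (B, L-1, C_out). Weights use a symmetric
    uniform small-scale initialization, seeded.
    """

    KERNEL = 2

    def __init__(self, c_in, c_out, rng=None):
        rng = rng or np.random.default_rng()
        limit = 1.0 / np.sqrt(self.KERNEL * c_in)
        self.w = rng.uniform(-limit, limit, size=(self.KERNEL, c_in, c_out))
        self.b = np.zeros(c_out)
        self._x = self._z = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] < 2:
            raise ValueError("sequence too short for kernel size 2")
        self._x = x
        z = x[:, :-1, :] @ self.w[0] + x[:, 1:, :] @ self.w[1] + self.b
        self._z = z
        return np.maximum(z, 0.0)

    def backward(self, grad):
        grad = grad * (self._z > 0)
        x = self._x
        self.dw[0] = np.tensordot(x[:, :-1, :], grad, axes=([0, 1], [0, 1]))
        self.dw[1] = np.tensordot(x[:, 1:, :], grad, axes=([0, 1], [0, 1]))
        self.db = grad.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        dx[:, :-1, :] += grad @ self.w[0].T
        dx[:, 1:, :] += grad @ self.w[1].T
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class MaxPool1D(Layer):
    """Max pooling, size 2, stride 2; an odd trailing element is dropped."""

    def forward(self, x, training=False, rng=None):
        b, length, c = x.shape
        l2 = length // 2
        self._in_shape = x.shape
        blocks = x[:, : 2 * l2, :].reshape(b, l2, 2, c)
        self._argmax = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, grad):
        b, l2, c = grad.shape
        dx = np.zeros(self._in_shape)
        blocks = dx[:, : 2 * l2, :].reshape(b, l2, 2, c)
        bi, li, ci = np.ogrid[:b, :l2, :c]
        blocks[bi, li, self._argmax, ci] = grad
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p):
        if not (0 <= p < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng()
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _LSTMDirection:
    """One direction of an LSTM over (B, T, D); gate order [i, f, o, g]."""

    def __init__(self, d_in, n_hidden, rng):
        limit = 1.0 / np.sqrt(n_hidden)
        self.wx = rng.uniform(-limit, limit, size=(d_in, 4 * n_hidden))
        self.wh = rng.uniform(-limit, limit, size=(n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        # forget-gate bias of 1 stabilizes early training (common default)
        self.b[n_hidden: 2 * n_hidden] = 1.0
        self.h = n_hidden
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        b, t, _ = x.shape
        h = self.h
        self._x = x
        self._hs = np.zeros((b, t + 1, h))
        self._cs = np.zeros((b, t + 1, h))
        self._gates = np.zeros((b, t, 4 * h))
        for z in range(t):
            raw = x[:, z, :] @ self.wx + self._hs[:, z, :] @ self.wh + self.b
            i = _sigmoid(raw[:, :h])
            f = _sigmoid(raw[:, h: 2 * h])
            o = _sigmoid(raw[:, 2 * h: 3 * h])
            g = np.tanh(raw[:, 3 * h:])
            c = f * self._cs[:, z, :] + i * g
            self._gates[:, z, :] = np.concatenate([i, f, o, g], axis=1)
            self._cs[:, z + 1, :] = c
            self._hs[:, z + 1, :] = o * np.tanh(c)
        return self._hs[:, 1:, :]

    def backward(self, grad_seq):
        x = self._x
        b, t, _ = x.shape
        h = self.h
        self.dwx.fill(0.0)
        self.dwh.fill(0.0)
        self.db.fill(0.0)
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        for z in range(t - 1, -1, -1):
            gates = self._gates[:, z, :]
            i, f = gates[:, :h], gates[:, h: 2 * h]
            o, g = gates[:, 2 * h: 3 * h], gates[:, 3 * h:]
            c = self._cs[:, z + 1, :]
            c_prev = self._cs[:, z, :]
            tc = np.tanh(c)
            dh = grad_seq[:, z, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            draw = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g ** 2),
                ],
                axis=1,
            )
            self.dwx += x[:, z, :].T @ draw
            self.dwh += self._hs[:, z, :].T @ draw
            self.db += draw.sum(axis=0)
            dx[:, z, :] = draw @ self.wx.T
            dh_next = draw @ self.wh.T
            dc_next = dc * f
        return dx


class LSTM(Layer):
    """(Bi)directional LSTM layer over (B, T, D) inputs.

    ``return_sequences`` keeps the full (B, T, H) output for stacking;
    otherwise only the final step (B, H) is returned. A bidirectional layer
    concatenates the two directions, doubling the output width.
    """

    def __init__(self, d_in, n_hidden, return_sequences=False,
                 bidirectional=False, rng=None):
        rng = rng or np.random.default_rng()
        self.fwd = _LSTMDirection(d_in, n_hidden, rng)
        self.bwd = _LSTMDirection(d_in, n_hidden, rng) if bidirectional else None
        self.return_sequences = return_sequences
        self.n_hidden = n_hidden

    @property
    def output_dim(self):
        return self.n_hidden * (2 if self.bwd is not None else 1)

    def forward(self, x, training=False, rng=None):
        self._t = x.shape[1]
        seq_f = self.fwd.forward(x)
        if self.bwd is None:
            return seq_f if self.return_sequences else seq_f[:, -1, :]
        seq_b = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        if self.return_sequences:
            return np.concatenate([seq_f, seq_b], axis=2)
        # final forward state + final backward state (which saw x[0] last)
        return np.concatenate([seq_f[:, -1, :], seq_b[:, 0, :]], axis=1)

    def backward(self, grad):
        h = self.n_hidden
        t = self._t
        if self.return_sequences:
            grad_f = grad[..., :h]
            grad_b = grad[..., h:] if self.bwd is not None else None
        else:
            grad_f = np.zeros((grad.shape[0], t, h))
            grad_f[:, -1, :] = grad[:, :h]
            if self.bwd is not None:
                grad_b = np.zeros((grad.shape[0], t, h))
                grad_b[:, 0, :] = grad[:, h:]
            else:
                grad_b = None
        dx = self.fwd.backward(grad_f)
        if self.bwd is not None:
            dx = dx + self.bwd.backward(grad_b[:, ::-1, :])[:, ::-1, :]
        return dx

    def params(self):
        out = [self.fwd.wx, self.fwd.wh, self.fwd.b]
        if self.bwd is not None:
            out += [self.bwd.wx, self.bwd.wh, self.bwd.b]
        return out

    def grads(self):
        out = [self.fwd.dwx, self.fwd.dwh, self.fwd.db]
        if self.bwd is not None:
            out += [self.bwd.dwx, self.bwd.dwh, self.bwd.db]
        return out


class Sequential:
    """An ordered layer stack ending in a 2-unit linear (logit) layer."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def predict_proba(self, x, batch_size=256):
        """Class-1 probability per item; dropout disabled, deterministic."""
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start: start + batch_size], training=False)
            out.append(softmax(logits)[:, 1])
        return np.concatenate(out)

    def loss_and_grad(self, x, y, sample_weights, rng=None):
        """Weighted soft-max cross-entropy and its gradient; backprops."""
        logits = self.forward(x, training=True, rng=rng)
        probs = softmax(logits)
        n = len(y)
        eps = 1e-12
        loss = -np.sum(sample_weights * np.log(probs[np.arange(n), y] + eps)) / n
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad *= sample_weights[:, None] / n
        self.backward(grad)
        return loss

    def state_dict(self):
        return {f"p{i}": p.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.params()):
            p[...] = state[f"p{i}"]


class Adam:
    """Adam optimizer (default lr 0.001, betas 0.9/0.999)."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
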