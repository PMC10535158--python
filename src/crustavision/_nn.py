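"""Minimal fully-connected network with an Adam trainer.

The deployed system runs small convolutional models; in this repository the
trainable stages (frame scorer, keypoint regressor) are backed by this tiny
numpy MLP operating on block-pooled pixel features.  It keeps the package
dependency-free of any deep-learning framework while honouring the stage
contracts (single sigmoid output for scorers, 14 linear outputs for the
keypoint head).
"""

from __future__ import annotations

import numpy as np

__all__ = ["TinyMLP", "block_pool"]


def block_pool(image: np.ndarray, factor_y: int, factor_x: int) -> np.ndarray:
    """Mean-pool a 2-D array over non-overlapping blocks.

    Image dimensions must be divisible by the pooling factors.
    """
    h, w = image.shape
    if h % factor_y or w % factor_x:
        raise ValueError(
            f"image shape {image.shape} not divisible by pool factors "
            f"({factor_y}, {factor_x})"
        )
    pooled = image.reshape(h // factor_y, factor_y, w // factor_x, factor_x)
    return pooled.mean(axis=(1, 3))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class TinyMLP:
    """Fully-connected net: ReLU hidden layers, linear or sigmoid output.

    Parameters
    ----------
    sizes:
        Layer widths including input and output, e.g. ``(576, 32, 1)``.
    out_activation:
        ``None`` for a linear head or ``"sigmoid"``.
    zero_init_head:
        Zero the final layer's weights so an untrained model emits exactly
        its (zero) output bias.
    """

    def __init__(
        self,
        sizes: tuple[int, ...],
        out_activation: str | None = None,
        seed: int = 0,
        zero_init_head: bool = False,
    ) -> None:
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        if out_activation not in (None, "sigmoid"):
            raise ValueError(f"unknown output activation {out_activation!r}")
        self.sizes = tuple(int(s) for s in sizes)
        self.out_activation = out_activation
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))
        if zero_init_head:
            self.weights[-1][:] = 0.0

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch forward pass; ``x`` is (n, d_in), returns (n, d_out)."""
        a = np.asarray(x, dtype=float)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _relu(a @ w + b)
        a = a @ self.weights[-1] + self.biases[-1]
        if self.out_activation == "sigmoid":
            a = _sigmoid(a)
        return a

    __call__ = forward

    # -- training ----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int | None = None,
        seed: int = 0,
    ) -> list[float]:
        """Train with Adam on a squared-error objective.

        Minimising the mean squared error also minimises its square root, so
        this serves models whose reported loss is RMSE.  Returns the per-epoch
        loss history.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        n = x.shape[0]
        if batch_size is None or batch_size >= n:
            batch_size = n
        rng = np.random.default_rng(seed)

        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history: list[float] = []

        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                grads, loss = self._backprop(xb, yb)
                epoch_loss += loss * len(idx)
                step += 1
                for i, g in enumerate(grads):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    m_hat = m[i] / (1 - beta1**step)
                    v_hat = v[i] / (1 - beta2**step)
                    params[i] -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            history.append(epoch_loss / n)
        return history

    def _backprop(self, x: np.ndarray, y: np.ndarray):
        n = x.shape[0]
        activations = [x]
        a = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _relu(a @ w + b)
            activations.append(a)
        z_out = a @ self.weights[-1] + self.biases[-1]
        out = _sigmoid(z_out) if self.out_activation == "sigmoid" else z_out

        diff = out - y
        loss = float(np.mean(diff**2))
        delta = 2.0 * diff / (n * y.shape[1])
        if self.out_activation == "sigmoid":
            delta = delta * out * (1.0 - out)

        grad_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
        grad_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore
        for layer in range(len(self.weights) - 1, -1, -1):
            grad_w[layer] = activations[layer].T @ delta
            grad_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (activations[layer] > 0)
        return grad_w + grad_b, loss

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(
            path,
            sizes=np.array(self.sizes),
            out_activation=np.array(self.out_activation or ""),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TinyMLP":
        data = np.load(path, allow_pickle=False)
        sizes = tuple(int(s) for s in data["sizes"])
        act = str(data["out_activation"]) or None
        net = cls(sizes, out_activation=act)
        for i in range(len(net.weights)):
            net.weights[i] = data[f"w{i}"]
            net.biases[i] = data[f"b{i}"]
        return net
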