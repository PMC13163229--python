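"""Layer primitives built on the autodiff engine.

Layers own named parameter tensors and a ``trainable`` flag with Keras-like
semantics: a frozen layer's parameters count as non-trainable, its batch
normalization runs in inference mode, and optimizers skip its parameters.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Param:
    """A named parameter array; ``trainable=False`` marks moving statistics."""

    def __init__(self, name: str, data: np.ndarray, trainable: bool = True):
        self.name = name
        self.tensor = Tensor(data, requires_grad=trainable, name=name)
        self.trainable = trainable

    @property
    def data(self) -> np.ndarray:
        return self.tensor.data

    @data.setter
    def data(self, value: np.ndarray) -> None:
        self.tensor.data = np.asarray(value, dtype=np.float64)

    @property
    def size(self) -> int:
        return self.tensor.data.size


class Layer:
    def __init__(self, name: str):
        self.name = name
        self.trainable = True
        self._params: list[Param] = []
        self.sublayers: list[Layer] = []

    # -- parameter bookkeeping -------------------------------------------
    def add_param(self, name: str, data: np.ndarray, trainable: bool = True) -> Param:
        p = Param(f"{self.name}/{name}", data, trainable)
        self._params.append(p)
        return p

    def params(self) -> list[Param]:
        out = list(self._params)
        for sub in self.sublayers:
            out.extend(sub.params())
        return out

    def trainable_params(self) -> list[Param]:
        out = [p for p in self._params if p.trainable and self.trainable]
        for sub in self.sublayers:
            if self.trainable:
                out.extend(sub.trainable_params())
        return out

    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def trainable_param_count(self) -> int:
        return sum(p.size for p in self.trainable_params())

    def set_trainable(self, flag: bool) -> None:
        self.trainable = flag
        for sub in self.sublayers:
            sub.set_trainable(flag)

    def walk(self):
        yield self
        for sub in self.sublayers:
            yield from sub.walk()

    def get_weights(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in weights:
                raise KeyError(f"missing weight {p.name}")
            if weights[p.name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data = weights[p.name]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv2D(Layer):
    def __init__(self, name, in_channels, filters, kernel, rng, stride=1, padding="same", activation=None):
        super().__init__(name)
        self.stride = stride
        self.padding = padding
        self.activation = activation
        fan_in = kernel * kernel * in_channels
        self.w = self.add_param("kernel", he_normal(rng, (kernel, kernel, in_channels, filters), fan_in))
        self.b = self.add_param("bias", np.zeros(filters))

    def __call__(self, x, training=False):
        y = T.conv2d(x, self.w.tensor, self.b.tensor, stride=self.stride, padding=self.padding)
        if self.activation == "relu":
            y = T.relu(y)
        return y


class DepthwiseConv2D(Layer):
    def __init__(self, name, channels, kernel, rng, activation=None):
        super().__init__(name)
        self.activation = activation
        self.w = self.add_param("kernel", he_normal(rng, (kernel, kernel, channels), kernel * kernel))
        self.b = self.add_param("bias", np.zeros(channels))

    def __call__(self, x, training=False):
        y = T.depthwise_conv2d(x, self.w.tensor, self.b.tensor)
        if self.activation == "relu":
            y = T.relu(y)
        return y


class Dense(Layer):
    def __init__(self, name, in_features, units, rng, activation=None):
        super().__init__(name)
        self.activation = activation
        self.w = self.add_param("kernel", glorot_uniform(rng, (in_features, units), in_features, units))
        self.b = self.add_param("bias", np.zeros(units))

    def __call__(self, x, training=False):
        y = T.matmul(x, self.w.tensor) + self.b.tensor
        if self.activation == "relu":
            y = T.relu(y)
        elif self.activation == "sigmoid":
            y = T.sigmoid(y)
        return y


class BatchNorm(Layer):
    """Channel-wise batch normalization (momentum 0.99, epsilon 1e-3).

    4·C parameters: gamma/beta trainable, moving mean/variance not. When the
    layer is frozen or in inference mode it normalizes with moving statistics.
    """

    def __init__(self, name, channels, momentum=0.99, epsilon=1e-3):
        super().__init__(name)
        self.momentum = momentum
        self.epsilon = epsilon
        self.gamma = self.add_param("gamma", np.ones(channels))
        self.beta = self.add_param("beta", np.zeros(channels))
        self.moving_mean = self.add_param("moving_mean", np.zeros(channels), trainable=False)
        self.moving_var = self.add_param("moving_variance", np.ones(channels), trainable=False)

    def __call__(self, x, training=False):
        axes = tuple(range(x.data.ndim - 1))
        if training and self.trainable:
            mu = T.reduce_mean(x, axis=axes, keepdims=True)
            xm = x - mu
            var = T.reduce_mean(xm * xm, axis=axes, keepdims=True)
            inv = T.pow_const(var + Tensor(self.epsilon), -0.5)
            xhat = xm * inv
            m = self.momentum
            self.moving_mean.data = m * self.moving_mean.data + (1 - m) * mu.data.ravel()
            self.moving_var.data = m * self.moving_var.data + (1 - m) * var.data.ravel()
        else:
            inv_np = 1.0 / np.sqrt(self.moving_var.data + self.epsilon)
            xhat = (x - Tensor(self.moving_mean.data)) * Tensor(inv_np)
        return xhat * self.gamma.tensor + self.beta.tensor


class Dropout(Layer):
    """Inverted dropout; active only in training mode, draws from ``rng``."""

    def __init__(self, name, rate, rng):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x, training=False):
        if not training or self.rate == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class MaxPool2D(Layer):
    def __init__(self, name, pool, stride, padding=0):
        super().__init__(name)
        self.pool = pool
        self.stride = stride
        self.padding = padding

    def __call__(self, x, training=False):
        return T.maxpool2d(x, self.pool, self.stride, self.padding)


def global_average_pool(x: Tensor) -> Tensor:
    return T.reduce_mean(x, axis=(1, 2))


def global_max_pool(x: Tensor) -> Tensor:
    return T.reduce_max(T.reduce_max(x, axis=1), axis=1)
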