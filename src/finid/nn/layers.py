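"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: tracks parameters, child modules, and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {prefix + "param." + k: v.data for k, v in self._params.items()}
        state.update({prefix + "buffer." + k: v
                      for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            state.update(m.named_state(prefix + name + "."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, t in self._params.items():
            t.data = np.asarray(state[prefix + "param." + k], dtype=np.float32)
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + "buffer." + k]
        for name, m in self._modules.items():
            m.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, kernel, stride=1, padding=None,
                 bias=True):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding = stride, padding
        fan_in = cin * kernel * kernel
        self.weight = self.register_param(
            "weight", he_init(rng, (cout, cin, kernel, kernel), fan_in))
        self.bias = (self.register_param("bias", np.zeros(cout, np.float32))
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1):
        super().__init__()
        self.momentum = momentum
        self.gamma = self.register_param("gamma", np.ones(c, np.float32))
        self.beta = self.register_param("beta", np.zeros(c, np.float32))
        self.running_mean = self.register_buffer("running_mean",
                                                 np.zeros(c, np.float32))
        self.running_var = self.register_buffer("running_var",
                                                np.ones(c, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum)


class Linear(Module):
    def __init__(self, rng, cin, cout):
        super().__init__()
        self.weight = self.register_param("weight",
                                          he_init(rng, (cout, cin), cin))
        self.bias = self.register_param("bias", np.zeros(cout, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.linear(x, self.weight, self.bias)


class ConvBNAct(Module):
    """conv -> batchnorm -> leaky ReLU, the detector's basic unit."""

    def __init__(self, rng, cin, cout, kernel=3, stride=1, slope=0.1):
        super().__init__()
        self.conv = Conv2d(rng, cin, cout, kernel, stride, bias=False)
        self.bn = BatchNorm2d(cout)
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return T.leaky_relu(self.bn.forward(self.conv.forward(x)), self.slope)


class BasicBlock(Module):
    """Two 3x3 convolutions with an identity (or projected) shortcut."""

    def __init__(self, rng, cin, cout, stride=1):
        super().__init__()
        self.conv1 = Conv2d(rng, cin, cout, 3, stride, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(rng, cout, cout, 3, 1, bias=False)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(rng, cin, cout, 1, stride, bias=False)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        out = T.relu(self.bn1.forward(self.conv1.forward(x)))
        out = self.bn2.forward(self.conv2.forward(out))
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x))
        else:
            sc = x
        return T.relu(T.add(out, sc))


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m.forward(x)
        return x


def save_checkpoint(path, model: Module, meta: dict | None = None):
    """Serialise parameters + buffers (+ JSON metadata) to an .npz file."""
    import json
    state = model.named_state()
    if meta is not None:
        state["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path):
    import json
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    meta = None
    if "__meta__" in state:
        meta = json.loads(state.pop("__meta__").tobytes().decode())
    return state, meta
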