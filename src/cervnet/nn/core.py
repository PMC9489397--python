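"""Minimal module system for NumPy networks.

Every layer is a :class:`Module` holding :class:`Parameter` objects and (possibly)
sub-modules.  ``forward`` caches whatever ``backward`` needs; ``backward`` receives the
gradient of the loss with respect to the module output and returns the gradient with
respect to the module input, accumulating parameter gradients in ``Parameter.grad``
along the way.  This is the classic explicit-backprop design: there is no tape, the
composite blocks wire their own reverse pass, and correctness is pinned down by
finite-difference tests.
"""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

import numpy as np

__all__ = ["Parameter", "Module", "Sequential"]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class: tracks parameters, sub-modules, buffers and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = name
        object.__setattr__(self, name, np.asarray(value, dtype=np.float64))

    # -- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = "") -> Iterator[Tuple[str, "Module"]]:
        yield (prefix.rstrip("."), self)
        for name, m in self._modules.items():
            yield from m.named_modules(f"{prefix}{name}.")

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield (f"{prefix}{name}", getattr(self, name))
        for name, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{name}.")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- state -----------------------------------------------------------
    def train(self, flag: bool = True) -> "Module":
        object.__setattr__(self, "training", flag)
        for m in self._modules.values():
            m.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {f"param:{k}": p.data for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data[...] = state[f"param:{k}"]
        for k, _ in self.named_buffers():
            self._set_buffer_by_path(k, state[f"buffer:{k}"])

    def _set_buffer_by_path(self, path: str, value: np.ndarray) -> None:
        obj = self
        *parents, leaf = path.split(".")
        for name in parents:
            obj = getattr(obj, name)
        current = getattr(obj, leaf)
        current[...] = value

    # -- computation -----------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    """Chain of modules executed (and back-propagated) in order."""

    def __init__(self, *modules: Module):
        super().__init__()
        self._order = []
        for i, m in enumerate(modules):
            setattr(self, str(i), m)
            self._order.append(m)

    def __iter__(self):
        return iter(self._order)

    def __len__(self):
        return len(self._order)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self._order:
            x = m(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for m in reversed(self._order):
            grad_out = m.backward(grad_out)
        return grad_out
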