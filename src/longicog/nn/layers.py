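"""Neural-network layers built on the autograd core.

Initialisation draws from a caller-supplied :class:`numpy.random.Generator`
so that model construction is fully reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Linear", "Dropout", "LSTM", "count_parameters"]


class Module:
    """Base class: parameter discovery, train/eval mode, zero_grad."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    """Affine map y = xW + b (bias optional), Glorot-uniform initialised."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(rng.uniform(-limit, limit, size=(in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Randomness comes from the
    generator passed at call time so training runs are seed-reproducible."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class LSTMCell(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        k = np.sqrt(1.0 / hidden_size)
        self.w_ih = Tensor(rng.uniform(-k, k, size=(input_size, 4 * hidden_size)),
                           requires_grad=True)
        self.w_hh = Tensor(rng.uniform(-k, k, size=(hidden_size, 4 * hidden_size)),
                           requires_grad=True)
        self.bias = Tensor(np.zeros(4 * hidden_size), requires_grad=True)
        self.hidden_size = hidden_size

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden_size
        z = x @ self.w_ih + h @ self.w_hh + self.bias  # (B, 4H), gate order i f g o
        B = z.shape[0]
        z = z.reshape(B, 4, H)
        zi = z.transpose(1, 0, 2)  # (4, B, H); slicing a Tensor is not supported,
        # so split via per-gate masks on the flat layout instead:
        del zi
        zd = z  # (B, 4, H)
        gates = []
        for g_idx in range(4):
            sel = np.zeros((1, 4, 1))
            sel[0, g_idx, 0] = 1.0
            gates.append((zd * Tensor(sel)).sum(axis=1))  # (B, H)
        i = gates[0].sigmoid()
        f = gates[1].sigmoid()
        g = gates[2].tanh()
        o = gates[3].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class LSTM(Module):
    """Multi-layer LSTM over padded batches; hidden/cell states start at zero.

    ``__call__`` takes a (B, T, F) tensor plus per-sample lengths and returns
    the top-layer hidden state at each sample's own last valid timestep.
    Samples with length 0 yield an exactly-zero hidden state.
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.cells = [
            LSTMCell(input_size if layer == 0 else hidden_size, hidden_size, rng)
            for layer in range(num_layers)
        ]

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        B, T = x.shape[0], (x.shape[1] if x.ndim == 3 else 0)
        H = self.hidden_size
        lengths = np.asarray(lengths, dtype=int)
        final = Tensor(np.zeros((B, H)))
        if T == 0:
            return final
        hs = [Tensor(np.zeros((B, H))) for _ in self.cells]
        cs = [Tensor(np.zeros((B, H))) for _ in self.cells]
        for t in range(T):
            sel = np.zeros((1, T, 1))
            sel[0, t, 0] = 1.0
            xt = (x * Tensor(sel)).sum(axis=1)  # (B, F)
            inp = xt
            # padded steps (t >= length) must not advance the state
            valid = (lengths > t).astype(float)[:, None]  # (B, 1)
            for layer, cell in enumerate(self.cells):
                h_new, c_new = cell(inp, hs[layer], cs[layer])
                hs[layer] = h_new * Tensor(valid) + hs[layer] * Tensor(1.0 - valid)
                cs[layer] = c_new * Tensor(valid) + cs[layer] * Tensor(1.0 - valid)
                inp = hs[layer]
            is_last = (lengths == t + 1).astype(float)[:, None]
            final = final + hs[-1] * Tensor(is_last)
        return final


def count_parameters(module: Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))
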