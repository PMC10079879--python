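"""Depth-wise 1D convolutional front end.

Three stacked layers of length-10 depth-wise filters (valid padding,
stride 1) turn a normalized EEG segment x in R^{S x L} into a feature grid
z3 in R^{S x C x Le} with Le = L - 3*(k-1):

* layer 1 applies one shared bank of C filters to every EEG channel row
  (1 map in -> C maps out, weights shared across channels), so features are
  extracted channel-wise with identical filters everywhere;
* layers 2 and 3 are per-map depth-wise convolutions (C -> C, no cross-map
  mixing) that deepen the temporal receptive field.

The S axis is spatial (EEG channel), C indexes the convolutional filters
and Le is the temporal feature position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Module, Parameter, Tensor


@dataclass(frozen=True)
class ConvConfig:
    """Front-end hyperparameters: kernel length, filter count, the
    nonlinearity applied after layers 1-2 ("gelu" or "linear"), and whether
    per-filter biases are learned (off by default; the segments are already
    z-scored)."""

    kernel: int = 10
    n_filters: int = 120
    activation: str = "gelu"
    bias: bool = False

    @property
    def support(self) -> int:
        """Total kernel support of the three-layer stack."""
        return 3 * (self.kernel - 1) + 1

    def out_length(self, L: int) -> int:
        return L - 3 * (self.kernel - 1)


@dataclass
class FeatureTensor:
    """The front-end output grid with explicit axis semantics:
    values[s, c, t] = (EEG channel s, filter c, temporal position t)."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("FeatureTensor must be (S, C, Le)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


class ConvFrontend(Module):
    """The three-layer depth-wise 1DCNN (see module docstring)."""

    def __init__(self, cfg: ConvConfig = ConvConfig(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        k, c = cfg.kernel, cfg.n_filters
        scale = 1.0 / np.sqrt(k)
        self.w1 = Parameter(scale * rng.standard_normal((c, k)))
        self.w2 = Parameter(scale * rng.standard_normal((c, k)))
        self.w3 = Parameter(scale * rng.standard_normal((c, k)))
        if cfg.bias:
            self.b1 = Parameter(np.zeros(c))
            self.b2 = Parameter(np.zeros(c))
            self.b3 = Parameter(np.zeros(c))

    def _act(self, h: Tensor) -> Tensor:
        return ag.gelu(h) if self.cfg.activation == "gelu" else h

    def _bias(self, h: Tensor, name: str) -> Tensor:
        if not self.cfg.bias:
            return h
        b = getattr(self, name)
        return h + ag.reshape(b, (self.cfg.n_filters, 1))

    def forward(self, x: Tensor) -> Tensor:
        """(..., S, L) -> (..., S, C, L - 3*(k-1))."""
        L = x.shape[-1]
        if L < self.cfg.support:
            raise ValueError(
                f"segment length {L} is below the total kernel support "
                f"{self.cfg.support} of three valid length-{self.cfg.kernel} "
                "convolutions")
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite values in front-end input")
        h = self._act(self._bias(ag.conv1d_bank(x, self.w1), "b1"))
        h = self._act(self._bias(ag.conv1d_depthwise(h, self.w2), "b2"))
        h = self._bias(ag.conv1d_depthwise(h, self.w3), "b3")
        return h

    __call__ = forward


def conv_forward(x: np.ndarray, frontend: ConvFrontend) -> FeatureTensor:
    """Run one segment (S, L) through the front end, returning the S x C x Le
    feature grid as plain arrays (inference convenience wrapper)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a single (S, L) segment")
    with ag.no_grad():
        out = frontend(Tensor(x))
    return FeatureTensor(out.data)
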