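"""CNN decoder head and the training loss.

The encoder output O in R^{M x L1} is reshaped back onto the S x C x M
grid and collapsed in three convolutional steps — (1) a length-C weight
vector contracts the filter axis, (2) an S x N weight mixes the spatial
axis into N decoder filters, (3) a shared (M/2) x M linear map halves the
temporal axis — followed by a fully connected softmax layer.  The loss is
mean categorical cross-entropy plus an L1 penalty lambda * sum|w| over the
trainable weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Module, Parameter, Tensor

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class DecoderConfig:
    """N: filter count of the spatial-mixing layer; lambda_l1: L1 penalty
    constant; activation after the three conv layers ("gelu" or "linear")."""

    n_classes: int
    N: int = 32
    lambda_l1: float = 1e-4
    activation: str = "gelu"

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


class DecoderHead(Module):
    def __init__(self, S: int, C: int, M: int, cfg: DecoderConfig,
                 rng: np.random.Generator | None = None):
        if M % 2 != 0:
            raise ValueError("M must be even (the third layer halves it)")
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.S, self.C, self.M = S, C, M
        self.w1 = Parameter(rng.standard_normal((C, 1)) / np.sqrt(C))
        self.w2 = Parameter(rng.standard_normal((S, cfg.N)) / np.sqrt(S))
        self.w3 = Parameter(rng.standard_normal((M // 2, M)) / np.sqrt(M))
        flat = (M // 2) * cfg.N
        self.W_fc = Parameter(
            rng.standard_normal((flat, cfg.n_classes)) / np.sqrt(flat))
        self.b_fc = Parameter(np.zeros(cfg.n_classes))

    def _act(self, h: Tensor) -> Tensor:
        return ag.gelu(h) if self.cfg.activation == "gelu" else h

    def forward(self, O: Tensor) -> Tensor:
        """(B, M, L1) -> (B, n_classes) class probabilities."""
        B, M, L1 = O.shape
        S, C = self.S, self.C
        if L1 != S * C:
            raise ValueError(f"L1={L1} does not equal S*C={S * C}")
        if not np.all(np.isfinite(O.data)):
            raise ValueError("non-finite decoder input")
        x = ag.transpose(ag.reshape(O, (B, M, S, C)), (0, 2, 3, 1))  # B,S,C,M
        # layer 1: contract the filter axis with w1 in R^{C x 1}
        x1 = ag.reshape(ag.transpose(x, (0, 1, 3, 2)) @ self.w1,
                        (B, S, M))
        x1 = self._act(x1)
        # layer 2: X2[m, n] = sum_s X1[s, m] * w2[s, n]
        x2 = ag.transpose(x1, (0, 2, 1)) @ self.w2                   # B,M,N
        x2 = self._act(x2)
        # layer 3: shared (M/2) x M map applied per decoder filter
        x3 = self.w3 @ x2                                            # B,M/2,N
        x3 = self._act(x3)
        flat = ag.reshape(x3, (B, (M // 2) * self.cfg.N))
        logits = flat @ self.W_fc + self.b_fc
        return ag.softmax(logits, axis=-1)

    __call__ = forward


def decode(O: np.ndarray, head: DecoderHead) -> np.ndarray:
    """Inference wrapper: one M x L1 matrix -> class probability vector."""
    with ag.no_grad():
        probs = head(Tensor(np.asarray(O, dtype=np.float64)[None]))
    return probs.data[0]


def loss(probs: Tensor, labels: np.ndarray,
         weights: Sequence[Parameter] = (), lambda_l1: float = 0.0) -> Tensor:
    """Mean cross-entropy over the batch plus lambda * sum|w|.

    `probs` is (B, n_classes) of valid probabilities; `labels` are class
    indices.  A true-class probability of exactly zero is clamped before
    the log (with a warning) so the loss stays finite.
    """
    labels = np.asarray(labels, dtype=np.intp)
    if labels.min(initial=0) < 0 or (probs.shape[1] and
                                     labels.max(initial=0) >= probs.shape[1]):
        raise ValueError("labels out of range")
    p_true = ag.take_per_row(probs, labels)
    if np.any(p_true.data <= _PROB_FLOOR):
        logger.warning("true-class probability underflow clamped to %g",
                       _PROB_FLOOR)
    ce = -ag.tmean(ag.log(ag.clip_min(p_true, _PROB_FLOOR)))
    if lambda_l1 and weights:
        penalty = None
        for w in weights:
            term = ag.tsum(ag.absolute(w))
            penalty = term if penalty is None else penalty + term
        return ce + lambda_l1 * penalty
    return ce
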