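"""The three-stage encoder over the convolutional feature grid.

The S x C x Le grid from the front end is refined by up to three
transformer stages run serially, each slicing the grid into tokens along a
different axis:

* regional — per EEG channel, the C filter rows (length Le) are the
  patches; output S x C x D;
* synchronous — per filter, the S channel rows (length D) are the patches;
  output C x S x D;
* temporal — the D axis is mean-compressed into M groups, each S x C slab
  is flattened to a length-L1 = S*C patch, and attention runs over the M
  temporal tokens; each output token is projected back to L1, giving the
  encoder output O in R^{M x L1}.

Any non-empty subset of {Reg, Syn, Temp} can be wired (the ablation grid):
a missing regional stage is replaced by a learned linear Le -> D embedding,
and a missing temporal stage by the same averaging compression + flatten
without attention, so every combination produces the canonical M x L1
output the decoder expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .attention import AttentionConfig, TransformerStage
from .autograd import Module, Parameter, Tensor

#: The seven stage combinations of the ablation grid.
ALL_COMBOS: tuple[frozenset[str], ...] = (
    frozenset({"Reg"}), frozenset({"Syn"}), frozenset({"Temp"}),
    frozenset({"Temp", "Syn"}), frozenset({"Temp", "Reg"}),
    frozenset({"Syn", "Reg"}), frozenset({"Temp", "Syn", "Reg"}),
)


def combo_name(combo: frozenset[str]) -> str:
    order = [s for s in ("Temp", "Syn", "Reg") if s in combo]
    return " + ".join(order)


@dataclass(frozen=True)
class EncoderConfig:
    """Geometry and stage settings.

    S, C, Le fix the input grid; attention carries D/A/K/mlp_ratio; M is
    the compressed temporal token count (must divide D); combo selects the
    stages to run.
    """

    S: int
    C: int
    Le: int
    attention: AttentionConfig = AttentionConfig()
    M: int = 10
    combo: frozenset = field(
        default_factory=lambda: frozenset({"Temp", "Syn", "Reg"}))

    def __post_init__(self):
        if not self.combo:
            raise ValueError("combo must name at least one stage")
        unknown = set(self.combo) - {"Reg", "Syn", "Temp"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.attention.D % self.M != 0:
            raise ValueError("M must divide D (temporal mean compression)")

    @property
    def L1(self) -> int:
        return self.S * self.C


def compress_temporal(grid: Tensor, M: int) -> Tensor:
    """(B, C, S, D) -> (B, M, S*C): average consecutive groups of D/M
    latent positions, then flatten each S x C slab."""
    B, C, S, D = grid.shape
    if D % M != 0:
        raise ValueError(f"M={M} does not divide D={D}")
    g = ag.reshape(grid, (B, C, S, M, D // M))
    g = ag.tmean(g, axis=4)                      # (B, C, S, M)
    g = ag.transpose(g, (0, 3, 2, 1))            # (B, M, S, C)
    return ag.reshape(g, (B, M, S * C))


class EEGformerEncoder(Module):
    """Serial Reg -> Syn -> Temp encoder (any subset), (B,S,C,Le) -> (B,M,L1)."""

    def __init__(self, cfg: EncoderConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        att = cfg.attention
        D = att.D
        if "Reg" in cfg.combo:
            self.regional = TransformerStage(cfg.Le, cfg.C, att, rng)
        else:
            # adapter: learned linear embedding of the Le axis into D
            self.embed_adapter = Parameter(
                rng.standard_normal((cfg.Le, D)) / np.sqrt(cfg.Le))
        if "Syn" in cfg.combo:
            self.synchronous = TransformerStage(D, cfg.S, att, rng)
        if "Temp" in cfg.combo:
            self.temporal = TransformerStage(cfg.L1, cfg.M, att, rng)
            self.W_out = Parameter(
                rng.standard_normal((D, cfg.L1)) / np.sqrt(D))

    # -- stage wrappers ------------------------------------------------------

    def regional_forward(self, z3: Tensor) -> Tensor:
        """(B, S, C, Le) -> (B, S, C, D): channels processed independently
        with shared weights."""
        B, S, C, Le = z3.shape
        flat = ag.reshape(z3, (B * S, C, Le))
        out = self.regional(flat)
        return ag.reshape(out, (B, S, C, self.cfg.attention.D))

    def synchronous_forward(self, z4: Tensor) -> Tensor:
        """(B, S, C, D) -> (B, C, S, D): attention over the S channel
        tokens within each filter map."""
        B, S, C, D = z4.shape
        per_filter = ag.transpose(z4, (0, 2, 1, 3))      # (B, C, S, D)
        flat = ag.reshape(per_filter, (B * C, S, D))
        out = self.synchronous(flat)
        return ag.reshape(out, (B, C, S, D))

    def temporal_forward(self, z5: Tensor) -> Tensor:
        """(B, C, S, D) -> (B, M, L1): compress, attend over the M temporal
        tokens, project each token back to L1."""
        patches = compress_temporal(z5, self.cfg.M)      # (B, M, L1)
        out = self.temporal(patches)                     # (B, M, D)
        return out @ self.W_out                          # (B, M, L1)

    # -- full forward --------------------------------------------------------

    def forward(self, z3: Tensor) -> Tensor:
        combo = self.cfg.combo
        if "Reg" in combo:
            grid = self.regional_forward(z3)             # (B, S, C, D)
        else:
            grid = z3 @ self.embed_adapter               # (B, S, C, D)
        if "Syn" in combo:
            grid = self.synchronous_forward(grid)        # (B, C, S, D)
        else:
            grid = ag.transpose(grid, (0, 2, 1, 3))      # (B, C, S, D)
        if "Temp" in combo:
            return self.temporal_forward(grid)
        return compress_temporal(grid, self.cfg.M)

    __call__ = forward
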