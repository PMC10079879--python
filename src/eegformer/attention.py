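"""Shared transformer machinery for the three attention stages.

Each stage (regional / synchronous / temporal) runs the same block
structure over a different tokenization of the feature grid: patches are
linearly embedded into a D-dimensional latent space, a positional term is
added and a learnable classification token is prepended; K pre-norm
encoder blocks of multi-head self-attention (scores softmax(q.k/sqrt(Dh))
over the content tokens plus the classification token) followed by a
residual MLP then refine the tokens.

Conventions: token index 0 is the classification token; LayerNorm is
applied to the block input before the Q/K/V projections (pre-norm) and
again before the MLP; heads are concatenated and projected by W_O back to
D; the MLP is affine-GELU-affine with hidden width mlp_ratio * D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Module, Parameter, Tensor


@dataclass(frozen=True)
class AttentionConfig:
    """Stage hyperparameters: latent dim D, head count A (Dh = D/A), blocks
    per stage K, and the MLP hidden-width multiplier."""

    D: int = 120
    A: int = 8
    K: int = 3
    mlp_ratio: int = 4

    def __post_init__(self):
        if self.D % self.A != 0:
            raise ValueError("D must be divisible by A")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def Dh(self) -> int:
        return self.D // self.A


@dataclass
class TokenGrid:
    """A stage's token collection: content tokens plus the classification
    token (always index 0 of ``tokens``) and the positional table used to
    build them."""

    tokens: np.ndarray          # (n+1, D); row 0 is the classification token
    pos: np.ndarray             # (n, D)
    cls: np.ndarray             # (D,)

    @property
    def content(self) -> np.ndarray:
        return self.tokens[1:]


def embed_patches(patches: np.ndarray, W_embed: np.ndarray,
                  pos: np.ndarray, cls: np.ndarray | None = None) -> TokenGrid:
    """token_i = W_embed @ patch_i + pos_i, with the classification token
    prepended at index 0.  Pure-NumPy reference entry point."""
    patches = np.asarray(patches, dtype=np.float64)
    W = np.asarray(W_embed, dtype=np.float64)
    pos = np.asarray(pos, dtype=np.float64)
    n, P = patches.shape
    D = W.shape[0]
    if W.shape[1] != P:
        raise ValueError(f"W_embed maps length-{W.shape[1]} patches, got {P}")
    if pos.shape != (n, D):
        raise ValueError(f"pos must be ({n}, {D}), got {pos.shape}")
    cls = np.zeros(D) if cls is None else np.asarray(cls, dtype=np.float64)
    if cls.shape != (D,):
        raise ValueError("classification token must be length D")
    content = patches @ W.T + pos
    return TokenGrid(np.concatenate([cls[None, :], content], axis=0), pos, cls)


def attention_scores(q: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """softmax over q.k_j / sqrt(Dh) for all keys (classification token's
    key included): non-negative weights summing to one."""
    q = np.asarray(q, dtype=np.float64)
    keys = np.asarray(keys, dtype=np.float64)
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(keys))):
        raise ValueError("non-finite attention inputs")
    logits = keys @ q / np.sqrt(q.shape[-1])
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


class LayerNorm(Module):
    """Pre-norm LN with learnable gain/bias over the last axis."""

    def __init__(self, D: int):
        self.gain = Parameter(np.ones(D))
        self.bias = Parameter(np.zeros(D))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x) * self.gain + self.bias


class MultiHeadSelfAttention(Module):
    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        D = cfg.D
        scale = 1.0 / np.sqrt(D)
        self.ln = LayerNorm(D)
        self.Wq = Parameter(scale * rng.standard_normal((D, D)))
        self.Wk = Parameter(scale * rng.standard_normal((D, D)))
        self.Wv = Parameter(scale * rng.standard_normal((D, D)))
        self.Wo = Parameter(scale * rng.standard_normal((D, D)))

    def __call__(self, z: Tensor) -> Tensor:
        """(B, n, D) -> (B, n, D); token 0 is the classification token and
        attends like any other."""
        B, n, D = z.shape
        A, Dh = self.cfg.A, self.cfg.Dh
        x = self.ln(z)

        def heads(t: Tensor) -> Tensor:
            return ag.transpose(ag.reshape(t, (B, n, A, Dh)), (0, 2, 1, 3))

        q = heads(x @ self.Wq)
        k = heads(x @ self.Wk)
        v = heads(x @ self.Wv)
        logits = (q @ ag.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(Dh))
        att = ag.softmax(logits, axis=-1)           # (B, A, n, n)
        mixed = att @ v                             # (B, A, n, Dh)
        merged = ag.reshape(ag.transpose(mixed, (0, 2, 1, 3)), (B, n, D))
        return merged @ self.Wo


class MLP(Module):
    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        D, H = cfg.D, cfg.mlp_ratio * cfg.D
        self.W1 = Parameter(rng.standard_normal((D, H)) / np.sqrt(D))
        self.b1 = Parameter(np.zeros(H))
        self.W2 = Parameter(rng.standard_normal((H, D)) / np.sqrt(H))
        self.b2 = Parameter(np.zeros(D))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.gelu(x @ self.W1 + self.b1) @ self.W2 + self.b2


class EncoderBlock(Module):
    """One pre-norm transformer block: z + MHSA(LN(z)), then + MLP(LN(.))."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(cfg, rng)
        self.ln2 = LayerNorm(cfg.D)
        self.mlp = MLP(cfg, rng)

    def __call__(self, z: Tensor) -> Tensor:
        h = z + self.attn(z)
        out = h + self.mlp(self.ln2(h))
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite activation in encoder block")
        return out


def encode_block(tokens: TokenGrid, block: EncoderBlock) -> TokenGrid:
    """Run one block over a TokenGrid (reference/inspection entry point)."""
    with ag.no_grad():
        out = block(Tensor(tokens.tokens[None, :, :]))
    return TokenGrid(out.data[0], tokens.pos, tokens.cls)


class TransformerStage(Module):
    """Patch embedding + positional table + classification token + K blocks.

    Built for a fixed geometry: `n_tokens` content patches of length
    `patch_len`.  forward() embeds, prepends the classification token, runs
    the blocks and returns the content tokens (classification token
    dropped), shape (B, n_tokens, D).
    """

    def __init__(self, patch_len: int, n_tokens: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        D = cfg.D
        self.W_embed = Parameter(
            rng.standard_normal((patch_len, D)) / np.sqrt(patch_len))
        self.pos = Parameter(0.02 * rng.standard_normal((n_tokens, D)))
        self.cls = Parameter(0.02 * rng.standard_normal(D))
        self.blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.K)]

    def forward(self, patches: Tensor) -> Tensor:
        B, n, P = patches.shape
        tokens = patches @ self.W_embed + self.pos
        cls = ag.broadcast_to(ag.reshape(self.cls, (1, 1, self.cfg.D)),
                              (B, 1, self.cfg.D))
        z = ag.concatenate([cls, tokens], axis=1)
        for block in self.blocks:
            z = block(z)
        return z[:, 1:, :]

    __call__ = forward
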