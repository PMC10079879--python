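"""The full pipeline: front end -> encoder stages -> decoder head."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .attention import AttentionConfig
from .autograd import Module, Tensor
from .conv import ConvConfig, ConvFrontend
from .decoder import DecoderConfig, DecoderHead
from .encoder import EncoderConfig, EEGformerEncoder


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to build the network for a fixed input geometry:
    S input channels, L samples per segment, the front-end / attention /
    decoder settings, the temporal token count M, the stage combo, and the
    weight-init seed."""

    S: int
    L: int
    n_classes: int
    conv: ConvConfig = ConvConfig()
    attention: AttentionConfig = AttentionConfig()
    M: int = 10
    combo: frozenset = field(
        default_factory=lambda: frozenset({"Temp", "Syn", "Reg"}))
    decoder_N: int = 32
    lambda_l1: float = 1e-4
    decoder_activation: str = "gelu"
    init_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["combo"] = sorted(self.combo)
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        d["combo"] = frozenset(d["combo"])
        if isinstance(d.get("conv"), dict):
            d["conv"] = ConvConfig(**d["conv"])
        if isinstance(d.get("attention"), dict):
            d["attention"] = AttentionConfig(**d["attention"])
        return ModelConfig(**d)


class EEGformer(Module):
    """End-to-end classifier: (B, S, L) segments -> (B, n_classes) probs."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.init_seed)
        self.cfg = cfg
        self.frontend = ConvFrontend(cfg.conv, rng)
        Le = cfg.conv.out_length(cfg.L)
        if Le < 1:
            raise ValueError(f"segment length {cfg.L} too short for the "
                             "convolutional stack")
        enc_cfg = EncoderConfig(S=cfg.S, C=cfg.conv.n_filters, Le=Le,
                                attention=cfg.attention, M=cfg.M,
                                combo=cfg.combo)
        self.encoder = EEGformerEncoder(enc_cfg, rng)
        self.head = DecoderHead(cfg.S, cfg.conv.n_filters, cfg.M,
                                DecoderConfig(n_classes=cfg.n_classes,
                                              N=cfg.decoder_N,
                                              lambda_l1=cfg.lambda_l1,
                                              activation=cfg.decoder_activation),
                                rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        z3 = self.frontend(x)          # (B, S, C, Le)
        O = self.encoder(z3)           # (B, M, L1)
        return self.head(O)            # (B, n_classes)

    __call__ = forward

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class predictions without building the autodiff graph."""
        x = np.asarray(x, dtype=np.float64)
        out = []
        with ag.no_grad():
            for i in range(0, len(x), batch_size):
                probs = self.forward(x[i:i + batch_size])
                out.append(np.argmax(probs.data, axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=np.int64)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = []
        with ag.no_grad():
            for i in range(0, len(x), batch_size):
                out.append(self.forward(x[i:i + batch_size]).data)
        return np.concatenate(out)

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        """Save config + parameters (named per stage) to an .npz file."""
        import json
        state = self.state_dict()
        np.savez(path, __config__=np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8), **state)

    @staticmethod
    def load(path) -> "EEGformer":
        import json
        with np.load(path) as f:
            cfg = ModelConfig.from_dict(
                json.loads(bytes(f["__config__"]).decode()))
            model = EEGformer(cfg)
            model.load_state_dict(
                {k: f[k] for k in f.files if k != "__config__"})
        return model
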