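"""The dual-channel autoencoder-Transformer network.

Each modality passes through a two-hidden-layer autoencoder (ReLU/ReLU
encoder, ReLU/Sigmoid decoder).  The autoencoder latent vector is reshaped
into ``n_tokens x d_model`` tokens, given sinusoidal positional encoding,
and refined by a stack of multi-head self-attention encoder layers.  The two
token grids are flattened, concatenated and linearly fused; an MLP head
predicts the case probability from the fused vector.  Two Transformer
decoder paths cross-attend to the fused tokens and drive each modality's
autoencoder decoder, producing the cross-modal (cycle) reconstructions that
align the two latent spaces.

The training loss is a weighted sum of five terms: binary cross-entropy for
classification, per-modality mean-squared reconstruction error through each
autoencoder's own path, and per-modality cycle-consistency reconstruction
error through the opposite (fused) path.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .autograd import Tensor, concatenate
from .data import EXPRESSION, METHYLATION
from . import nn


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shape and loss-weight configuration of the network.

    ``latent_dim`` must factor exactly as ``n_tokens * d_model`` and
    ``d_model`` must be divisible by ``n_heads``.
    """

    rna_input_dim: int
    meth_input_dim: int
    ae_hidden_dim: int = 512
    n_tokens: int = 8
    d_model: int = 16
    n_encoder_layers: int = 3
    n_decoder_layers: int = 1
    n_heads: int = 4
    ffn_hidden_dim: int = 64
    fusion_dim: int = 0  # 0 -> defaults to latent_dim
    mlp_hidden_dims: Tuple[int, ...] = (64,)
    mask_rate: float = 0.1
    loss_weights: Tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)

    @property
    def latent_dim(self) -> int:
        return self.n_tokens * self.d_model

    def validate(self) -> None:
        for name in (
            "rna_input_dim", "meth_input_dim", "ae_hidden_dim", "n_tokens",
            "d_model", "n_encoder_layers", "n_decoder_layers", "n_heads",
            "ffn_hidden_dim",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_model % self.n_heads != 0:
            raise ValueError(f"d_model={self.d_model} not divisible by n_heads={self.n_heads}")
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even for sinusoidal positional encoding")
        if not 0.0 <= self.mask_rate < 1.0:
            raise ValueError(f"mask_rate={self.mask_rate} must lie in [0, 1)")
        if len(self.loss_weights) != 5:
            raise ValueError("loss_weights must have five entries")

    @property
    def effective_fusion_dim(self) -> int:
        return self.fusion_dim if self.fusion_dim > 0 else self.latent_dim


@dataclass
class LossBreakdown:
    classification: float
    reconstruction_rna: float
    reconstruction_meth: float
    cycle_rna: float
    cycle_meth: float
    total: float

    def terms(self) -> Dict[str, float]:
        return {
            "classification": self.classification,
            "reconstruction_rna": self.reconstruction_rna,
            "reconstruction_meth": self.reconstruction_meth,
            "cycle_rna": self.cycle_rna,
            "cycle_meth": self.cycle_meth,
            "total": self.total,
        }


def positional_encoding(n_tokens: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional-encoding grid.

    PE[pos, 2i] = sin(pos / 10000^(2i/d_model)),
    PE[pos, 2i+1] = cos(pos / 10000^(2i/d_model)).
    """
    if d_model % 2 != 0:
        raise ValueError("d_model must be even")
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.zeros((n_tokens, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def apply_feature_mask(
    x: np.ndarray, mask_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero each input feature independently with probability ``mask_rate``
    (denoising-style input masking, active during training only)."""
    if not 0.0 <= mask_rate < 1.0:
        raise ValueError(f"mask_rate={mask_rate} must lie in [0, 1)")
    if mask_rate == 0.0:
        return x
    keep = rng.random(x.shape) >= mask_rate
    return x * keep


class _AutoencoderPair(nn.Module):
    """Two-hidden-layer encoder/decoder for one modality."""

    def __init__(self, input_dim: int, hidden_dim: int, latent_dim: int, rng):
        super().__init__()
        self.enc1 = nn.Linear(input_dim, hidden_dim, rng)
        self.enc2 = nn.Linear(hidden_dim, latent_dim, rng)
        self.dec1 = nn.Linear(latent_dim, hidden_dim, rng)
        self.dec2 = nn.Linear(hidden_dim, input_dim, rng)

    def encode(self, x: Tensor) -> Tensor:
        # Z = ReLU(W2 ReLU(W1 x + b1) + b2)
        return self.enc2(self.enc1(x).relu()).relu()

    def decode(self, z: Tensor) -> Tensor:
        # X^ = Sigmoid(W4 ReLU(W3 z + b3) + b4)
        return self.dec2(self.dec1(z).relu()).sigmoid()


class AETransModel(nn.Module):
    """Full dual-channel network; see module docstring for the data flow."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        L, T, D = config.latent_dim, config.n_tokens, config.d_model

        self.rna_ae = _AutoencoderPair(config.rna_input_dim, config.ae_hidden_dim, L, rng)
        self.meth_ae = _AutoencoderPair(config.meth_input_dim, config.ae_hidden_dim, L, rng)
        self.rna_encoder = nn.Sequential(
            [nn.EncoderLayer(D, config.n_heads, config.ffn_hidden_dim, rng)
             for _ in range(config.n_encoder_layers)]
        )
        self.meth_encoder = nn.Sequential(
            [nn.EncoderLayer(D, config.n_heads, config.ffn_hidden_dim, rng)
             for _ in range(config.n_encoder_layers)]
        )
        F = config.effective_fusion_dim
        if F % T != 0:
            raise ValueError(f"fusion_dim={F} must be divisible by n_tokens={T}")
        self.fusion = nn.Linear(2 * L, F, rng)
        self.classifier = nn.MLP((F, *config.mlp_hidden_dims, 1), rng)
        self._fusion_token_dim = F // T
        self.rna_dec_in = nn.Linear(self._fusion_token_dim, D, rng)
        self.meth_dec_in = nn.Linear(self._fusion_token_dim, D, rng)
        self.rna_decoder = nn.Sequential(
            [nn.DecoderLayer(D, config.n_heads, config.ffn_hidden_dim, rng)
             for _ in range(config.n_decoder_layers)]
        )
        self.meth_decoder = nn.Sequential(
            [nn.DecoderLayer(D, config.n_heads, config.ffn_hidden_dim, rng)
             for _ in range(config.n_decoder_layers)]
        )
        self._pe = positional_encoding(T, D)
        self.mask_rng = np.random.default_rng(seed + 1)

    # -- spec operations ------------------------------------------------------
    def _ae(self, modality: str) -> _AutoencoderPair:
        if modality == EXPRESSION:
            return self.rna_ae
        if modality == METHYLATION:
            return self.meth_ae
        raise ValueError(f"unknown modality {modality!r}")

    def ae_encode(self, x: Union[np.ndarray, Tensor], modality: str) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        expected = (self.config.rna_input_dim if modality == EXPRESSION
                    else self.config.meth_input_dim)
        if x.shape[-1] != expected:
            raise ValueError(f"{modality} input dim {x.shape[-1]} != configured {expected}")
        return self._ae(modality).encode(x)

    def ae_decode(self, z: Union[np.ndarray, Tensor], modality: str) -> Tensor:
        z = z if isinstance(z, Tensor) else Tensor(z)
        if z.shape[-1] != self.config.latent_dim:
            raise ValueError(f"latent dim {z.shape[-1]} != configured {self.config.latent_dim}")
        return self._ae(modality).decode(z)

    def _tokens(self, z: Tensor) -> Tensor:
        """Reshape an AE latent batch into tokens and add positional encoding."""
        b = z.shape[0]
        tokens = z.reshape(b, self.config.n_tokens, self.config.d_model)
        return tokens + self._pe

    def transformer_encode(self, tokens: Tensor, modality: str) -> Tensor:
        stack = self.rna_encoder if modality == EXPRESSION else self.meth_encoder
        return stack(tokens)

    def fuse_and_classify(
        self, rna_tokens: Tensor, meth_tokens: Tensor
    ) -> Tuple[Tensor, Tensor]:
        """Concatenate flattened encoder outputs, fuse and score: returns
        (case probability, fused vector)."""
        b = rna_tokens.shape[0]
        flat = concatenate(
            [rna_tokens.reshape(b, -1), meth_tokens.reshape(b, -1)], axis=-1
        )
        fused = self.fusion(flat)
        logit = self.classifier(fused)
        prob = logit.sigmoid().reshape(b)
        return prob, fused

    def cross_reconstruct(self, fused: Tensor, target_modality: str) -> Tensor:
        """Decode the fused representation into the target modality's input
        space via that modality's Transformer decoder and AE decoder."""
        if target_modality not in (EXPRESSION, METHYLATION):
            raise ValueError(f"unknown modality {target_modality!r}")
        b = fused.shape[0]
        mem = fused.reshape(b, self.config.n_tokens, self._fusion_token_dim)
        proj = self.rna_dec_in if target_modality == EXPRESSION else self.meth_dec_in
        stack = self.rna_decoder if target_modality == EXPRESSION else self.meth_decoder
        mem_tokens = proj(mem)
        tokens = stack(mem_tokens + self._pe, mem_tokens)
        z = tokens.reshape(b, self.config.latent_dim)
        return self.ae_decode(z, target_modality)

    # -- full forward ----------------------------------------------------------
    def forward(
        self, x_rna: Union[np.ndarray, Tensor], x_meth: Union[np.ndarray, Tensor]
    ) -> Dict[str, Tensor]:
        """Full pair-level forward pass.

        Returns probabilities, the fused vector, own-path reconstructions and
        cross-path (cycle) reconstructions.
        """
        x_rna = x_rna if isinstance(x_rna, Tensor) else Tensor(x_rna)
        x_meth = x_meth if isinstance(x_meth, Tensor) else Tensor(x_meth)
        if self.training and self.config.mask_rate > 0:
            keep_rna = self.mask_rng.random(x_rna.shape) >= self.config.mask_rate
            keep_meth = self.mask_rng.random(x_meth.shape) >= self.config.mask_rate
            x_rna_in = x_rna * keep_rna.astype(np.float64)
            x_meth_in = x_meth * keep_meth.astype(np.float64)
        else:
            x_rna_in, x_meth_in = x_rna, x_meth

        z_rna = self.ae_encode(x_rna_in, EXPRESSION)
        z_meth = self.ae_encode(x_meth_in, METHYLATION)
        rna_tokens = self.transformer_encode(self._tokens(z_rna), EXPRESSION)
        meth_tokens = self.transformer_encode(self._tokens(z_meth), METHYLATION)
        prob, fused = self.fuse_and_classify(rna_tokens, meth_tokens)
        return {
            "probability": prob,
            "fused": fused,
            "recon_rna": self.ae_decode(z_rna, EXPRESSION),
            "recon_meth": self.ae_decode(z_meth, METHYLATION),
            "cycle_rna": self.cross_reconstruct(fused, EXPRESSION),
            "cycle_meth": self.cross_reconstruct(fused, METHYLATION),
        }

    def predict_proba(self, x_rna: np.ndarray, x_meth: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        out = self.forward(x_rna, x_meth)["probability"].data.copy()
        self.train(was_training)
        return out

    # -- loss -------------------------------------------------------------------
    def compute_loss(
        self,
        outputs: Dict[str, Tensor],
        labels: np.ndarray,
        x_rna: Union[np.ndarray, Tensor],
        x_meth: Union[np.ndarray, Tensor],
    ) -> Tuple[Tensor, LossBreakdown]:
        x_rna = x_rna if isinstance(x_rna, Tensor) else Tensor(x_rna)
        x_meth = x_meth if isinstance(x_meth, Tensor) else Tensor(x_meth)
        w_cls, w_rr, w_rm, w_cr, w_cm = self.config.loss_weights
        y = np.asarray(labels, dtype=np.float64)

        p = outputs["probability"]
        eps = 1e-7
        if p.data.min() < 0.0 or p.data.max() > 1.0:
            warnings.warn("predicted probability outside (0,1); clipping")
        p_safe = Tensor(np.clip(p.data, eps, 1 - eps), parents=(p,))

        def passthrough(g):
            p._accumulate(g)

        p_safe._backward = passthrough
        bce = -(Tensor(y) * p_safe.log() + Tensor(1.0 - y) * (1.0 - p_safe).log()).mean()

        def mse(a: Tensor, b: Tensor) -> Tensor:
            return ((a - b) ** 2).mean()

        rec_rna = mse(outputs["recon_rna"], x_rna)
        rec_meth = mse(outputs["recon_meth"], x_meth)
        cyc_rna = mse(outputs["cycle_rna"], x_rna)
        cyc_meth = mse(outputs["cycle_meth"], x_meth)
        total = (
            bce * w_cls + rec_rna * w_rr + rec_meth * w_rm
            + cyc_rna * w_cr + cyc_meth * w_cm
        )
        breakdown = LossBreakdown(
            classification=bce.item(),
            reconstruction_rna=rec_rna.item(),
            reconstruction_meth=rec_meth.item(),
            cycle_rna=cyc_rna.item(),
            cycle_meth=cyc_meth.item(),
            total=total.item(),
        )
        return total, breakdown

    # -- checkpointing -----------------------------------------------------------
    def save(self, path: Union[str, Path]) -> None:
        """Single-file archive: config JSON + named weight arrays."""
        arrays = {f"param:{k}": v for k, v in self.state_dict().items()}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "AETransModel":
        with np.load(path) as archive:
            cfg_raw = json.loads(bytes(archive["config_json"].tolist()).decode())
            cfg_raw["mlp_hidden_dims"] = tuple(cfg_raw["mlp_hidden_dims"])
            cfg_raw["loss_weights"] = tuple(cfg_raw["loss_weights"])
            config = ArchitectureConfig(**cfg_raw)
            model = cls(config, seed=0)
            state = {
                k[len("param:"):]: archive[k]
                for k in archive.files
                if k.startswith("param:")
            }
        model.load_state_dict(state)
        return model
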