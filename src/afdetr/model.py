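"""The detection network: CNN backbone, transformer encoder, dual-query decoder.

The model maps a normalized ECG segment of length ``L0`` to ``N`` parallel
predictions, each a class distribution over {NonAF, AF, NonObj} and a 1D
box.  The backbone downsamples the signal to ``L = L0 / stride`` feature
tokens of width ``D``; the encoder refines them with self-attention over
sinusoidal token-position encodings; the decoder carries ``N`` learned
content queries whose positional part is derived from a per-query anchor
box, refined layer by layer in sigmoid space.  Every decoder layer has its
own (unshared) classification and box-offset heads, supervised by per-layer
auxiliary losses; the final layer is the model's prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np

from . import nn
from .boxes import Box1D, inverse_sigmoid, merge_duplicates
from .nn import Tensor
from .records import NON_OBJ

__all__ = ["ModelConfig", "PredictionSet", "sinusoidal_pe", "AFDetr",
           "decode_predictions"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``T_enc``/``T_dec`` are the sinusoidal temperatures of the encoder
    token-position encoding and the decoder box encoding.  ``N`` must stay
    well above the maximum plausible beat count per segment.  The backbone
    channel plan starts at ``backbone_channels[0]`` for the stem and doubles
    through the residual blocks by default; ``backbone_pools`` gives the
    pooling stride after the stem and after each block (1 = no pooling), so
    the total stride is their product.
    """

    D: int = 128
    H: int = 8
    n_enc: int = 4
    n_dec: int = 4
    N: int = 100
    T_enc: float = 10000.0
    T_dec: float = 20.0
    init_box_width: float = 0.4 / 30.0
    backbone_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    backbone_pools: tuple[int, ...] = (3, 2, 2, 2, 2)
    ffn_dim: int | None = None
    num_classes: int = 3
    uniform_anchor_jitter: bool = False  # random-uniform initial centers
    #: multiplier applied to normalized coordinates before the decoder
    #: sinusoid.  With plain 2*pi every embedding frequency completes at
    #: most one cycle over the segment and the positional similarity kernel
    #: is almost flat; scaling by 2*pi*32 puts enough high-frequency content
    #: in the embedding to resolve individual feature tokens.
    pe_scale: float = 2.0 * np.pi * 32.0
    #: gain on the positional embeddings entering attention queries/keys;
    #: >1 makes the positional prior dominate the random content terms at
    #: initialization (fully learnable afterwards)
    pe_gain: float = 2.0

    def __post_init__(self):
        if self.D % 2 != 0:
            raise ValueError("feature width D must be even")
        if self.D % self.H != 0:
            raise ValueError("D must be divisible by the head count H")
        if min(self.n_enc, self.n_dec) < 1:
            raise ValueError("layer counts must be >= 1")
        if len(self.backbone_pools) != len(self.backbone_channels):
            raise ValueError("need one pooling factor per backbone stage")

    @property
    def total_stride(self) -> int:
        return int(np.prod(self.backbone_pools))

    @property
    def ffn_hidden(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.D


class PredictionSet(NamedTuple):
    """Per-decoder-layer class probabilities and boxes, plus the final view."""

    layer_probs: list[np.ndarray]   # each (N, 3)
    layer_boxes: list[np.ndarray]   # each (N, 2)

    @property
    def probs(self) -> np.ndarray:
        return self.layer_probs[-1]

    @property
    def boxes(self) -> np.ndarray:
        return self.layer_boxes[-1]


def sinusoidal_pe(x, T: float, D: int) -> np.ndarray:
    """Sinusoidal embedding of scalar position(s) ``x`` into ``D`` dimensions.

    Element ``2i`` is ``sin(x / T^(2i/D))`` and element ``2i+1`` is
    ``cos(x / T^(2i/D))``; consequently ``||PE(x)||^2 = D/2`` for every x.
    """
    if D % 2 != 0:
        raise ValueError("embedding dimension must be even")
    x = np.asarray(x, dtype=np.float64)
    i2 = np.arange(0, D, 2, dtype=np.float64)
    denom = T ** (i2 / D)
    args = x[..., None] / denom
    out = np.empty(x.shape + (D,), dtype=np.float64)
    out[..., 0::2] = np.sin(args)
    out[..., 1::2] = np.cos(args)
    return out


class ResBlock1d(nn.Module):
    """Two kernel-3 convolutions with batch norm; 1x1 projection on the skip
    path when the channel count changes."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = self.add("conv1", nn.Conv1d(c_in, c_out, 3, rng, padding=1))
        self.bn1 = self.add("bn1", nn.BatchNorm1d(c_out))
        self.conv2 = self.add("conv2", nn.Conv1d(c_out, c_out, 3, rng, padding=1))
        self.bn2 = self.add("bn2", nn.BatchNorm1d(c_out))
        if c_in != c_out:
            self.proj = self.add("proj", nn.Conv1d(c_in, c_out, 1, rng))
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class Backbone(nn.Module):
    """Stem convolution + four residual blocks + width-1 projection to D.

    Pooling follows the plan in the config (stride-3 pool after the stem,
    stride-2 pools after the blocks by default, total stride 48).  Inputs
    whose length is not divisible by the total stride are right-padded with
    zeros.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        ch = cfg.backbone_channels
        self.pools = cfg.backbone_pools
        self.stride = cfg.total_stride
        self.stem = self.add("stem", nn.Conv1d(1, ch[0], 3, rng, padding=1))
        self.stem_bn = self.add("stem_bn", nn.BatchNorm1d(ch[0]))
        self.blocks = []
        for i in range(1, len(ch)):
            blk = ResBlock1d(ch[i - 1], ch[i], rng)
            self.add(f"block{i}", blk)
            self.blocks.append(blk)
        self.proj = self.add("proj", nn.Conv1d(ch[-1], cfg.D, 1, rng))

    def __call__(self, x: Tensor) -> Tensor:
        """(B, L0) -> (B, L, D) with L = ceil(L0 / stride)."""
        B, L0 = x.shape
        pad = (-L0) % self.stride
        if pad:
            x = nn.cat([x, Tensor(np.zeros((B, pad)))], axis=1)
        h = x.reshape(B, 1, L0 + pad)
        h = self.stem_bn(self.stem(h)).relu()
        if self.pools[0] > 1:
            h = nn.maxpool1d(h, self.pools[0])
        for blk, pool in zip(self.blocks, self.pools[1:]):
            h = blk(h)
            if pool > 1:
                h = nn.maxpool1d(h, pool)
        h = self.proj(h)
        return h.transpose(0, 2, 1)  # (B, L, D)


class EncoderLayer(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = self.add("attn", nn.MultiHeadAttention(cfg.D, cfg.H, rng))
        self.norm1 = self.add("norm1", nn.LayerNorm(cfg.D))
        self.ffn = self.add("ffn", nn.FeedForward(cfg.D, cfg.ffn_hidden, rng))
        self.norm2 = self.add("norm2", nn.LayerNorm(cfg.D))

    def __call__(self, f: Tensor, pe: np.ndarray) -> Tensor:
        qk = f + pe
        s = self.attn(qk, qk, f)
        f = self.norm1(f + s)
        return self.norm2(f + self.ffn(f))


class DecoderLayer(nn.Module):
    """One decoder layer with its own (unshared) prediction heads."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.self_attn = self.add("self_attn",
                                  nn.MultiHeadAttention(cfg.D, cfg.H, rng, identity_qk=True))
        self.norm1 = self.add("norm1", nn.LayerNorm(cfg.D))
        self.cross_attn = self.add("cross_attn",
                                   nn.MultiHeadAttention(cfg.D, cfg.H, rng, identity_qk=True))
        self.norm2 = self.add("norm2", nn.LayerNorm(cfg.D))
        self.ffn = self.add("ffn", nn.FeedForward(cfg.D, cfg.ffn_hidden, rng))
        self.norm3 = self.add("norm3", nn.LayerNorm(cfg.D))
        # box head: 3 linear layers, zero-initialized output so that the
        # initial offsets vanish and boxes start at their anchors
        self.box_head = self.add("box_head", nn.MLP([cfg.D, cfg.D, cfg.D, 2], rng,
                                                    zero_init_last=True))
        self.cls_head = self.add("cls_head", nn.MLP([cfg.D, cfg.D, cfg.num_classes], rng))

    def __call__(self, C: Tensor, P: Tensor, memory: Tensor, mem_pe: np.ndarray,
                 attn_mask: np.ndarray | None) -> tuple[Tensor, Tensor, Tensor]:
        s = self.self_attn(C + P, C + P, C, mask=attn_mask)
        c1 = self.norm1(C + s)
        x = self.cross_attn(c1 + P, memory + mem_pe, memory)
        c2 = self.norm2(c1 + x)
        c3 = self.norm3(c2 + self.ffn(c2))
        offsets = self.box_head(c3)
        logits = self.cls_head(c3)
        return c3, offsets, logits


class AFDetr(nn.Module):
    """Full detection model (see module docstring)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = self.add("backbone", Backbone(cfg, rng))
        self.enc_layers = []
        for i in range(cfg.n_enc):
            lyr = EncoderLayer(cfg, rng)
            self.add(f"enc{i}", lyr)
            self.enc_layers.append(lyr)
        self.dec_layers = []
        for i in range(cfg.n_dec):
            lyr = DecoderLayer(cfg, rng)
            self.add(f"dec{i}", lyr)
            self.dec_layers.append(lyr)
        # shared across decoder layers: box -> positional query.  The MLP is
        # initialized as a near pass-through of the center embedding PE(x)
        # (shift-by-one trick around the ReLU), so positional queries and the
        # cross-attention keys start in the same sinusoidal space; training
        # is free to reshape it.
        self.pos_mlp = self.add("pos_mlp", nn.MLP([2 * cfg.D, cfg.D, cfg.D], rng))
        w1, b1 = self.pos_mlp.layers[0].w, self.pos_mlp.layers[0].b
        w2, b2 = self.pos_mlp.layers[1].w, self.pos_mlp.layers[1].b
        eye = np.eye(cfg.D, dtype=w1.data.dtype)
        shift = 1.0 + cfg.pe_gain  # keeps the ReLU in its linear region
        w1.data = np.concatenate([eye, 0.1 * w1.data[cfg.D:]], axis=0)
        b1.data = np.full(cfg.D, shift, dtype=b1.data.dtype)
        w2.data = eye.copy()
        b2.data = np.full(cfg.D, -shift, dtype=b2.data.dtype)
        self.content_embed = self.add("content_embed", nn.Embedding(cfg.N, cfg.D, rng))
        self.label_embed = self.add("label_embed", nn.Embedding(cfg.num_classes, cfg.D, rng))
        self._anchor_rng = np.random.default_rng(seed + 1)

    # -- pieces --------------------------------------------------------------

    def initial_boxes(self, batch: int) -> np.ndarray:
        """Anchors: evenly spaced centers ``(q + 0.5) / N`` at the fixed width."""
        N = self.cfg.N
        if self.cfg.uniform_anchor_jitter:
            centers = np.sort(self._anchor_rng.uniform(0, 1, size=N))
        else:
            centers = (np.arange(N) + 0.5) / N
        boxes = np.stack([centers, np.full(N, self.cfg.init_box_width)], axis=-1)
        return np.broadcast_to(boxes, (batch, N, 2)).copy()

    def positional_query(self, boxes: np.ndarray) -> Tensor:
        """Boxes (..., 2) -> positional queries (..., D).

        Center and width are each scaled by 2*pi (so [0, 1] spans one period
        of the slowest sinusoid), embedded with the decoder temperature,
        concatenated, and passed through the shared two-layer perceptron.
        """
        cfg = self.cfg
        pe_x = sinusoidal_pe(cfg.pe_scale * boxes[..., 0], cfg.T_dec, cfg.D)
        pe_w = sinusoidal_pe(cfg.pe_scale * boxes[..., 1], cfg.T_dec, cfg.D)
        return self.pos_mlp(Tensor(cfg.pe_gain * np.concatenate([pe_x, pe_w], axis=-1)))

    def encode(self, x: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Backbone + encoder.  Returns the memory and the cross-attention
        key encoding.

        Encoder self-attention uses the integer token index with the
        encoder temperature.  The cross-attention keys instead use the
        decoder's encoding function on the *normalized* token center
        position (scaled like the box centers), so that positional queries
        and keys share one embedding space.
        """
        feats = self.backbone(Tensor(np.asarray(x, dtype=np.float64)))
        L = feats.shape[1]
        enc_pe = sinusoidal_pe(np.arange(L, dtype=float), self.cfg.T_enc, self.cfg.D)
        for lyr in self.enc_layers:
            feats = lyr(feats, enc_pe)
        centers = (np.arange(L, dtype=float) + 0.5) / L
        cross_pe = self.cfg.pe_gain * sinusoidal_pe(
            self.cfg.pe_scale * centers, self.cfg.T_dec, self.cfg.D)
        return feats, cross_pe

    # -- forward -------------------------------------------------------------

    def forward(self, x: np.ndarray, dn_batch=None):
        """Run the network.

        Parameters
        ----------
        x : (B, L0) array of normalized segments.
        dn_batch : optional denoising-query batch built by
            :func:`afdetr.denoising.build_dn_inputs`; its queries are
            prepended to the ordinary ones and isolated by the attention
            mask.

        Returns
        -------
        list over decoder layers of ``(logits Tensor (B, nq, 3),
        boxes Tensor (B, nq, 2))`` where the first ``n_dn`` slots are the
        denoising queries (empty unless training with denoising).
        """
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        B = x.shape[0]
        memory, mem_pe = self.encode(x)

        boxes = self.initial_boxes(B)          # (B, N, 2) numpy
        C = self.content_embed(np.arange(self.cfg.N))      # (N, D)
        C = C.reshape(1, self.cfg.N, self.cfg.D)
        if B > 1:
            C = nn.cat([C] * B, axis=0)
        attn_mask = None
        if dn_batch is not None and dn_batch.n_dn > 0:
            dn_content = self.label_embed(dn_batch.labels)  # (B, n_dn, D)
            C = nn.cat([dn_content, C], axis=1)
            boxes = np.concatenate([dn_batch.boxes, boxes], axis=1)
            attn_mask = dn_batch.attn_mask  # (B, 1, nq, nq) additive

        outputs = []
        for lyr in self.dec_layers:
            P = self.positional_query(boxes)
            C, offsets, logits = lyr(C, P, memory, mem_pe, attn_mask)
            ref = inverse_sigmoid(boxes)       # detached previous boxes
            new_boxes = (offsets + ref).sigmoid()
            outputs.append((logits, new_boxes))
            boxes = new_boxes.data             # detach between layers
        return outputs

    def predict(self, x: np.ndarray) -> PredictionSet:
        """Inference-mode forward for one segment or a batch; no denoising."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                outputs = self.forward(x)
        finally:
            self.train(was_training)
        squeeze = np.asarray(x).ndim == 1
        layer_probs, layer_boxes = [], []
        for logits, boxes in outputs:
            p = np.exp(logits.data - logits.data.max(axis=-1, keepdims=True))
            p = p / p.sum(axis=-1, keepdims=True)
            if squeeze:
                layer_probs.append(p[0])
                layer_boxes.append(boxes.data[0])
            else:
                layer_probs.append(p)
                layer_boxes.append(boxes.data)
        return PredictionSet(layer_probs, layer_boxes)


def decode_predictions(pred: PredictionSet, conf_threshold: float = 0.0,
                       merge_iou: float = 0.8) -> list[tuple[int, float, Box1D]]:
    """Turn the final-layer prediction set into detections.

    Each query takes its argmax class; NonObj queries are dropped, the rest
    keep their max class probability as the score, and same-label near-
    duplicates (IoU > ``merge_iou``) are merged keeping the best score.
    """
    probs, boxes = pred.probs, pred.boxes
    labels = probs.argmax(axis=-1)
    keep = labels != NON_OBJ
    dets = [
        (int(lbl), float(probs[i, lbl]), Box1D(float(boxes[i, 0]), float(boxes[i, 1])))
        for i, lbl in enumerate(labels)
        if keep[i] and probs[i, lbl] >= conf_threshold
    ]
    return merge_duplicates(dets, merge_iou)
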