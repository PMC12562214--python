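"""Optimization: seeding, batching, learning-rate schedule, epoch loop.

The schedule anneals the base rate as
``eta = eta_base / (1 + 10 * t_cur / t_max)^2`` stepped once per epoch.
Adam drives the updates; all randomness (weight init, shuffling, denoising
noise) derives from the single seed in the config, so two runs with the
same seed produce identical loss curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .denoising import DnConfig, build_dn_inputs, dn_reconstruction_loss
from .matching import (
    LossWeights,
    MatchWeights,
    box_loss_t,
    classification_loss_t,
    cost_matrix,
    hungarian_match,
)
from .model import AFDetr, ModelConfig
from .nn import Adam, Tensor
from .records import EcgSegment, NON_OBJ

__all__ = ["TrainConfig", "lr_schedule", "fit", "matched_loss_t",
           "save_checkpoint", "load_checkpoint", "TrainingDiverged"]

CHECKPOINT_VERSION = 1


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the batch id."""


@dataclass
class TrainConfig:
    base_lr: float = 1e-4
    batch_size: int = 64
    t_max: int = 30
    seed: int = 0
    loss: LossWeights = field(default_factory=LossWeights)
    match: MatchWeights = field(default_factory=MatchWeights)
    dn: DnConfig = field(default_factory=DnConfig)
    aux_loss: bool = True     # per-layer auxiliary supervision

    def __post_init__(self):
        if self.t_max < 1 or self.batch_size < 1:
            raise ValueError("t_max and batch_size must be >= 1")


def lr_schedule(t_cur: int, cfg: TrainConfig) -> float:
    """Annealed learning rate at epoch ``t_cur`` (monotonically decreasing)."""
    if not (0 <= t_cur <= cfg.t_max):
        raise ValueError("epoch outside [0, t_max]")
    return cfg.base_lr / (1.0 + 10.0 * t_cur / cfg.t_max) ** 2


def matched_loss_t(layer_outputs, gt_sets, match_w: MatchWeights,
                   loss_w: LossWeights, n_dn: int = 0,
                   aux_loss: bool = True) -> tuple[Tensor, dict]:
    """Differentiable Hungarian-matched loss over decoder layers.

    ``layer_outputs`` come from :meth:`AFDetr.forward`; the first ``n_dn``
    query slots (denoising queries) are excluded.  When ``aux_loss`` is
    false only the final layer contributes.  Matching runs on detached
    predictions; gradients flow through the selected entries only.
    """
    total = Tensor(0.0)
    parts = {"cls": 0.0, "box": 0.0}
    layers = layer_outputs if aux_loss else layer_outputs[-1:]
    B = len(gt_sets)
    for logits, boxes in layers:
        N = logits.shape[1] - n_dn
        targets = np.full((B, N), NON_OBJ, dtype=np.intp)
        mb, mq, gi = [], [], []
        for b, (gtb, gtc) in enumerate(gt_sets):
            M = len(gtc)
            if M == 0:
                continue
            p = logits.data[b, n_dn:]
            p = np.exp(p - p.max(axis=-1, keepdims=True))
            p = p / p.sum(axis=-1, keepdims=True)
            cm = cost_matrix(gtc, gtb, p, boxes.data[b, n_dn:], match_w)
            if not np.all(np.isfinite(cm)):
                raise TrainingDiverged("non-finite matching costs (diverged weights)")
            match = hungarian_match(cm, lexicographic=False)
            targets[b, match.assignment] = gtc
            mb.extend([b] * M)
            mq.extend((match.assignment + n_dn).tolist())
            gi.append(gtb)
        ord_logits = logits[:, n_dn:]
        lcls = classification_loss_t(targets.reshape(-1),
                                     ord_logits.reshape(B * N, 3), loss_w)
        layer_loss = loss_w.lambda_cls * lcls
        parts["cls"] += lcls.item()
        if mb:
            pred_boxes = boxes[np.asarray(mb), np.asarray(mq)]
            lbox = box_loss_t(pred_boxes, np.concatenate(gi, axis=0), loss_w)
            layer_loss = layer_loss + lbox
            parts["box"] += lbox.item()
        total = total + layer_loss
    return total, parts


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for k in range(0, n, batch_size):
        yield order[k:k + batch_size]


def fit(train_segments: list[EcgSegment], val_segments: list[EcgSegment],
        model_cfg: ModelConfig, train_cfg: TrainConfig,
        model: AFDetr | None = None, verbose: bool = False):
    """Train a model; returns ``(model, history)``.

    The best checkpoint by validation matched loss is restored at the end.
    History records per-epoch learning rate and every loss component.
    """
    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = AFDetr(model_cfg, seed=int(rng.integers(0, 2 ** 31 - 1)))
    dn_rng = np.random.default_rng(train_cfg.seed + 7919)
    shuffle_rng = np.random.default_rng(train_cfg.seed + 104729)
    opt = Adam(model.parameters(), lr=train_cfg.base_lr)

    xs = np.stack([s.x for s in train_segments])
    gts = [s.gt_arrays() for s in train_segments]
    history: list[dict] = []
    best = (np.inf, None)
    for epoch in range(train_cfg.t_max):
        opt.lr = lr_schedule(epoch, train_cfg)
        model.train()
        ep = {"epoch": epoch, "lr": opt.lr, "loss": 0.0, "cls": 0.0, "box": 0.0}
        if train_cfg.dn.enabled:
            ep["dn"] = 0.0
        nb = 0
        for batch_id, idx in enumerate(_batches(len(xs), train_cfg.batch_size,
                                                shuffle_rng)):
            batch_gts = [gts[i] for i in idx]
            dn_batch = build_dn_inputs(batch_gts, train_cfg.dn, model_cfg.N, dn_rng)
            n_dn = dn_batch.n_dn if dn_batch is not None else 0
            outputs = model.forward(xs[idx], dn_batch=dn_batch)
            if not np.all(np.isfinite(outputs[-1][0].data)):
                raise TrainingDiverged(
                    f"non-finite predictions at epoch {epoch}, batch {batch_id}")
            loss, parts = matched_loss_t(outputs, batch_gts, train_cfg.match,
                                         train_cfg.loss, n_dn=n_dn,
                                         aux_loss=train_cfg.aux_loss)
            if dn_batch is not None:
                dn_loss = dn_reconstruction_loss(outputs, dn_batch, train_cfg.loss)
                loss = loss + dn_loss
                ep["dn"] += dn_loss.item()
            if not np.isfinite(loss.item()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {batch_id}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep["loss"] += loss.item()
            ep["cls"] += parts["cls"]
            ep["box"] += parts["box"]
            nb += 1
        for key in ("loss", "cls", "box", "dn"):
            if key in ep:
                ep[key] /= max(nb, 1)
        ep["val_loss"] = validation_loss(model, val_segments, train_cfg)
        history.append(ep)
        if verbose:
            print(f"epoch {epoch:3d} lr {ep['lr']:.2e} "
                  f"loss {ep['loss']:.4f} val {ep['val_loss']:.4f}")
        if ep["val_loss"] < best[0]:
            best = (ep["val_loss"], model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, history


def validation_loss(model: AFDetr, segments: list[EcgSegment],
                    train_cfg: TrainConfig, batch_size: int = 64) -> float:
    """Matched loss (no denoising) on held-out segments in eval mode."""
    if not segments:
        return float("nan")
    model.eval()
    total, n = 0.0, 0
    from .nn import no_grad
    for k in range(0, len(segments), batch_size):
        chunk = segments[k:k + batch_size]
        xs = np.stack([s.x for s in chunk])
        gt_sets = [s.gt_arrays() for s in chunk]
        with no_grad():
            outputs = model.forward(xs)
        loss, _ = matched_loss_t(outputs, gt_sets, train_cfg.match, train_cfg.loss)
        total += loss.item() * len(chunk)
        n += len(chunk)
    return total / n


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, model: AFDetr, extra: dict | None = None) -> None:
    """Single-archive checkpoint: named parameter arrays + serialized config.

    The file is a numpy ``.npz`` archive; the suffix is enforced so the
    path used for saving is the path that loads.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"version": CHECKPOINT_VERSION, "model_config": asdict(model.cfg)}
    if extra:
        meta["extra"] = extra
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> AFDetr:
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        mc = meta["model_config"]
        for key in ("backbone_channels", "backbone_pools"):
            mc[key] = tuple(mc[key])
        model = AFDetr(ModelConfig(**mc))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model.load_state_dict(state)
    model.eval()
    return model
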