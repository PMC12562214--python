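"""Named configuration profiles.

``default_*`` is the full-scale configuration (30 s segments, D=128,
4+4 transformer layers, N=100 queries).  ``reduced_*`` is the desk-scale
profile used by the package's own end-to-end checks: 10 s segments, a
narrower backbone with total stride 12, D=32 with 2+2 transformer layers
and N=40 queries, trained for 12 epochs on a few hundred synthetic
segments.  The reduced profile uses a larger base learning rate (1e-3)
because its training run is orders of magnitude shorter than a full-scale
run; the annealing schedule keeps its standard form.
"""

from __future__ import annotations

from .denoising import DnConfig
from .model import ModelConfig
from .train import TrainConfig

__all__ = ["default_model_config", "reduced_model_config",
           "reduced_train_config", "REDUCED_DURATION_S"]

REDUCED_DURATION_S = 10.0


def default_model_config(duration_s: float = 30.0) -> ModelConfig:
    """Full-scale architecture (box width 400 ms normalized by duration)."""
    return ModelConfig(init_box_width=0.4 / duration_s)


def reduced_model_config(duration_s: float = REDUCED_DURATION_S) -> ModelConfig:
    """Desk-scale architecture: D=32, 2+2 layers, N=40, total stride 12."""
    return ModelConfig(
        D=32, H=2, n_enc=2, n_dec=2, N=40,
        init_box_width=0.4 / duration_s,
        backbone_channels=(8, 16, 32, 32, 32),
        backbone_pools=(3, 2, 2, 1, 1),
    )


def reduced_train_config(seed: int, t_max: int = 12, batch_size: int = 16,
                         dn_enabled: bool = True, aux_loss: bool = True) -> TrainConfig:
    """Desk-scale optimization: 12 annealed epochs from base rate 1e-3."""
    return TrainConfig(
        base_lr=1e-3, batch_size=batch_size, t_max=t_max, seed=seed,
        dn=DnConfig(n_groups=3, enabled=dn_enabled), aux_loss=aux_loss,
    )
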