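"""The double-loss system: BCE, soft Dice, their convex combination, and the
global/local split.

``Dice(p, q)`` denotes the *soft* Dice coefficient
``(2·Σ p q + ε) / (Σ p² + Σ q² + ε)`` — no thresholding of ``p`` — and every
occurrence of Dice inside a loss means ``1 − coefficient``, the only reading
under which minimization trains the network.  The global objective is
``BCE_Dice(p, q) + DiceLoss(p, q)``, which for α = 0.5 weights BCE by 0.5
and the Dice loss by 1.5; the local objective is the Dice loss of the
deep-supervision mask (bilinearly upsampled to label resolution) against the
full-resolution ground truth.

All functions accept either numpy arrays or autodiff tensors and return a
scalar tensor, so the same code path serves evaluation and training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grad import engine
from .grad.engine import Tensor, as_tensor


@dataclasses.dataclass(frozen=True)
class LossConfig:
    """Mixing weights and numerical guards of the objective.

    alpha: BCE weight inside the BCE-Dice combination (1−alpha on Dice).
    lambda_local: weight of the local (deep-supervision) loss in the total.
    epsilon: Dice smoothing constant guarding empty-mask batches.
    clip: probability clamp bound applied before the BCE logarithms.
    """

    alpha: float = 0.5
    lambda_local: float = 1.0
    epsilon: float = 1e-6
    clip: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.clip < 0.5:
            raise ValueError(f"clip must be in (0, 0.5), got {self.clip}")


_DEFAULT = LossConfig()


def _check_shapes(p, q):
    if p.shape != q.shape:
        raise ValueError(f"prediction/label shape mismatch: {p.shape} vs {q.shape}")


def bce_loss(p, q, clip: float = _DEFAULT.clip) -> Tensor:
    """Mean binary cross-entropy over all pixels, with p clamped to [clip, 1−clip]."""
    p, q = as_tensor(p), as_tensor(q)
    _check_shapes(p, q)
    pc = engine.clip(p, clip, 1.0 - clip)
    q_arr = q.data.astype(pc.dtype)
    term = engine.mul(q_arr, engine.log(pc)) + engine.mul(1.0 - q_arr, engine.log(1.0 - pc))
    return -engine.tmean(term)


def dice_coefficient(p, q, epsilon: float = _DEFAULT.epsilon) -> Tensor:
    """Soft Dice coefficient (2Σpq + ε) / (Σp² + Σq² + ε)."""
    p, q = as_tensor(p), as_tensor(q)
    _check_shapes(p, q)
    q = as_tensor(q.data.astype(p.dtype))
    inter = engine.tsum(engine.mul(p, q))
    denom = engine.tsum(engine.mul(p, p)) + engine.tsum(engine.mul(q, q))
    return (2.0 * inter + epsilon) / (denom + epsilon)


def dice_loss(p, q, epsilon: float = _DEFAULT.epsilon) -> Tensor:
    """1 − soft Dice coefficient."""
    return 1.0 - dice_coefficient(p, q, epsilon=epsilon)


def bce_dice(p, q, alpha: float = _DEFAULT.alpha, cfg: LossConfig = _DEFAULT) -> Tensor:
    """alpha·BCE + (1−alpha)·DiceLoss."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    return alpha * bce_loss(p, q, clip=cfg.clip) + \
        (1.0 - alpha) * dice_loss(p, q, epsilon=cfg.epsilon)


def global_loss(p, q, cfg: LossConfig = _DEFAULT) -> Tensor:
    """BCE_Dice(p, q) + DiceLoss(p, q) — the full-resolution objective."""
    return bce_dice(p, q, alpha=cfg.alpha, cfg=cfg) + dice_loss(p, q, epsilon=cfg.epsilon)


def local_loss(aux, q, cfg: LossConfig = _DEFAULT) -> Tensor:
    """Dice loss of the deep-supervision mask against the full-resolution label.

    ``aux`` is an :class:`~polypseg.attention.SSIAMask` (or a probability
    tensor); its probability is bilinearly upsampled to the label's spatial
    size before the comparison.
    """
    if aux is None:
        raise ValueError("local_loss called without an auxiliary mask "
                         "(deep supervision disabled); the trainer must skip it")
    prob = getattr(aux, "probability", aux)
    prob = as_tensor(prob)
    q = as_tensor(q)
    q_nchw = q.data
    if q_nchw.ndim == 3:  # (B, H, W) -> (B, 1, H, W)
        q_nchw = q_nchw[:, None]
    up = engine.interpolate_bilinear(prob, q_nchw.shape[2:])
    return dice_loss(up, as_tensor(q_nchw), epsilon=cfg.epsilon)


def total_loss(out, q, cfg: LossConfig = _DEFAULT):
    """Global plus weighted local loss.

    ``out`` is a :class:`~polypseg.network.NetworkOutput`; when its auxiliary
    mask is absent (or ``lambda_local`` is 0) only the global term remains.
    Returns ``(scalar tensor, component dict)`` with float entries
    ``global``, ``local`` and ``total`` for logging.
    """
    q_arr = as_tensor(q).data
    if q_arr.ndim == 3:
        q_arr = q_arr[:, None]
    g = global_loss(out.prediction, as_tensor(q_arr), cfg=cfg)
    if out.aux_mask is not None and cfg.lambda_local != 0.0:
        loc = local_loss(out.aux_mask, as_tensor(q_arr), cfg=cfg)
        total = g + cfg.lambda_local * loc
        local_val = float(loc.item())
    else:
        total = g
        local_val = 0.0
    components = {"global": float(g.item()), "local": local_val,
                  "total": float(total.item())}
    return total, components
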