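"""Training objectives: BCE, multilabel hinge, and their alpha-weighted mix.

The hybrid loss L = alpha * L_bce + (1 - alpha) * L_hinge (default alpha =
0.95) balances per-label probability calibration (BCE) against pairwise
label ranking (hinge).  The hinge term sums max(0, 1 - (s_i - s_j)) over all
(positive i, negative j) label pairs of each patient and divides by the
number of patients; it is evaluated on pre-sigmoid logits by default, since
on the probability scale the unit margin is unattainable (differences of
sigmoids are < 1) and the loss could never reach zero.  A probability-scale
mode is retained for literal fidelity.

Every function accepts plain numpy arrays (returning a float) or autodiff
tensors (returning a scalar tensor for backprop); both routes share one code
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

PROB_CLAMP = 1e-7


@dataclass
class LossConfig:
    alpha: float = 0.95
    hinge_on: str = "logits"            # "logits" | "probabilities"
    reduction: str = "mean-per-patient"  # "mean-per-patient" | "paper-sum"

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.hinge_on not in ("logits", "probabilities"):
            raise ValueError(f"unknown hinge_on {self.hinge_on!r}")
        if self.reduction not in ("mean-per-patient", "paper-sum"):
            raise ValueError(f"unknown reduction {self.reduction!r}")


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _unwrap(t: Tensor, was_tensor: bool):
    return t if was_tensor else float(t.data)


def bce_loss(targets, probabilities, reduction: str = "mean-per-patient"):
    """Binary cross-entropy summed over labels per patient.

    ``paper-sum`` leaves the plain sum over patients; the default divides by
    the number of patients so the value is batch-size independent.
    Probabilities are clamped away from {0, 1} for log stability.
    """
    o, _ = _wrap(targets)
    p, is_t = _wrap(probabilities)
    if o.shape != p.shape:
        raise ValueError(f"shape mismatch: targets {o.shape} vs probabilities {p.shape}")
    n_patients = o.shape[0] if o.ndim > 1 else 1
    p = p.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    ll = o * p.log() + (1.0 - o) * (1.0 - p).log()
    total = -ll.sum()
    if reduction == "mean-per-patient":
        total = total * (1.0 / n_patients)
    return _unwrap(total, is_t)


def multilabel_hinge_loss(targets, scores):
    """Pairwise ranking hinge over (positive, negative) label pairs.

    For each patient, every pair (i, j) with o_i = 1, o_j = 0 contributes
    max(0, 1 - (s_i - s_j)); the total is divided by the number of patients
    (not the pair count, so patients with many labels weigh more).  Patients
    with no positive or no negative labels contribute 0.
    """
    o, _ = _wrap(targets)
    s, is_t = _wrap(scores)
    if o.shape != s.shape:
        raise ValueError(f"shape mismatch: targets {o.shape} vs scores {s.shape}")
    squeeze = o.ndim == 1
    o_data = np.atleast_2d(o.data)
    if squeeze:
        s = s.reshape(1, -1)
    B, d = o_data.shape
    pair_mask = o_data[:, :, None] * (1.0 - o_data)[:, None, :]  # (B, d_pos, d_neg)
    diff = s.reshape(B, d, 1) - s.reshape(B, 1, d)
    margins = (1.0 - diff).relu()
    total = (margins * pair_mask).sum() * (1.0 / B)
    return _unwrap(total, is_t)


def combined_loss(targets, probabilities, logits, config: LossConfig | None = None):
    """alpha * L_bce + (1 - alpha) * L_hinge."""
    config = config or LossConfig()
    bce = bce_loss(targets, probabilities, reduction=config.reduction)
    hinge_scores = logits if config.hinge_on == "logits" else probabilities
    hinge = multilabel_hinge_loss(targets, hinge_scores)
    return config.alpha * bce + (1.0 - config.alpha) * hinge
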