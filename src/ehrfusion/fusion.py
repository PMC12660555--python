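"""Fusion of semantic and temporal embeddings into the patient representation.

The semantic disease logits z_a (length d_a) and the temporal embedding z_b
(length d_b) are concatenated, z_in = [z_a || z_b], and passed through an
MLP — h = ReLU(W_1 z_in + b_1), z = W_out h + b_out — whose output z holds
one logit per target label.  Probabilities are the elementwise sigmoid of z
and decisions dichotomize at a threshold (default 0.5, boundary assigned to
the positive class, so an untrained zero-logit model predicts positive).

Either modality may be absent (d_a = 0 or d_b = 0), which realizes the
single-modality ablations with the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

TASKS = ("multilabel-10", "heart-failure")
DEFAULT_HF_CODE = "CHF"


@dataclass
class PredictionOutput:
    probabilities: np.ndarray
    decisions: np.ndarray
    threshold: float


def fuse(z_a: np.ndarray | None, z_b: np.ndarray | None) -> np.ndarray:
    """Exact concatenation along the feature axis, z_a first."""
    parts = [np.asarray(p, dtype=np.float64) for p in (z_a, z_b) if p is not None and np.size(p)]
    if not parts:
        raise ValueError("at least one modality must be present")
    return np.concatenate(parts, axis=-1)


class FusionMLP(nn.Module):
    """One ReLU hidden layer plus affine output; extra depth is config-gated."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        d_hidden: int,
        rng: np.random.Generator,
        n_hidden_layers: int = 1,
    ):
        if n_hidden_layers < 1:
            raise ValueError("n_hidden_layers must be >= 1")
        dims = [d_in] + [d_hidden] * n_hidden_layers
        self.hidden = [nn.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.out = nn.Linear(d_hidden, d_out, rng)

    def __call__(self, z_in: nn.Tensor) -> nn.Tensor:
        x = nn.Tensor.as_tensor(z_in)
        for lin in self.hidden:
            x = lin(x).relu()
        return self.out(x)


def mlp_forward(
    z_in: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w_out: np.ndarray,
    b_out: np.ndarray,
) -> np.ndarray:
    """Array-level reference forward pass: z = W_out ReLU(W_1 z_in + b_1) + b_out.

    ``w1`` is (d_hidden, d_in) and ``w_out`` is (d_out, d_hidden), matching
    the column-vector convention of the model equations.
    """
    z_in = np.asarray(z_in, dtype=np.float64)
    h = np.maximum(z_in @ np.asarray(w1).T + b1, 0.0)
    return h @ np.asarray(w_out).T + b_out


def predict(z: np.ndarray, threshold: float = 0.5) -> PredictionOutput:
    """Sigmoid probabilities and thresholded decisions (boundary -> positive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    z = np.asarray(z, dtype=np.float64)
    probabilities = 1.0 / (1.0 + np.exp(-z))
    decisions = (probabilities >= threshold).astype(np.float64)
    return PredictionOutput(probabilities=probabilities, decisions=decisions, threshold=threshold)


def make_task_head(task: str, labels, hf_code: str = DEFAULT_HF_CODE) -> dict:
    """Resolve the output head for a task.

    ``multilabel-10`` predicts the full label space (d_out = d);
    ``heart-failure`` is the binary variant (d_out = 1) whose target is the
    heart-failure component of the next visit's label vector.
    """
    if task == "multilabel-10":
        return {"d_out": labels.d, "target_indices": list(range(labels.d))}
    if task == "heart-failure":
        if hf_code not in labels.codes:
            raise ValueError(f"heart-failure code {hf_code!r} not in label space {labels.codes}")
        return {"d_out": 1, "target_indices": [labels.index(hf_code)]}
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
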