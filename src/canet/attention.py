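"""Slice-wise attention pooling.

The mechanism that lets a 2-D backbone summarise a 3-D volume: each
axial slice's feature vector f_i is scored by a single shared affine map
with tanh activation,

    scores_i = tanh(w . f_i + b),

the scores are softmax-normalised into attention weights alpha, and the
volume descriptor is the weighted sum d = F alpha.  The output length
equals the feature dimension D regardless of the number of slices N,
and the whole mechanism has exactly D + 1 trainable scalars.

``F`` is oriented D x N with slices as columns, so ``d = F @ alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SliceFeatureMatrix",
    "AttentionParams",
    "AttentionOutput",
    "importance_scores",
    "attention_weights",
    "attend",
    "apply_attention",
    "visualize_attention",
]


@dataclass
class SliceFeatureMatrix:
    """Per-slice backbone features, one column per slice (D x N)."""

    F: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=np.float64)
        if self.F.ndim != 2:
            raise ValueError(f"F must be 2-D (features x slices), got shape {self.F.shape}")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F contains non-finite entries")

    @property
    def n_slices(self) -> int:
        return self.F.shape[1]

    @property
    def feature_dim(self) -> int:
        return self.F.shape[0]


@dataclass
class AttentionParams:
    """Shared scorer weights: vector w (length D) and scalar bias b."""

    w: np.ndarray
    b: float = 0.0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        self.b = float(self.b)
        if not (np.all(np.isfinite(self.w)) and np.isfinite(self.b)):
            raise ValueError("attention parameters must be finite")

    @property
    def n_params(self) -> int:
        return self.w.size + 1


@dataclass
class AttentionOutput:
    scores: np.ndarray  # per-slice importance in (-1, 1), length N
    alpha: np.ndarray   # softmax weights, length N, sums to 1
    attended: np.ndarray  # pooled feature d = F alpha, length D


def _as_matrix(F: SliceFeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(F, SliceFeatureMatrix):
        return F.F
    return np.asarray(F, dtype=np.float64)


def importance_scores(
    F: SliceFeatureMatrix | np.ndarray, params: AttentionParams
) -> np.ndarray:
    """tanh(w . f_i + b) for every slice i; values strictly in (-1, 1)."""
    Fm = _as_matrix(F)
    if params.w.size != Fm.shape[0]:
        raise ValueError(
            f"weight length {params.w.size} does not match feature dimension {Fm.shape[0]}"
        )
    return np.tanh(params.w @ Fm + params.b)


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Stable softmax of the importance scores; positive, sums to 1."""
    s = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    e = np.exp(s - s.max())
    return e / e.sum()


def attend(F: SliceFeatureMatrix | np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Weighted sum of slice features, d = F @ alpha (length D)."""
    Fm = _as_matrix(F)
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.shape != (Fm.shape[1],):
        raise ValueError(
            f"alpha length {alpha.shape} does not match slice count {Fm.shape[1]}"
        )
    return Fm @ alpha


def apply_attention(
    F: SliceFeatureMatrix | np.ndarray, params: AttentionParams
) -> AttentionOutput:
    """Score, normalise, pool; output dimension is independent of N."""
    scores = importance_scores(F, params)
    alpha = attention_weights(scores)
    return AttentionOutput(scores=scores, alpha=alpha, attended=attend(F, alpha))


def visualize_attention(voxels: np.ndarray, alpha: np.ndarray, out_path: Path) -> Path:
    """Write a PNG montage: original slices, alpha-weighted slices, and the
    alpha-vs-slice-index profile.  Slices with larger alpha render brighter.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    voxels = np.asarray(voxels, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    n = voxels.shape[0]
    if alpha.shape != (n,):
        raise ValueError(f"alpha length {alpha.shape} != slice count {n}")
    vmax = float(voxels.max()) or 1.0
    fig, axes = plt.subplots(3, n, figsize=(1.2 * n, 4.2))
    if n == 1:
        axes = axes[:, None]
    for i in range(n):
        axes[0, i].imshow(voxels[i], cmap="gray", vmin=0, vmax=vmax)
        axes[1, i].imshow(alpha[i] * voxels[i], cmap="gray", vmin=0, vmax=vmax)
        for r in (0, 1):
            axes[r, i].set_xticks([])
            axes[r, i].set_yticks([])
        axes[2, i].axis("off")
    axes[0, 0].set_ylabel("slices", fontsize=8)
    axes[1, 0].set_ylabel("weighted", fontsize=8)
    gs = axes[2, 0].get_gridspec()
    ax = fig.add_subplot(gs[2, :])
    ax.plot(np.arange(n), alpha, marker="o")
    ax.set_xlabel("slice index")
    ax.set_ylabel("attention weight")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    try:
        fig.savefig(out_path, dpi=100)
    except OSError as exc:
        raise OSError(f"could not write attention montage to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    return out_path
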