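"""Augmentation, patient-grouped cross-validation, optimisation, metrics.

The protocol: patients are assigned to k stratified folds (grouping by
patient so no subject contributes to both train and test); in each CV
round three folds train, one validates (early stopping on validation
loss) and one tests.  Single-time-point models treat every available
interval's volume of a training nodule as an independent sample but are
evaluated per screening interval; multi-branch models consume
consecutive interval pairs / the triplet.  Longitudinal tuples are
augmented in unison -- one sampled geometric transform applied
identically to every member -- so the pair stays roughly aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

from .models import Model
from .volumes import LongitudinalSeries

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "FoldPlan",
    "EvalReport",
    "augment",
    "make_folds",
    "build_samples",
    "train",
    "evaluate",
    "roc_auc",
    "average_precision",
    "nll",
]

_LABEL_INDEX = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes of the random training-time transforms.

    Geometric components (flips, in-plane shift as a fraction of the
    extent, in-plane rotation in degrees) are sampled once per
    longitudinal tuple; Gaussian intensity noise (normalised units) is
    drawn independently per volume.  All-zero magnitudes give the exact
    identity.
    """

    flip_prob: float = 0.5
    max_shift_frac: float = 0.1
    max_rotate_deg: float = 15.0
    noise_sigma: float = 0.01


@dataclass
class TrainConfig:
    """Optimisation protocol (defaults follow the CAN/CRN recipe)."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class FoldPlan:
    """k disjoint patient sets covering the cohort; per round, fold i is
    the test set, fold (i+1) mod k validates, the rest train."""

    folds: list[list[str]]

    @property
    def k(self) -> int:
        return len(self.folds)

    def roles(self, round_index: int) -> tuple[set[str], set[str], set[str]]:
        k = self.k
        i = round_index % k
        test = set(self.folds[i])
        val = set(self.folds[(i + 1) % k])
        train_ids = set().union(*(self.folds[j] for j in range(k)
                                  if j not in (i, (i + 1) % k)))
        return train_ids, val, test


@dataclass
class EvalReport:
    """Metrics over one evaluated sample set; AUC/AP are NaN (with a
    diagnostic note) when the set is single-class."""

    auc: float
    ap: float
    nll: float
    n_samples: int
    n_positive: int
    interval: str
    fold_index: int | None = None
    predictions: pd.DataFrame | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ap": self.ap,
            "nll": self.nll,
            "n_samples": self.n_samples,
            "n_positive": self.n_positive,
            "interval": self.interval,
            "fold_index": self.fold_index,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels) -> float:
    """Concordance probability (Mann-Whitney), ties credited 1/2.

    NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def average_precision(scores, labels) -> float:
    """Step-wise AP = sum_n (R_n - R_{n-1}) P_n over descending unique
    score thresholds (no interpolation).  NaN without positives."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], (labels[order] == 1).astype(np.float64)
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # last index of each tied-score block = one threshold
    last = np.nonzero(np.diff(s, append=-np.inf))[0]
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / n_pos
    return float(np.sum(np.diff(recall, prepend=0.0) * precision))


def nll(prob_true, eps: float = 1e-12) -> float:
    """Mean negative log-probability assigned to the true class."""
    p = np.clip(np.asarray(prob_true, dtype=np.float64), eps, 1.0)
    return float(-np.log(p).mean())


# ---------------------------------------------------------------------------
# folds


def make_folds(series_list: list[LongitudinalSeries], k: int = 5, seed: int = 0) -> FoldPlan:
    """Greedy stratified patient assignment: per class, shuffled patients
    go round-robin to the currently smallest fold.  Deterministic under
    ``seed``; rejects fewer patients than folds."""
    if len(series_list) < k:
        raise ValueError(f"need at least k={k} patients, got {len(series_list)}")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    per_class_counts = np.zeros((k, 2), dtype=int)
    for label in ("malignant", "benign"):
        pids = sorted(s.patient_id for s in series_list if s.label == label)
        rng.shuffle(pids)
        c = _LABEL_INDEX[label]
        for pid in pids:
            j = int(np.lexsort((np.arange(k), per_class_counts.sum(axis=1),
                                per_class_counts[:, c]))[0])
            folds[j].append(pid)
            per_class_counts[j, c] += 1
    return FoldPlan(folds=[sorted(f) for f in folds])


# ---------------------------------------------------------------------------
# augmentation


def augment(
    volumes: tuple[np.ndarray, ...] | list[np.ndarray],
    rng: np.random.Generator,
    config: AugmentConfig = AugmentConfig(),
) -> list[np.ndarray]:
    """Augment a longitudinal tuple of (N, H, W) grids in unison.

    One flip/shift/rotation draw is applied identically to every volume
    of the tuple; Gaussian noise is then added independently per volume.
    """
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"volumes in a tuple must share a shape, got {shapes}")
    flip_y = config.flip_prob > 0 and rng.random() < config.flip_prob
    flip_x = config.flip_prob > 0 and rng.random() < config.flip_prob
    shape = volumes[0].shape
    shift = (
        rng.uniform(-config.max_shift_frac, config.max_shift_frac, size=2)
        * np.array(shape[1:])
        if config.max_shift_frac > 0
        else np.zeros(2)
    )
    angle = (
        rng.uniform(-config.max_rotate_deg, config.max_rotate_deg)
        if config.max_rotate_deg > 0
        else 0.0
    )
    out = []
    for v in volumes:
        v = np.asarray(v, dtype=np.float64)
        if flip_y:
            v = v[:, ::-1, :]
        if flip_x:
            v = v[:, :, ::-1]
        if angle != 0.0:
            v = ndimage.rotate(v, angle, axes=(1, 2), reshape=False, order=1,
                               mode="nearest")
        if np.any(shift != 0):
            v = ndimage.shift(v, (0.0, shift[0], shift[1]), order=1, mode="nearest")
        if config.noise_sigma > 0:
            v = v + rng.normal(0.0, config.noise_sigma, size=v.shape)
        out.append(np.ascontiguousarray(v))
    return out


# ---------------------------------------------------------------------------
# sample assembly


def _series_tuples(series: LongitudinalSeries, m: int) -> list[tuple]:
    """Index tuples of consecutive intervals of length m within a series."""
    ivals = series.intervals
    out = []
    for i in range(len(ivals) - m + 1):
        window = ivals[i : i + m]
        if window == list(range(window[0], window[0] + m)):
            out.append(tuple(range(i, i + m)))
    return out


def build_samples(
    series_list: list[LongitudinalSeries], m_branches: int
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Assemble model-ready samples from preprocessed series.

    For one branch every volume is an independent sample; for m >= 2
    only consecutive-interval pairs / the triplet are used.  Returns
    ``X`` of shape (n, m, N, H, W), integer labels, and a bookkeeping
    frame (patient_id, intervals, label).
    """
    xs, ys, rows = [], [], []
    for series in series_list:
        for idx in _series_tuples(series, m_branches):
            vols = [series.volumes[i] for i in idx]
            xs.append(np.stack([v.voxels for v in vols]))
            ys.append(_LABEL_INDEX[series.label])
            rows.append(
                {
                    "patient_id": series.patient_id,
                    "intervals": ",".join(str(v.interval) for v in vols),
                    "label": series.label,
                }
            )
    if not xs:
        raise ValueError("no eligible samples (check interval structure vs branches)")
    return np.stack(xs), np.asarray(ys), pd.DataFrame(rows)


def _to_batch(x: np.ndarray) -> np.ndarray:
    """(n, m, N, H, W) -> (n, m, N, 3, H, W) channel replication."""
    return np.repeat(x[:, :, :, None, :, :], 3, axis=3)


# ---------------------------------------------------------------------------
# training loop


def train(
    model: Model,
    series_list: list[LongitudinalSeries],
    plan: FoldPlan,
    round_index: int,
    config: TrainConfig,
) -> pd.DataFrame:
    """Minimise cross-entropy with Adam; early-stop on validation loss.

    Returns the per-epoch history; the model is left at the weights of
    the best validation epoch.
    """
    from . import nn

    train_ids, val_ids, _ = plan.roles(round_index)
    m = model.config.M_branches
    tr = [s for s in series_list if s.patient_id in train_ids]
    va = [s for s in series_list if s.patient_id in val_ids]
    if not tr or not va:
        raise ValueError("empty train or validation split")
    Xtr, ytr, _ = build_samples(tr, m)
    Xva, yva, _ = build_samples(va, m)
    Xva_b = _to_batch(Xva)

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    best_loss, best_params, best_epoch = math.inf, None, -1
    history = []
    n = len(Xtr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Xtr[idx]
            if config.augment is not None:
                xb = np.stack(
                    [np.stack(augment(tuple(sample), rng, config.augment))
                     for sample in xb]
                )
            loss, grads = model.loss_and_grads(_to_batch(xb), ytr[idx])
            opt.step(grads)
            epoch_loss += loss
            n_batches += 1
        probs = model.predict_proba(Xva_b)
        val_loss = nll(probs[np.arange(len(yva)), yva])
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
             "val_loss": val_loss}
        )
        if val_loss < best_loss - 1e-6:
            best_loss, best_epoch = val_loss, epoch
            best_params = {k: v.copy() for k, v in model.parameters().items()}
        elif epoch - best_epoch >= config.patience:
            break
    if best_params is not None:
        for k, v in model.parameters().items():
            v[...] = best_params[k]
    return pd.DataFrame(history)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    model: Model,
    series_list: list[LongitudinalSeries],
    interval_filter: int | str = "all",
    fold_index: int | None = None,
    batch_size: int = 32,
) -> EvalReport:
    """Score every eligible sample and compute ROC-AUC, AP and NLL.

    For single-branch models ``interval_filter`` restricts to one
    screening interval (or pools all); multi-branch models always use
    the consecutive tuples and ignore the filter.
    """
    m = model.config.M_branches
    if m == 1 and interval_filter != "all":
        series_list = [
            LongitudinalSeries(
                volumes=[v for v in s.volumes if v.interval == int(interval_filter)],
                patient_id=s.patient_id,
                label=s.label,
            )
            for s in series_list
            if any(v.interval == int(interval_filter) for v in s.volumes)
        ]
    X, y, table = build_samples(series_list, m)
    scores = np.empty(len(y))
    for start in range(0, len(y), batch_size):
        xb = _to_batch(X[start : start + batch_size])
        scores[start : start + batch_size] = model.predict_proba(xb)[:, 1]
    table = table.assign(score=scores)
    p_true = np.where(y == 1, scores, 1.0 - scores)
    note = ""
    if len(np.unique(y)) < 2:
        note = "single-class evaluation set: AUC and AP undefined"
    return EvalReport(
        auc=roc_auc(scores, y),
        ap=average_precision(scores, y),
        nll=nll(p_true),
        n_samples=int(len(y)),
        n_positive=int((y == 1).sum()),
        interval=str(interval_filter),
        fold_index=fold_index,
        predictions=table,
        note=note,
    )


def save_report(report: EvalReport, path: Path) -> None:
    """JSON metrics + CSV prediction table alongside."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.to_dict(), indent=2))
    if report.predictions is not None:
        report.predictions.to_csv(path.with_suffix(".predictions.csv"), index=False)
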