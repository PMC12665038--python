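"""Training loops, evaluation metrics, and the paired DeLong AUC test.

Training minimizes binary cross-entropy with Adam (defaults: learning rate
1e-5, 50 epochs, batch size 100) and keeps the checkpoint with the best
validation AUC. Selective fine-tuning (transfer learning) re-trains the
input/convolutional/output parameter groups at learning rate 1e-4 for up to
30 epochs with early-stopping patience 5 while every Transformer-encoder
parameter stays bitwise frozen.

Metric formulas: ACC=(TP+TN)/(TP+TN+FP+FN), Precision=TP/(TP+FP),
Recall=TP/(TP+FN), F1=2PR/(P+R), FPR=FP/(FP+TN), TPR=Recall; AUC is the
normalized Mann-Whitney statistic (ties credit 1/2, matching the DeLong
kernel), AUPR the step-wise integral of precision over recall.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._autodiff import Adam, Tensor
from .genomio import Genome, GenomicRegion, region_to_tensor
from .model import EtnetModel
from .pairset import frame_to_pairs

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    ACC: float
    Precision: float
    Recall: float
    F1: float
    AUC: float
    AUPR: float
    roc_points: np.ndarray = field(repr=False)  # (k, 2) of (FPR, TPR)
    pr_points: np.ndarray = field(repr=False)   # (k, 2) of (Recall, Precision)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k))
                for k in ("ACC", "Precision", "Recall", "F1", "AUC", "AUPR")}


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    variance: float
    z: float
    p_value: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return labels


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    labels = _check_binary(labels)
    pred = np.asarray(scores) >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (labels == 1))),
        TN=int(np.sum(~pred & (labels == 0))),
        FP=int(np.sum(pred & (labels == 0))),
        FN=int(np.sum(~pred & (labels == 1))),
    )


def auc_mann_whitney(labels, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    m, n = int(labels.sum()), int((1 - labels).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = rankdata(scores)  # average ranks handle ties with 1/2 credit
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """All evaluation metrics plus ROC and PR curve points."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    cc = confusion(labels, scores, threshold)
    acc = (cc.TP + cc.TN) / cc.total
    precision = cc.TP / (cc.TP + cc.FP) if cc.TP + cc.FP else 0.0
    recall = cc.TP / (cc.TP + cc.FN) if cc.TP + cc.FN else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    auc = auc_mann_whitney(labels, scores)

    # ROC / PR points over descending unique score thresholds
    order = np.argsort(-scores, kind="mergesort")
    sl, ss = labels[order], scores[order]
    distinct = np.flatnonzero(np.diff(ss)) if len(ss) > 1 else np.array([], dtype=int)
    cut = np.concatenate([distinct, [len(ss) - 1]])
    tps = np.cumsum(sl)[cut].astype(float)
    fps = np.cumsum(1 - sl)[cut].astype(float)
    P, N = labels.sum(), (1 - labels).sum()
    tpr = np.concatenate([[0.0], tps / P])
    fpr = np.concatenate([[0.0], fps / N])
    prec = np.concatenate([[1.0], tps / (tps + fps)])
    # AUPR = sum over threshold steps of precision * recall increment
    aupr = float(np.sum(np.diff(tpr) * prec[1:]))
    return MetricsReport(ACC=acc, Precision=precision, Recall=recall, F1=f1,
                         AUC=auc, AUPR=aupr,
                         roc_points=np.column_stack([fpr, tpr]),
                         pr_points=np.column_stack([tpr, prec]))


def delong_paired(labels, scores_a, scores_b) -> DeLongResult:
    """DeLong test for the difference of two correlated AUCs.

    Structural components: for each positive sample the mean of the
    1/2-tie kernel against all negatives (V10) and vice versa (V01);
    var(dAUC) = [1,-1] (S10/m + S01/n) [1,-1]^T with S10, S01 the 2x2
    sample covariance matrices of the components of the two models.
    """
    labels = _check_binary(labels)
    a, b = (np.asarray(s, dtype=float) for s in (scores_a, scores_b))
    if not (len(labels) == len(a) == len(b)):
        raise ValueError("labels and both score vectors must be equal length")
    pos, neg = labels == 1, labels == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong test undefined: single-class labels")

    def components(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        x, y = s[pos], s[neg]
        psi = (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
        return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())

    v10a, v01a, auc_a = components(a)
    v10b, v01b, auc_b = components(b)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ (s10 / m + s01 / n) @ contrast)
    delta = auc_a - auc_b
    if var <= 0:
        if abs(delta) < 1e-12:
            return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        warnings.warn("degenerate DeLong variance with unequal AUCs; p reported as <1e-300")
        return DeLongResult(auc_a, auc_b, 0.0, np.inf if delta > 0 else -np.inf, 1e-300)
    z = delta / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, var, float(z), max(p, 1e-300))


# ---------------------------------------------------------------------------
# dataset tensorization

def manifest_tensors(df: pd.DataFrame, genome: Genome, width: int,
                     splits: tuple[str, ...] | None = None
                     ) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Encode a dataset manifest into (left, right, labels) arrays per split."""
    pairs = frame_to_pairs(df)
    split_col = df["split"].astype(str).tolist() if "split" in df else ["."] * len(pairs)
    cache: dict[str, np.ndarray] = {}

    def enc(region: GenomicRegion) -> np.ndarray:
        if region.key not in cache:
            cache[region.key] = region_to_tensor(genome, region, width)
        return cache[region.key]

    wanted = set(splits) if splits is not None else set(split_col)
    out: dict[str, list] = {s: [] for s in wanted}
    labels: dict[str, list] = {s: [] for s in wanted}
    rights: dict[str, list] = {s: [] for s in wanted}
    for p, s in zip(pairs, split_col):
        if s not in wanted:
            continue
        out[s].append(enc(p.left))
        rights[s].append(enc(p.right))
        labels[s].append(p.label)
    return {s: (np.stack(out[s]) if out[s] else np.empty((0, width, 4)),
                np.stack(rights[s]) if rights[s] else np.empty((0, width, 4)),
                np.array(labels[s], dtype=float))
            for s in wanted}


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")


def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on pre-sigmoid scores."""
    yt = Tensor(y.reshape(-1, 1))
    absx = logits.relu() + (-logits).relu()
    loss = logits.relu() - logits * yt + (Tensor(1.0) + (-absx).exp()).log()
    return loss.mean()


def _fit(model: EtnetModel, train_data, val_data, params: dict[str, Tensor],
         lr: float, epochs: int, batch_size: int, seed: int,
         patience: int | None) -> TrainHistory:
    stream = callable(train_data)
    if not stream:
        xl, xr, y = train_data
        if len(y) == 0:
            raise ValueError("training split is empty")
    rng = np.random.default_rng(seed)
    opt = Adam(list(params.values()), lr=lr)
    history = TrainHistory()
    best_state, best_auc, since_best = None, -np.inf, 0
    for epoch in range(epochs):
        if stream:  # fresh sample per epoch (synthetic data streams)
            xl, xr, y = train_data(epoch)
        order = rng.permutation(len(y))
        losses = []
        for lo in range(0, len(y), batch_size):
            idx = order[lo:lo + batch_size]
            logits = model.forward_logits(xl[idx], xr[idx], rng=rng)
            loss = _bce_with_logits(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.epoch_loss.append(float(np.mean(losses)))
        if val_data is not None and len(val_data[2]) > 0:
            vauc = auc_mann_whitney(val_data[2], model.predict(val_data[0], val_data[1]))
        else:
            vauc = float("nan")
        history.val_auc.append(vauc)
        if not np.isnan(vauc) and vauc > best_auc:
            best_auc, since_best = vauc, 0
            history.best_epoch = epoch
            best_state = model.state_dict()
        else:
            since_best += 1
        if patience is not None and since_best > patience:
            logger.info("early stopping at epoch %d (patience %d)", epoch, patience)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
        history.best_val_auc = best_auc
    return history


def train(model: EtnetModel, manifest: pd.DataFrame, genome: Genome,
          lr: float = 1e-5, epochs: int = 50, batch_size: int = 100,
          seed: int = 0, patience: int | None = None) -> TrainHistory:
    """Train from scratch on the manifest's train split, selecting the
    best-validation-AUC checkpoint. ``patience`` enables early stopping
    (the baseline protocol uses patience=5)."""
    data = manifest_tensors(manifest, genome, model.config.seq_len,
                            splits=("train", "validation"))
    return _fit(model, data["train"], data.get("validation"), model.params,
                lr=lr, epochs=epochs, batch_size=batch_size, seed=seed,
                patience=patience)


def train_arrays(model: EtnetModel, train_data, val_data=None, lr: float = 1e-5,
                 epochs: int = 50, batch_size: int = 100, seed: int = 0,
                 patience: int | None = None) -> TrainHistory:
    """Train directly on (left, right, labels) arrays (fixture pipelines).

    ``train_data`` may also be a callable ``epoch -> (left, right, labels)``
    for synthetic data streams that draw a fresh sample every epoch."""
    return _fit(model, train_data, val_data, model.params, lr=lr, epochs=epochs,
                batch_size=batch_size, seed=seed, patience=patience)


def finetune_selective(model: EtnetModel, manifest: pd.DataFrame | None,
                       genome: Genome | None = None, lr: float = 1e-4,
                       epochs: int = 30, patience: int | None = 5,
                       batch_size: int = 100, seed: int = 0,
                       train_data=None, val_data=None) -> TrainHistory:
    """Adapt input/conv/output layers to a new dataset; freeze the encoder.

    Accepts either a manifest + genome or pre-encoded arrays. Transformer
    parameters are excluded from the optimizer, so they remain bitwise
    unchanged.
    """
    if train_data is None:
        if manifest is None or genome is None:
            raise ValueError("provide a manifest and genome, or train_data arrays")
        data = manifest_tensors(manifest, genome, model.config.seq_len,
                                splits=("train", "validation"))
        train_data, val_data = data["train"], data.get("validation")
    adaptable = model.adaptable_parameters()
    if not adaptable or not model.transformer_parameters():
        raise ValueError("model lacks identifiable layer groups for selective fine-tuning")
    return _fit(model, train_data, val_data, adaptable, lr=lr, epochs=epochs,
                batch_size=batch_size, seed=seed, patience=patience)


# ---------------------------------------------------------------------------
# grouped evaluation

PAIR_SIZE_THRESHOLD = 541  # bp, the 95th percentile of native enhancer length


def _size_class(row: pd.Series) -> str:
    longest = max(row.left_end - row.left_start, row.right_end - row.right_start)
    return "small" if longest <= PAIR_SIZE_THRESHOLD else "large"


def evaluate_by_category(model: EtnetModel, manifest: pd.DataFrame, genome: Genome,
                         group_key: str = "se_category", split: str = "test",
                         min_group: int = 20, batch_size: int = 100) -> dict[str, dict]:
    """Per-group metrics on one split, plus the overall report.

    ``group_key`` is 'se_category', 'size_class' (derived from native
    enhancer lengths, threshold 541 bp), or any manifest column such as
    'cell_line'. Groups smaller than ``min_group`` or with single-class
    labels are flagged and their metrics omitted.
    """
    df = manifest[manifest["split"].astype(str) == split].reset_index(drop=True)
    if group_key == "size_class":
        groups = df.apply(_size_class, axis=1)
    elif group_key in df.columns:
        groups = df[group_key].astype(str)
    else:
        raise ValueError(f"unknown group key {group_key!r}")
    data = manifest_tensors(df.assign(split="all"), genome, model.config.seq_len)
    xl, xr, y = data["all"]
    scores = model.predict(xl, xr, batch_size=batch_size)
    out: dict[str, dict] = {}
    for name in ["overall", *sorted(groups.unique())]:
        mask = np.ones(len(df), bool) if name == "overall" else (groups == name).to_numpy()
        yy, ss = y[mask], scores[mask]
        entry: dict = {"n": int(mask.sum()), "flagged": False, "metrics": None}
        if entry["n"] < min_group and name != "overall":
            entry["flagged"] = True
        if len(np.unique(yy)) < 2:
            entry["flagged"] = True
        else:
            entry["metrics"] = metrics(yy, ss)
        out[name] = entry
    return out
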