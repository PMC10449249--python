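"""Branch A: the disease-category classifier (PDCM).

A (diagnosis, symptoms) unit is vectorized to 20x768 and 50x768
matrices, each encoded by a stacked bidirectional recurrent encoder to
a 768-wide feature; the two features are concatenated, dropout is
applied during training, the 6-wide symptom weight vector is prepended
and an affine softmax head assigns one of six categories (five Padua
disease items + Others).  The head is trained with focal loss, Adam
updates, a stratified 7:3 split, uncertainty-marker negative
amplification and best-validation-F1 early stopping; the encoder
parameters are deterministic functions of the seed and stay fixed (no
deep-learning framework is required offline).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from paduavte.encoder import FEATURE_DIM, EncoderParams, encode_batch
from paduavte.swm import N_CATEGORIES, SwmStats
from paduavte.vectorize import HashingVectorizer, Vectorizer

FUSED_DIM = 2 * FEATURE_DIM  # 1536
HEAD_DIM = N_CATEGORIES + FUSED_DIM  # 1542

MODES = ("diagnose_only", "diagnose_symptom", "pdcm", "pdcm_without_amplification")

__all__ = [
    "TrainingUnit",
    "TrainConfig",
    "FusedFeature",
    "PDCMModel",
    "fuse",
    "classify",
    "focal_loss",
    "amplify_negatives",
    "train",
    "predict_patient",
]


@dataclass
class TrainingUnit:
    diagnosis_text: str
    symptom_terms: List[str]
    category_label: int

    def __post_init__(self) -> None:
        if not self.diagnosis_text:
            raise ValueError("diagnosis_text must be non-empty")
        if not (0 <= self.category_label < N_CATEGORIES):
            raise ValueError(f"category_label out of range: {self.category_label}")


@dataclass
class TrainConfig:
    max_epochs: int = 100
    patience: int = 10
    train_fraction: float = 0.7
    dropout_rate: float = 0.5
    focal_gamma: float = 2.0
    focal_alpha: Optional[List[float]] = None  # None => inverse-frequency
    seed: int = 0
    mode: str = "pdcm"
    amplify_fraction: float = 0.10
    uncertainty_markers: List[str] = field(default_factory=lambda: ["?", "undecided"])
    learning_rate: float = 1e-3
    batch_size: int = 32
    f1_average: str = "macro"
    loss_eps: float = 1e-7

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if not (0 <= self.amplify_fraction <= 1):
            raise ValueError("amplify_fraction must be in [0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.f1_average not in ("macro", "micro"):
            raise ValueError("f1_average must be macro or micro")


@dataclass
class FusedFeature:
    h_concatenated: np.ndarray  # (1536,)
    h_dropouted: np.ndarray  # (1536,)
    h_swm: np.ndarray  # (1542,)


def fuse(
    h_diag: np.ndarray,
    h_symp: np.ndarray,
    swm: Sequence[float],
    dropout_rate: float = 0.0,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> FusedFeature:
    """Concatenate [diagnosis, symptoms], dropout (training only), prepend SWM."""
    h_diag = np.asarray(h_diag, dtype=np.float64)
    h_symp = np.asarray(h_symp, dtype=np.float64)
    swm = np.asarray(swm, dtype=np.float64)
    if h_diag.shape != (FEATURE_DIM,) or h_symp.shape != (FEATURE_DIM,):
        raise ValueError(f"feature vectors must have length {FEATURE_DIM}")
    if swm.shape != (N_CATEGORIES,):
        raise ValueError(f"swm must have length {N_CATEGORIES}")
    h_concat = np.concatenate([h_diag, h_symp])
    if training and dropout_rate > 0:
        gen = rng if rng is not None else np.random.default_rng()
        keep = (gen.random(FUSED_DIM) >= dropout_rate).astype(np.float64)
        h_drop = h_concat * keep / (1.0 - dropout_rate)
    else:
        h_drop = h_concat.copy()
    return FusedFeature(h_concat, h_drop, np.concatenate([swm, h_drop]))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def classify(fused: FusedFeature | np.ndarray, weights: np.ndarray, bias: np.ndarray, head: str = "softmax") -> np.ndarray:
    """Affine map to 6 logits, then softmax (default) or sigmoid."""
    x = fused.h_swm if isinstance(fused, FusedFeature) else np.asarray(fused, dtype=np.float64)
    z = x @ weights + bias
    if head == "softmax":
        return _softmax(z)
    if head == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"bad head {head!r}")


def focal_loss(
    scores: np.ndarray,
    labels: np.ndarray | int,
    gamma: float = 2.0,
    alpha: Optional[Sequence[float]] = None,
    eps: float = 1e-7,
) -> float:
    """Batch-averaged focal loss -alpha_y (1-p_y)^gamma log(p_y).

    Reduces to cross-entropy at gamma=0, alpha=1.
    """
    p = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    y = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    if p.shape[0] != y.shape[0]:
        raise ValueError("scores/labels length mismatch")
    a = np.ones(p.shape[1]) if alpha is None else np.asarray(alpha, dtype=np.float64)
    py = np.clip(p[np.arange(len(y)), y], eps, 1.0)
    losses = -a[y] * (1.0 - py) ** gamma * np.log(py)
    return float(losses.mean())


def amplify_negatives(
    units: Sequence[TrainingUnit],
    fraction: float = 0.10,
    markers: Sequence[str] = ("?", "undecided"),
    seed: int = 0,
) -> List[TrainingUnit]:
    """Append uncertainty-marked copies of Padua-category diagnoses as Others.

    ``floor(fraction * n_padua)`` units with labels 0..4 are sampled
    without replacement (seeded); each copy's diagnosis text gains a
    random marker and is relabeled to the Others class (5).
    """
    if not units:
        raise ValueError("units must be non-empty")
    if not markers:
        raise ValueError("markers must be non-empty")
    if fraction > 1:
        raise ValueError("fraction must be <= 1")
    padua_idx = [i for i, u in enumerate(units) if u.category_label != N_CATEGORIES - 1]
    k = int(math.floor(fraction * len(padua_idx)))
    rng = np.random.Generator(np.random.Philox(key=np.uint64(seed)))
    out = list(units)
    if k == 0:
        return out
    chosen = rng.choice(len(padua_idx), size=k, replace=False)
    for j in sorted(chosen):
        u = units[padua_idx[int(j)]]
        marker = markers[int(rng.integers(len(markers)))]
        out.append(TrainingUnit(f"{u.diagnosis_text} {marker}", list(u.symptom_terms), N_CATEGORIES - 1))
    return out


def _f1_multiclass(pred: np.ndarray, truth: np.ndarray, average: str = "macro") -> float:
    classes = range(N_CATEGORIES)
    if average == "micro":
        tp = sum(int(((pred == c) & (truth == c)).sum()) for c in classes)
        fp = sum(int(((pred == c) & (truth != c)).sum()) for c in classes)
        fn = sum(int(((pred != c) & (truth == c)).sum()) for c in classes)
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    scores = []
    for c in classes:
        if not ((truth == c).any() or (pred == c).any()):
            continue
        tp = int(((pred == c) & (truth == c)).sum())
        fp = int(((pred == c) & (truth != c)).sum())
        fn = int(((pred != c) & (truth == c)).sum())
        scores.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return float(np.mean(scores)) if scores else 0.0


class PDCMModel:
    """Trained Branch A model: vectorizer + frozen encoders + fitted head."""

    def __init__(
        self,
        vectorizer: Vectorizer,
        swm_stats: SwmStats,
        config: TrainConfig,
        weights: Optional[np.ndarray] = None,
        bias: Optional[np.ndarray] = None,
    ):
        self.vectorizer = vectorizer
        self.swm_stats = swm_stats
        self.config = config
        self.diag_encoder = EncoderParams.init(seed=config.seed * 2 + 1)
        self.symp_encoder = EncoderParams.init(seed=config.seed * 2 + 2)
        self.weights = weights if weights is not None else np.zeros((HEAD_DIM, N_CATEGORIES))
        self.bias = bias if bias is not None else np.zeros(N_CATEGORIES)
        self.history: List[dict] = []
        self.best_epoch: Optional[int] = None

    # -- feature assembly -------------------------------------------------

    def _mode_masks(self) -> Tuple[float, float]:
        """(symptom feature multiplier, swm multiplier) for the ablation mode."""
        mode = self.config.mode
        if mode == "diagnose_only":
            return 0.0, 0.0
        if mode == "diagnose_symptom":
            return 1.0, 0.0
        return 1.0, 1.0

    def features(self, units: Sequence[TrainingUnit]) -> np.ndarray:
        """Fused (n, 1542) features [SWM, h_diag, h_symp] for a batch of units."""
        symp_mask, swm_mask = self._mode_masks()
        diag_mats = np.stack([self.vectorizer.vectorize(u.diagnosis_text, "diagnosis") for u in units])
        h_diag = encode_batch(diag_mats, self.diag_encoder)
        if symp_mask:
            symp_mats = np.stack([self.vectorizer.vectorize(u.symptom_terms, "symptom") for u in units])
            h_symp = encode_batch(symp_mats, self.symp_encoder)
        else:
            h_symp = np.zeros((len(units), FEATURE_DIM))
        if swm_mask:
            swm = np.array([self.swm_stats.swm(u.symptom_terms) for u in units])
        else:
            swm = np.zeros((len(units), N_CATEGORIES))
        return np.concatenate([swm, h_diag, h_symp * symp_mask], axis=1)

    def predict_scores(self, units: Sequence[TrainingUnit]) -> np.ndarray:
        if not units:
            return np.zeros((0, N_CATEGORIES))
        return _softmax(self.features(units) @ self.weights + self.bias)

    def predict_labels(self, units: Sequence[TrainingUnit]) -> np.ndarray:
        return self.predict_scores(units).argmax(axis=1)

    # -- persistence ------------------------------------------------------

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "vectorizer": self.vectorizer.spec(),
            "swm_stats": json.loads(self.swm_stats.to_json()),
            "best_epoch": self.best_epoch,
            "history": self.history,
        }
        with open(os.path.join(directory, "model.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, ensure_ascii=False)
        np.savez(os.path.join(directory, "head.npz"), weights=self.weights, bias=self.bias)

    @classmethod
    def load(cls, directory: str) -> "PDCMModel":
        with open(os.path.join(directory, "model.json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        config = TrainConfig(**meta["config"])
        vectorizer = HashingVectorizer.from_spec(meta["vectorizer"])
        swm_stats = SwmStats.from_json(json.dumps(meta["swm_stats"]))
        arrays = np.load(os.path.join(directory, "head.npz"))
        model = cls(vectorizer, swm_stats, config, weights=arrays["weights"], bias=arrays["bias"])
        model.best_epoch = meta.get("best_epoch")
        model.history = meta.get("history", [])
        return model


def _stratified_split(labels: np.ndarray, train_fraction: float, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    train_idx: List[int] = []
    val_idx: List[int] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(train_fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
        train_idx.extend(idx[:k].tolist())
        val_idx.extend(idx[k:].tolist())
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def train(
    units: Sequence[TrainingUnit],
    swm_stats: SwmStats,
    config: TrainConfig | None = None,
    vectorizer: Optional[Vectorizer] = None,
) -> PDCMModel:
    """Fit the classification head; returns the best-validation-F1 model.

    Stratified seeded 7:3 split; uncertainty-marker amplification is
    applied to the training portion unless the mode disables it;
    training runs at most ``max_epochs`` epochs and stops early after
    ``patience`` epochs without validation-F1 improvement.
    """
    config = config or TrainConfig()
    labels_all = np.array([u.category_label for u in units])
    if len(np.unique(labels_all)) < 2:
        raise ValueError("training requires at least two categories")

    vec = vectorizer if vectorizer is not None else HashingVectorizer(seed=config.seed)
    model = PDCMModel(vec, swm_stats, config)
    rng = np.random.Generator(np.random.Philox(key=np.uint64(config.seed) ^ np.uint64(0xA5A5A5A5)))

    train_idx, val_idx = _stratified_split(labels_all, config.train_fraction, rng)
    train_units: List[TrainingUnit] = [units[i] for i in train_idx]
    val_units: List[TrainingUnit] = [units[i] for i in val_idx]

    if config.mode != "pdcm_without_amplification" and config.amplify_fraction > 0:
        train_units = amplify_negatives(
            train_units, config.amplify_fraction, config.uncertainty_markers, seed=config.seed
        )

    x_train = model.features(train_units)
    y_train = np.array([u.category_label for u in train_units])
    x_val = model.features(val_units)
    y_val = np.array([u.category_label for u in val_units])

    if config.focal_alpha is not None:
        alpha = np.asarray(config.focal_alpha, dtype=np.float64)
    else:
        counts = np.bincount(y_train, minlength=N_CATEGORIES).astype(np.float64)
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        alpha = inv / inv.sum() * N_CATEGORIES  # inverse-frequency, mean 1

    w = np.zeros((HEAD_DIM, N_CATEGORIES))
    b = np.zeros(N_CATEGORIES)
    m_w = np.zeros_like(w); v_w = np.zeros_like(w)
    m_b = np.zeros_like(b); v_b = np.zeros_like(b)
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0

    best_f1 = -1.0
    best = (w.copy(), b.copy(), 0)
    stall = 0
    n = len(train_units)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            yb = y_train[idx]
            if config.dropout_rate > 0:
                keep = (rng.random(xb[:, N_CATEGORIES:].shape) >= config.dropout_rate).astype(np.float64)
                xb = xb.copy()
                xb[:, N_CATEGORIES:] = xb[:, N_CATEGORIES:] * keep / (1.0 - config.dropout_rate)
            p = _softmax(xb @ w + b)
            py = np.clip(p[np.arange(len(yb)), yb], config.loss_eps, 1.0)
            one_minus = 1.0 - py
            loss = float((-alpha[yb] * one_minus**config.focal_gamma * np.log(py)).mean())
            epoch_loss += loss * len(yb)
            # d(loss)/d(p_y), then chain through softmax
            g = config.focal_gamma
            dL_dpy = alpha[yb] * (g * one_minus ** max(g - 1.0, 0.0) * np.log(py) - one_minus**g / py)
            onehot = np.zeros_like(p)
            onehot[np.arange(len(yb)), yb] = 1.0
            dz = (dL_dpy * py)[:, None] * (onehot - p) / len(yb)
            gw = xb.T @ dz
            gb = dz.sum(axis=0)
            step += 1
            m_w = beta1 * m_w + (1 - beta1) * gw; v_w = beta2 * v_w + (1 - beta2) * gw**2
            m_b = beta1 * m_b + (1 - beta1) * gb; v_b = beta2 * v_b + (1 - beta2) * gb**2
            corr1 = 1 - beta1**step; corr2 = 1 - beta2**step
            w -= config.learning_rate * (m_w / corr1) / (np.sqrt(v_w / corr2) + adam_eps)
            b -= config.learning_rate * (m_b / corr1) / (np.sqrt(v_b / corr2) + adam_eps)

        val_pred = _softmax(x_val @ w + b).argmax(axis=1)
        val_f1 = _f1_multiclass(val_pred, y_val, config.f1_average)
        model.history.append({"epoch": epoch, "train_loss": epoch_loss / n, "val_f1": val_f1})
        if val_f1 > best_f1:
            best_f1 = val_f1
            best = (w.copy(), b.copy(), epoch)
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    model.weights, model.bias, model.best_epoch = best
    return model


def predict_patient(
    model: PDCMModel,
    diagnoses: Sequence[str],
    symptoms: Sequence[str],
) -> Tuple[List[bool], np.ndarray]:
    """Patient-level Branch A aggregation.

    Each diagnosis forms a unit with the patient's symptoms; a Padua
    disease item (categories 0..4) is flagged iff some unit's argmax
    lands on it, and the per-category patient score is the max over
    units.  No diagnoses => all flags false, zero scores.
    """
    if not diagnoses:
        return [False] * (N_CATEGORIES - 1), np.zeros(N_CATEGORIES)
    units = [TrainingUnit(d, list(symptoms), 0) for d in diagnoses if d.strip()]
    if not units:
        return [False] * (N_CATEGORIES - 1), np.zeros(N_CATEGORIES)
    scores = model.predict_scores(units)
    argmax = scores.argmax(axis=1)
    flags = [bool((argmax == k).any()) for k in range(N_CATEGORIES - 1)]
    return flags, scores.max(axis=0)
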