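"""Evaluation indexes: AUC, F1, Hamming distance, one-error, ranking loss,
coverage, and the sensitivity/specificity/precision panel.

All metrics are implemented directly over numpy arrays (ties get half
credit in the rank-based metrics, the standard Mann-Whitney
treatment); the test suite checks each against a brute-force
enumeration oracle.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np

__all__ = [
    "auc",
    "f1",
    "hamming_distance",
    "one_error",
    "ranking_loss",
    "coverage",
    "binary_panel",
    "multilabel_report",
]


def _columns(scores, labels):
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValueError("scores/labels shape mismatch")
    return s, y


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute half."""
    s, y = _columns(scores, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes present")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=np.float64)
    # average ranks over ties
    sorted_s = s[order]
    i = 0
    rank = 1
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        avg = (rank + rank + (j - i)) / 2.0
        ranks[order[i : j + 1]] = avg
        rank += j - i + 1
        i = j + 1
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _matrices(pred, truth):
    p = np.asarray(pred).astype(int)
    t = np.asarray(truth).astype(int)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    return p, t


def f1(pred, truth, average: str = "macro") -> float:
    """Multi-label F1 over binary matrices; zero denominators give 0."""
    p, t = _matrices(pred, truth)
    p = np.atleast_2d(p)
    t = np.atleast_2d(t)
    if average == "micro":
        tp = int(((p == 1) & (t == 1)).sum())
        fp = int(((p == 1) & (t == 0)).sum())
        fn = int(((p == 0) & (t == 1)).sum())
        denom = 2 * tp + fp + fn
        return 2 * tp / denom if denom else 0.0
    if average == "macro":
        vals = []
        for j in range(p.shape[1]):
            tp = int(((p[:, j] == 1) & (t[:, j] == 1)).sum())
            fp = int(((p[:, j] == 1) & (t[:, j] == 0)).sum())
            fn = int(((p[:, j] == 0) & (t[:, j] == 1)).sum())
            denom = 2 * tp + fp + fn
            vals.append(2 * tp / denom if denom else 0.0)
        return float(np.mean(vals))
    raise ValueError("average must be macro or micro")


def hamming_distance(pred, truth) -> float:
    """Fraction of label slots where prediction and truth disagree."""
    p, t = _matrices(pred, truth)
    return float((p != t).mean())


def one_error(scores, truth) -> float:
    """Fraction of samples whose top-scored label is not relevant."""
    s = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    t = np.atleast_2d(np.asarray(truth).astype(int))
    if s.shape != t.shape:
        raise ValueError("shape mismatch")
    errs = []
    for i in range(s.shape[0]):
        if t[i].sum() == 0:
            warnings.warn(f"one_error: sample {i} has no relevant label; excluded")
            continue
        errs.append(0.0 if t[i, int(s[i].argmax())] == 1 else 1.0)
    if not errs:
        raise ValueError("one_error: no sample with a relevant label")
    return float(np.mean(errs))


def ranking_loss(scores, truth) -> float:
    """Mean fraction of (relevant, irrelevant) pairs ranked wrongly; ties half."""
    s = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    t = np.atleast_2d(np.asarray(truth).astype(int))
    if s.shape != t.shape:
        raise ValueError("shape mismatch")
    vals = []
    for i in range(s.shape[0]):
        rel = np.flatnonzero(t[i] == 1)
        irr = np.flatnonzero(t[i] == 0)
        if len(rel) == 0 or len(irr) == 0:
            warnings.warn(f"ranking_loss: sample {i} degenerate; excluded")
            continue
        bad = 0.0
        for r in rel:
            for q in irr:
                if s[i, r] < s[i, q]:
                    bad += 1.0
                elif s[i, r] == s[i, q]:
                    bad += 0.5
        vals.append(bad / (len(rel) * len(irr)))
    if not vals:
        raise ValueError("ranking_loss: all samples degenerate")
    return float(np.mean(vals))


def coverage(scores, truth, normalized: bool = False) -> float:
    """Mean (worst relevant label's 1-based rank by descending score) - 1.

    With ``normalized`` the per-sample value is divided by the number
    of labels L, mapping the range [0, L-1] into [0, 1).
    """
    s = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    t = np.atleast_2d(np.asarray(truth).astype(int))
    if s.shape != t.shape:
        raise ValueError("shape mismatch")
    L = s.shape[1]
    vals = []
    for i in range(s.shape[0]):
        rel = np.flatnonzero(t[i] == 1)
        if len(rel) == 0:
            warnings.warn(f"coverage: sample {i} has no relevant label; excluded")
            continue
        # rank of label j = number of labels with strictly greater score, + 1
        worst = 0
        for r in rel:
            rank = 1 + int((s[i] > s[i, r]).sum())
            worst = max(worst, rank)
        v = float(worst - 1)
        vals.append(v / L if normalized else v)
    if not vals:
        raise ValueError("coverage: no sample with a relevant label")
    return float(np.mean(vals))


def binary_panel(pred, truth) -> Dict[str, Optional[float]]:
    """Sensitivity, specificity, precision; undefined ratios are None."""
    p = np.asarray(pred).astype(bool).ravel()
    t = np.asarray(truth).astype(bool).ravel()
    if p.shape != t.shape or len(p) == 0:
        raise ValueError("pred/truth must be non-empty and same length")
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "precision": tp / (tp + fp) if (tp + fp) else None,
    }


def multilabel_report(scores, pred, truth, normalized_coverage: bool = False) -> Dict[str, float]:
    """The full index panel, keyed in report column order."""
    s = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    t = np.atleast_2d(np.asarray(truth).astype(int))
    aucs = []
    for j in range(s.shape[1]):
        if len(set(t[:, j].tolist())) == 2:
            aucs.append(auc(s[:, j], t[:, j]))
    return {
        "AUC": float(np.mean(aucs)) if aucs else None,
        "HD": hamming_distance(pred, truth),
        "RL": ranking_loss(s, t),
        "Cov": coverage(s, t, normalized=normalized_coverage),
        "OE": one_error(s, t),
        "F1": f1(pred, truth, average="macro"),
    }
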