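"""The evaluation suite for imbalanced five-class taste prediction.

Covers per-class precision/recall/F1, accuracy, the macro (unweighted) and
class-frequency-weighted averages, one-vs-rest AUROC, support-aware scoring
under abstention, reduction to binary one-vs-rest tasks, and the
multi-label analysis in which every class with probability above 1/C
(i.e. > 0.2 for five classes) counts as a predicted label.

Conventions: macro = (1/C) sum_i M_i; weighted = sum_i (n_i/N) M_i with n_i
the class-i instance count. Undefined 0/0 ratios score 0 and are flagged.
Under abstention, accuracy and the per-class metrics are computed on the
accepted subset only, with the accepted fraction reported as support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .labels import ABSTAIN, LABEL_ORDER, N_CLASSES, TasteLabel
from .confidence import consensus_predict, support_fraction

logger = logging.getLogger(__name__)


@dataclass
class PerClassMetrics:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    undefined_flags: np.ndarray  # True where a 0/0 was scored as 0


@dataclass
class MetricsTable:
    n_classes: int
    class_counts: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    auroc: np.ndarray | None
    macro: dict
    weighted: dict
    support_fraction: float = 1.0

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "support_fraction": self.support_fraction,
            "per_class": {
                lab.value: {
                    "n": int(self.class_counts[i]),
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    **(
                        {"auroc": float(self.auroc[i])}
                        if self.auroc is not None and np.isfinite(self.auroc[i])
                        else {}
                    ),
                }
                for i, lab in enumerate(LABEL_ORDER)
            },
            "macro": {k: float(v) for k, v in self.macro.items()},
            "weighted": {k: float(v) for k, v in self.weighted.items()},
        }
        return out


@dataclass
class MultiLabelOutcome:
    n_exact: int = 0
    n_too_many: int = 0
    n_collapsed: int = 0
    n_collapsed_correct: int = 0
    n_other: int = 0
    threshold: float = 0.2


def _as_indices(labels) -> np.ndarray:
    return np.asarray(
        [l.index if isinstance(l, TasteLabel) else int(l) for l in labels], dtype=int
    )


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """5x5 count matrix; entry (i, j) = truths of class i predicted as j."""
    t, p = _as_indices(y_true), _as_indices(y_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} vs {len(p)}")
    if len(t) and (t.min() < 0 or t.max() >= N_CLASSES or p.min() < 0 or p.max() >= N_CLASSES):
        raise ValueError("label index outside the five classes")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def per_class_metrics(cm: np.ndarray) -> PerClassMetrics:
    """One-vs-rest precision, recall and F1 per class; 0/0 scores 0, flagged."""
    cm = np.asarray(cm)
    tp = np.diag(cm).astype(float)
    pred = cm.sum(axis=0).astype(float)
    true = cm.sum(axis=1).astype(float)
    undefined = (pred == 0) | (true == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred > 0, tp / np.maximum(pred, 1), 0.0)
        recall = np.where(true > 0, tp / np.maximum(true, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    if undefined.any():
        logger.debug(
            "classes with undefined (0/0) metrics scored as 0: %s",
            [LABEL_ORDER[i].value for i in np.flatnonzero(undefined)],
        )
    return PerClassMetrics(precision=precision, recall=recall, f1=f1, undefined_flags=undefined)


def macro_average(values) -> float:
    """Unweighted mean of a per-class metric: (1/C) sum_i M_i."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("macro average of no values")
    return float(values.mean())


def weighted_average(values, counts) -> float:
    """Class-frequency-weighted mean: sum_i (n_i / N) M_i."""
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("negative class count")
    total = counts.sum()
    if total == 0:
        raise ValueError("weighted average with all-zero counts")
    return float((counts / total) @ values)


def _auroc_rank(y_binary: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUROC with midrank ties."""
    n_pos = int(y_binary.sum())
    n_neg = len(y_binary) - n_pos
    ranks = rankdata(scores)
    return (ranks[y_binary == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def ovr_auroc(y_true, probabilities) -> tuple[np.ndarray, float]:
    """One-vs-rest AUROC per class plus the macro average over scored classes.

    Classes without both a positive and a negative example are skipped
    (NaN in the per-class vector) and excluded from the macro average.
    """
    t = _as_indices(y_true)
    P = np.asarray(probabilities, dtype=float)
    if P.shape != (len(t), N_CLASSES):
        raise ValueError(f"probability array shape {P.shape} != ({len(t)}, {N_CLASSES})")
    per_class = np.full(N_CLASSES, np.nan)
    for i in range(N_CLASSES):
        y_bin = (t == i).astype(int)
        if 0 < y_bin.sum() < len(y_bin):
            per_class[i] = _auroc_rank(y_bin, P[:, i])
        else:
            logger.debug("AUROC skipped for degenerate class %s", LABEL_ORDER[i].value)
    scored = per_class[np.isfinite(per_class)]
    macro = float(scored.mean()) if scored.size else float("nan")
    return per_class, macro


def binary_reduction(y_true, y_pred_or_abstain, positive_class: TasteLabel, probabilities=None):
    """Collapse to positive-vs-rest; abstentions are excluded, support reported.

    Returns a dict with accuracy, precision, recall, f1, support (fraction
    scored) and, when probability vectors are given, the AUROC of the
    positive-class probability.
    """
    y_true = list(y_true)
    y_pred_or_abstain = list(y_pred_or_abstain)
    pairs = [(t, p) for t, p in zip(y_true, y_pred_or_abstain) if p is not ABSTAIN]
    n_total = len(y_true)
    support = len(pairs) / n_total if n_total else 0.0
    t_bin = np.asarray([1 if t == positive_class else 0 for t, _ in pairs])
    p_bin = np.asarray([1 if p == positive_class else 0 for _, p in pairs])
    tp = int(((t_bin == 1) & (p_bin == 1)).sum())
    fp = int(((t_bin == 0) & (p_bin == 1)).sum())
    fn = int(((t_bin == 1) & (p_bin == 0)).sum())
    accuracy = float((t_bin == p_bin).mean()) if len(pairs) else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    out = {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "support": support,
    }
    if probabilities is not None:
        P = np.asarray(probabilities, dtype=float)
        y_bin_all = np.asarray([1 if t == positive_class else 0 for t in y_true])
        if 0 < y_bin_all.sum() < len(y_bin_all):
            out["auroc"] = _auroc_rank(y_bin_all, P[:, positive_class.index])
    return out


def multilabel_eval(probabilities, true_label_sets, threshold: float = 0.2) -> MultiLabelOutcome:
    """Categorize multi-taste molecules by the labels with p > threshold.

    Per molecule the predicted set is {i : p_i > threshold} (strict).
    Categories (mutually exclusive): *exact* — predicted set equals the
    true set; *too_many* — a strict superset; *collapsed* — exactly one
    predicted label, counted as *collapsed_correct* when that label is in
    the true set; everything else falls into *other*. Molecules whose only
    extra label is "undefined" should be excluded upstream.
    """
    out = MultiLabelOutcome(threshold=threshold)
    P = np.asarray(probabilities, dtype=float)
    for p_vec, true_set in zip(P, true_label_sets):
        true_idx = frozenset(
            l.index if isinstance(l, TasteLabel) else int(l) for l in true_set
        )
        pred_idx = frozenset(np.flatnonzero(p_vec > threshold).tolist())
        if pred_idx == true_idx:
            out.n_exact += 1
        elif pred_idx > true_idx:
            out.n_too_many += 1
        elif len(pred_idx) == 1:
            out.n_collapsed += 1
            if next(iter(pred_idx)) in true_idx:
                out.n_collapsed_correct += 1
        else:
            out.n_other += 1
    return out


def evaluate(
    model,
    test_records,
    confidence_k: int | None = None,
    confidence_threshold: int | None = None,
    seed: int = 0,
) -> MetricsTable:
    """Score a model on held-out records; optionally under consensus voting.

    Without confidence settings every record receives its argmax label.
    With ``confidence_k`` set, predictions come from consensus voting over
    k synonymous SMILES; abstained molecules are excluded from accuracy and
    per-class metrics but counted in the reported support. AUROC is always
    computed from the canonical-form probability vectors of all records.
    """
    records = list(test_records)
    if not records:
        raise ValueError("empty test set")
    y_true = [r.label for r in records]
    smiles_in = [r.canonical_smiles or r.raw_smiles for r in records]
    probs = np.stack([model.predict_proba(s) for s in smiles_in])

    if confidence_k:
        results = [
            consensus_predict(model, s, k=confidence_k, threshold=confidence_threshold, seed=seed + i)
            for i, s in enumerate(smiles_in)
        ]
        y_pred = [r.accepted_label for r in results]
        support = support_fraction(results)
    else:
        y_pred = [LABEL_ORDER[int(np.argmax(p))] for p in probs]
        support = 1.0

    scored = [(t, p) for t, p in zip(y_true, y_pred) if p is not ABSTAIN]
    if not scored:
        raise ValueError("all predictions abstained; nothing to score")
    cm = confusion_matrix([t for t, _ in scored], [p for _, p in scored])
    pc = per_class_metrics(cm)
    counts = cm.sum(axis=1)
    accuracy = float(np.diag(cm).sum() / cm.sum())
    auroc_per_class, auroc_macro = ovr_auroc(y_true, probs)

    macro = {
        "precision": macro_average(pc.precision),
        "recall": macro_average(pc.recall),
        "f1": macro_average(pc.f1),
        "auroc": auroc_macro,
    }
    weighted = {
        "precision": weighted_average(pc.precision, counts),
        "recall": weighted_average(pc.recall, counts),
        "f1": weighted_average(pc.f1, counts),
    }
    return MetricsTable(
        n_classes=N_CLASSES,
        class_counts=counts,
        accuracy=accuracy,
        precision=pc.precision,
        recall=pc.recall,
        f1=pc.f1,
        auroc=auroc_per_class,
        macro=macro,
        weighted=weighted,
        support_fraction=support,
    )
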