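"""Evaluation of ordinal skin tone classification with tolerance margins.

Accuracy is the proportion of images classified correctly, where "correct"
allows a deviation margin expressed as a fraction of the scale:

    correct  ⇔  |predicted − gold| ≤ floor(margin · K)

so a 10% margin is a one-class tolerance on the 10-class Monk scale and an
exact-match requirement on the 6-class Fitzpatrick scale, and a 20% margin
("sufficient accuracy") is two Monk classes or one Fitzpatrick class.  An
alternative reading of the margin as a fraction of the ITA axis is
available via ``margin_semantics="ita_fraction"``.

Balanced accuracy is the mean per-class recall (same tolerance), computed
over classes that actually occur in the gold standard.  Agreement among
human raters uses Fleiss' kappa; subgroup accuracy differences use the
Mann–Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "EvalConfig",
    "EvalReport",
    "class_tolerance",
    "pair_correct",
    "tolerance_accuracy",
    "per_class_recall",
    "balanced_accuracy",
    "confusion_matrix",
    "evaluate",
    "fleiss_kappa",
    "mann_whitney",
    "subgroup_compare",
]


@dataclass(frozen=True)
class EvalConfig:
    accuracy_margin: float = 0.10
    sufficient_margin: float = 0.20
    margin_semantics: str = "class_fraction"  # or "ita_fraction"

    def __post_init__(self):
        for m in (self.accuracy_margin, self.sufficient_margin):
            if not 0 <= m < 1:
                raise ValueError("margins must lie in [0, 1)")
        if self.margin_semantics not in ("class_fraction", "ita_fraction"):
            raise ValueError(f"unknown margin semantics {self.margin_semantics!r}")


def class_tolerance(margin: float, n_classes: int) -> int:
    """Allowed absolute class deviation: floor(margin · K)."""
    return math.floor(margin * n_classes)


def _validate_pairs(gold, pred, n_classes):
    gold = np.asarray(gold, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if gold.size == 0:
        raise ValueError("metric undefined on empty input")
    if gold.shape != pred.shape:
        raise ValueError("gold and predicted class arrays differ in length")
    for name, arr in (("gold", gold), ("predicted", pred)):
        if arr.min() < 1 or arr.max() > n_classes:
            raise ValueError(f"{name} classes outside [1, {n_classes}]")
    return gold, pred


def pair_correct(
    gold, pred, margin: float, n_classes: int,
    semantics: str = "class_fraction", gold_ita=None, pred_ita=None,
) -> np.ndarray:
    """Boolean per-pair correctness under the tolerance margin."""
    gold, pred = _validate_pairs(gold, pred, n_classes)
    if semantics == "class_fraction":
        return np.abs(pred - gold) <= class_tolerance(margin, n_classes)
    if semantics == "ita_fraction":
        if gold_ita is None or pred_ita is None:
            raise ValueError("ita_fraction semantics require gold_ita and pred_ita")
        # margin as a fraction of the 200° span of the serialized ITA tables
        dev = np.abs(np.asarray(pred_ita, float) - np.asarray(gold_ita, float))
        return dev <= margin * 200.0
    raise ValueError(f"unknown margin semantics {semantics!r}")


def tolerance_accuracy(gold, pred, margin: float, n_classes: int, **kw) -> float:
    """Proportion of pairs correct within the margin (Eq.: correct / total)."""
    return float(np.mean(pair_correct(gold, pred, margin, n_classes, **kw)))


def per_class_recall(gold, pred, margin: float, n_classes: int, **kw) -> np.ndarray:
    """Tolerance-correct proportion among pairs of each gold class.

    Returns an array of length K with NaN for classes without gold support.
    """
    gold_a, _ = _validate_pairs(gold, pred, n_classes)
    ok = pair_correct(gold, pred, margin, n_classes, **kw)
    out = np.full(n_classes, np.nan)
    for k in range(1, n_classes + 1):
        sel = gold_a == k
        if sel.any():
            out[k - 1] = float(ok[sel].mean())
    return out


def balanced_accuracy(gold, pred, margin: float, n_classes: int, **kw) -> float:
    """Mean per-class recall over classes present in the gold standard."""
    rec = per_class_recall(gold, pred, margin, n_classes, **kw)
    return float(np.nanmean(rec))


def confusion_matrix(gold, pred, n_classes: int) -> np.ndarray:
    """K×K counts, rows = gold class, columns = predicted class."""
    gold, pred = _validate_pairs(gold, pred, n_classes)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (gold - 1, pred - 1), 1)
    return cm


@dataclass
class EvalReport:
    """Tolerance accuracies, balanced accuracy, recalls, confusion matrix."""

    scale_name: str
    n: int
    n_classes: int
    accuracy: float
    sufficient_accuracy: float
    balanced_accuracy: float
    per_class_recall: list
    confusion_matrix: list
    config: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale_name,
            "n": self.n,
            "n_classes": self.n_classes,
            "accuracy": self.accuracy,
            "sufficient_accuracy": self.sufficient_accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "per_class_recall": self.per_class_recall,
            "confusion_matrix": self.confusion_matrix,
            "accuracy_margin": self.config.accuracy_margin,
            "sufficient_margin": self.config.sufficient_margin,
            "margin_semantics": self.config.margin_semantics,
        }


def evaluate(
    gold, pred, n_classes: int, scale_name: str = "", config: EvalConfig | None = None, **kw
) -> EvalReport:
    """Full evaluation of predicted vs gold classes on one scale."""
    config = config or EvalConfig()
    sem = dict(semantics=config.margin_semantics, **kw)
    rec = per_class_recall(gold, pred, config.accuracy_margin, n_classes, **sem)
    return EvalReport(
        scale_name=scale_name,
        n=int(np.asarray(gold).size),
        n_classes=n_classes,
        accuracy=tolerance_accuracy(gold, pred, config.accuracy_margin, n_classes, **sem),
        sufficient_accuracy=tolerance_accuracy(gold, pred, config.sufficient_margin, n_classes, **sem),
        balanced_accuracy=float(np.nanmean(rec)),
        per_class_recall=[None if np.isnan(r) else float(r) for r in rec],
        confusion_matrix=confusion_matrix(gold, pred, n_classes).tolist(),
        config=config,
    )


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa for agreement among m raters over categorical ratings.

    Parameters
    ----------
    ratings : (n_subjects, n_categories) integer array
        ``ratings[i, j]`` = number of raters assigning subject i to category
        j.  Every row must sum to the same rater count m ≥ 2.
    """
    tab = np.asarray(ratings, dtype=np.float64)
    if tab.ndim != 2 or tab.shape[0] < 1:
        raise ValueError("ratings must be a (subjects, categories) matrix")
    m = tab.sum(axis=1)
    if not np.all(m == m[0]):
        raise ValueError("every subject must be rated by the same number of raters")
    m = float(m[0])
    if m < 2:
        raise ValueError("Fleiss' kappa requires at least 2 raters")
    n = tab.shape[0]
    p_j = tab.sum(axis=0) / (n * m)                       # category prevalences
    P_i = (np.sum(tab * (tab - 1), axis=1)) / (m * (m - 1))  # per-subject agreement
    P_bar = P_i.mean()
    P_e = float(np.sum(p_j**2))
    if P_e == 1.0:  # all ratings in one category: observed = chance = 1
        return 1.0
    return float((P_bar - P_e) / (1 - P_e))


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann–Whitney U test between two samples.

    Returns ``(U_a, p_two_sided)`` where ``U_a`` is the rank-sum U statistic
    of the first group with midrank ties.  The p-value is computed by exact
    enumeration when both samples have n ≤ 8 and no ties occur, otherwise by
    the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = _scipy_stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def subgroup_compare(
    results: pd.DataFrame,
    gold: pd.DataFrame,
    grouping: str,
    scale: str = "monk",
    n_classes: int = 10,
    margin: float = 0.10,
    variable: str = "correct",
) -> dict:
    """Compare per-image classification quality between two subgroups.

    ``results`` needs columns image_id, region, and a class column named after
    the scale; ``gold`` needs image_id, region, scale, class, and (for the
    image_type grouping) an image_type column.  ``grouping`` is one of
    ``body_site`` (arm vs face), ``image_type`` (values of the gold table's
    image_type column), or ``light_vs_dark`` (gold class in the lighter half
    of the scale vs the darker half).  The compared per-image variable is the
    tolerance-correctness indicator (default) or the absolute class deviation
    (``variable="deviation"``).
    """
    g = gold[gold["scale"] == scale]
    merged = results.merge(g, on=["image_id", "region"], suffixes=("", "_gold"))
    merged = merged.dropna(subset=[scale])
    pred = merged[scale].astype(int).to_numpy()
    gold_cls = merged["class"].astype(int).to_numpy()
    if variable == "correct":
        values = pair_correct(gold_cls, pred, margin, n_classes).astype(float)
    elif variable == "deviation":
        values = np.abs(pred - gold_cls).astype(float)
    else:
        raise ValueError(f"unknown comparison variable {variable!r}")

    if grouping == "body_site":
        in_a = merged["region"].to_numpy() == "arm"
        names = ("arm", "face")
    elif grouping == "image_type":
        types = sorted(merged["image_type"].unique())
        if len(types) != 2:
            raise ValueError(f"image_type grouping needs exactly 2 types, got {types}")
        in_a = merged["image_type"].to_numpy() == types[0]
        names = tuple(types)
    elif grouping == "light_vs_dark":
        in_a = gold_cls <= n_classes // 2
        names = (f"classes 1-{n_classes // 2}", f"classes {n_classes // 2 + 1}-{n_classes}")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    va, vb = values[in_a], values[~in_a]
    report = {
        "grouping": grouping,
        "scale": scale,
        "variable": variable,
        "groups": list(names),
        "n": [int(va.size), int(vb.size)],
        "accuracy": [
            float(pair_correct(gold_cls[in_a], pred[in_a], margin, n_classes).mean()) if va.size else None,
            float(pair_correct(gold_cls[~in_a], pred[~in_a], margin, n_classes).mean()) if vb.size else None,
        ],
    }
    if va.size == 0 or vb.size == 0:
        report.update({"U": None, "p": None, "note": "not computable: a group is empty"})
        return report
    U, p = mann_whitney(va, vb)
    report.update({"U": U, "p": p})
    return report
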