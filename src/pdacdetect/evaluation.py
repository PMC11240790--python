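"""Detection and segmentation metrics.

Two complementary case-level criteria are reported:

* localization — a tumor case counts as localized when the predicted
  tumor mask shares at least one voxel with the ground truth;
* classification — the case score is the maximum voxel of the (ensemble)
  tumor probability map, thresholded at the operating point (default 0.61).

``f1_paper`` is the arithmetic mean of precision and recall — a
non-standard definition retained under this explicit name so it is never
mistaken for the usual harmonic-mean F1, reported alongside as
``f1_harmonic``.
Mean Dice is averaged over tumor-positive cases only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CaseOutcome", "MetricsReport", "dice", "confusion_metrics",
           "roc_auc", "roc_curve_table", "localization_hit", "evaluate_cohort",
           "f1_paper"]


@dataclass
class CaseOutcome:
    case_id: str
    truth: bool
    score: float
    call: bool
    localization_hit: bool | None = None
    tumor_dsc: float | None = None
    tumor_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.truth:
            self.localization_hit = None


@dataclass
class MetricsReport:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1_paper: float | None
    f1_harmonic: float | None
    accuracy: float
    auroc: float | None
    mean_dice: float | None
    sd_dice: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    localization_rate: float | None = None
    subgroups: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "subgroups"}
        d["subgroups"] = {k: v.to_dict() for k, v in self.subgroups.items()}
        return d


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); both masks empty -> 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def f1_paper(precision: float, sensitivity: float) -> float:
    """Arithmetic mean of precision and recall (non-standard F1 variant)."""
    return 0.5 * (precision + sensitivity)


def localization_hit(pred_mask: np.ndarray, gt_tumor: np.ndarray) -> bool:
    """True iff predicted and ground-truth tumor masks share >= 1 voxel."""
    pred_mask = np.asarray(pred_mask).astype(bool)
    gt_tumor = np.asarray(gt_tumor).astype(bool)
    if pred_mask.shape != gt_tumor.shape:
        raise ValueError("mask shapes differ")
    return bool((pred_mask & gt_tumor).any())


def roc_auc(scores, truths) -> float:
    """AUROC by the Mann–Whitney rank formula (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    n_pos = int(truths.sum())
    n_neg = int((~truths).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    pos = scores[truths]
    neg = scores[~truths]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (n_pos * n_neg))


def roc_curve_table(scores, truths) -> pd.DataFrame:
    """Threshold sweep: one row (threshold, tpr, fpr) per distinct score.

    Thresholds are inclusive (call positive when score >= threshold); the
    table brackets the sweep with a threshold above every score so the
    curve runs from (0,0) to (1,1).  Trapezoidal integration of this table
    equals :func:`roc_auc` exactly.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    n_pos = int(truths.sum())
    n_neg = int((~truths).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc curve needs both classes present")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for t in thresholds:
        calls = scores >= t
        rows.append({
            "threshold": t,
            "tpr": int((calls & truths).sum()) / n_pos,
            "fpr": int((calls & ~truths).sum()) / n_neg,
        })
    return pd.DataFrame(rows)


def confusion_metrics(outcomes: list[CaseOutcome], threshold: float | None = None) -> MetricsReport:
    """Confusion-matrix metrics over case outcomes.

    When ``threshold`` is given, calls are recomputed as
    ``score >= threshold``; otherwise the stored calls are used.
    Degenerate metrics (no positives / no negatives / no calls) are
    reported as None, never silently 0.
    """
    if not outcomes:
        raise ValueError("empty outcome list")
    truths = np.array([o.truth for o in outcomes])
    if threshold is not None:
        calls = np.array([o.score >= threshold for o in outcomes])
    else:
        calls = np.array([o.call for o in outcomes])
    tp = int((calls & truths).sum())
    fp = int((calls & ~truths).sum())
    tn = int((~calls & ~truths).sum())
    fn = int((~calls & truths).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    prec = tp / (tp + fp) if (tp + fp) else None
    f1p = f1_paper(prec, sens) if (prec is not None and sens is not None) else None
    f1h = (2 * prec * sens / (prec + sens)
           if (prec is not None and sens is not None and prec + sens > 0) else None)
    acc = (tp + tn) / len(outcomes)
    dscs = [o.tumor_dsc for o in outcomes if o.truth and o.tumor_dsc is not None]
    # localization is scored among detected (called-positive) tumor cases
    hits = [o.localization_hit for o, c in zip(outcomes, calls)
            if o.truth and c and o.localization_hit is not None]
    try:
        auroc = roc_auc([o.score for o in outcomes], truths)
    except ValueError:
        auroc = None
    return MetricsReport(
        sensitivity=sens, specificity=spec, precision=prec,
        f1_paper=f1p, f1_harmonic=f1h, accuracy=acc, auroc=auroc,
        mean_dice=float(np.mean(dscs)) if dscs else None,
        sd_dice=float(np.std(dscs)) if dscs else None,
        tp=tp, fp=fp, tn=tn, fn=fn,
        localization_rate=float(np.mean(hits)) if hits else None,
    )


def evaluate_cohort(
    outcomes: list[CaseOutcome],
    threshold: float = 0.61,
    subgroup_diameter_mm: float | None = 20.0,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Cohort report with a small-tumor subgroup and the ROC curve table.

    The subgroup mirrors the "small tumors versus the full control set"
    construction: tumor cases with diameter below the cutoff plus every
    control case.
    """
    if not outcomes:
        raise ValueError("empty cohort")
    report = confusion_metrics(outcomes, threshold=threshold)
    if subgroup_diameter_mm is not None:
        sub = [
            o for o in outcomes
            if (not o.truth)
            or (o.tumor_diameter_mm is not None and o.tumor_diameter_mm < subgroup_diameter_mm)
        ]
        if any(o.truth for o in sub):
            key = f"lt_{subgroup_diameter_mm:g}mm_vs_controls"
            report.subgroups[key] = confusion_metrics(sub, threshold=threshold)
    curve = roc_curve_table([o.score for o in outcomes], [o.truth for o in outcomes])
    return report, curve
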