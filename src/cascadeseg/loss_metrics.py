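"""Class-imbalance-adaptive cross-entropy and volumetric overlap metrics.

The loss weights each class c by w_c = 1 / ln(t + P_c), where P_c is the
class's pixel proportion in the training set and t > 1 is a hyper-parameter
(default 1.02); weights are clamped to [1, 50].  Rare classes (tumor pixels
are a tiny fraction of an abdominal CT) therefore receive weights near the
upper clamp while the background stays near 1.

Evaluation uses, per foreground class and case,
  Dice  = 2*TP / (2*TP + FP + FN),
  VOE   = 1 - TP / (TP + FP + FN)            (Jaccard complement),
  RVD   = FP / (TP + FN)                      (unsigned form), and
  signed RVD = (TP + FP) / (TP + FN) - 1      (negative = under-segmentation).
Summary tables report the signed RVD, which is what makes under-segmented
runs show negative volume differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_T = 1.02
DEFAULT_CLAMP = (1.0, 50.0)
N_CLASSES = 3
_EPS = 1e-12


@dataclass(frozen=True)
class ClassWeights:
    w: np.ndarray           # (3,) background, liver, tumor
    t: float
    proportions: np.ndarray
    clamp: tuple[float, float] = DEFAULT_CLAMP

    def __post_init__(self):
        lo, hi = self.clamp
        if np.any(self.w < lo - 1e-9) or np.any(self.w > hi + 1e-9):
            raise ValueError("weights outside clamp interval")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class CaseMetrics:
    case_id: str
    dice: dict[int, float]
    voe: dict[int, float]
    rvd: dict[int, float]
    rvd_signed: dict[int, float]
    pattern: str = "none"


def class_proportions(masks) -> np.ndarray:
    """Pixel proportion of each class over one mask or a list of masks."""
    if isinstance(masks, np.ndarray):
        masks = [masks]
    masks = [np.asarray(getattr(m, "labels", m)) for m in masks]
    total = sum(m.size for m in masks)
    if total == 0:
        raise ValueError("no pixels in input masks")
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    for m in masks:
        counts += np.bincount(m.ravel().astype(np.int64), minlength=N_CLASSES)[:N_CLASSES]
    return counts / total


def adaptive_weights(proportions: np.ndarray, t: float = DEFAULT_T,
                     clamp: tuple[float, float] = DEFAULT_CLAMP) -> ClassWeights:
    """w_c = 1 / ln(t + P_c), clamped into [clamp[0], clamp[1]]."""
    if t <= 1.0:
        raise ValueError(f"t must be > 1 so ln(t + P) > 0 for all P >= 0; got {t}")
    p = np.asarray(proportions, dtype=np.float64)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must be non-negative and sum to 1")
    raw = 1.0 / np.log(t + p)
    return ClassWeights(np.clip(raw, *clamp), t, p, clamp)


def weighted_cross_entropy(probs: np.ndarray, truth: np.ndarray,
                           weights: ClassWeights | np.ndarray | None = None) -> float:
    """Mean per-pixel weighted cross-entropy of probability maps vs labels.

    probs: (..., C, H, W) on the per-pixel simplex; truth: (..., H, W) ints.
    Predicted probabilities are floored at 1e-12 so degenerate predictions
    yield a large finite loss rather than NaN.
    """
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth)
    if probs.ndim == 3:
        probs, truth = probs[None], truth[None]
    n, c = probs.shape[:2]
    if truth.shape != (n,) + probs.shape[2:]:
        raise ValueError(f"truth shape {truth.shape} incompatible with probs")
    w = np.ones(c) if weights is None else (
        weights.w if isinstance(weights, ClassWeights) else np.asarray(weights))
    pt = np.take_along_axis(probs, truth[:, None], axis=1)[:, 0]
    wpix = w[truth]
    return float(-(wpix * np.log(np.maximum(pt, _EPS))).mean() * 1.0)


def confusion(pred, truth, class_id: int) -> ConfusionCounts:
    """TP/FP/FN pixel counts for one class."""
    p = np.asarray(getattr(pred, "labels", pred))
    t = np.asarray(getattr(truth, "labels", truth))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape}, truth {t.shape}")
    pm, tm = p == class_id, t == class_id
    return ConfusionCounts(tp=int((pm & tm).sum()),
                           fp=int((pm & ~tm).sum()),
                           fn=int((~pm & tm).sum()))


def dice(counts: ConfusionCounts) -> float:
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 1.0 if denom == 0 else 2.0 * counts.tp / denom


def voe(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp + counts.fn
    return 0.0 if denom == 0 else 1.0 - counts.tp / denom


def rvd(counts: ConfusionCounts) -> float:
    """Unsigned form FP / (TP + FN); 0 when both volumes are empty."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return 0.0 if counts.fp == 0 else float("inf")
    return counts.fp / denom


def rvd_signed(counts: ConfusionCounts) -> float:
    """(|pred| - |truth|) / |truth|; negative means under-segmentation."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return 0.0 if counts.fp == 0 else float("inf")
    return (counts.tp + counts.fp) / denom - 1.0


def dice_masks(pred, truth, class_id: int) -> float:
    return dice(confusion(pred, truth, class_id))


def case_metrics(pred, truth, case_id: str = "case",
                 pattern: str = "none",
                 classes: tuple[int, ...] = (1, 2)) -> CaseMetrics:
    out = CaseMetrics(case_id, {}, {}, {}, {}, pattern)
    for c in classes:
        counts = confusion(pred, truth, c)
        out.dice[c] = dice(counts)
        out.voe[c] = voe(counts)
        out.rvd[c] = rvd(counts)
        out.rvd_signed[c] = rvd_signed(counts)
    return out


CLASS_NAMES = {1: "liver", 2: "tumor"}


def metrics_frame(cases: list[CaseMetrics]) -> pd.DataFrame:
    rows = []
    for cm in cases:
        row: dict = {"case": cm.case_id, "pattern": cm.pattern}
        for c, name in CLASS_NAMES.items():
            if c in cm.dice:
                row[f"dice_{name}"] = cm.dice[c]
                row[f"voe_{name}"] = cm.voe[c]
                row[f"rvd_{name}"] = cm.rvd_signed[c]
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_metrics(cases: list[CaseMetrics],
                      group_by_pattern: bool = True) -> pd.DataFrame:
    """Unweighted per-case means, overall and (optionally) per pattern."""
    df = metrics_frame(cases)
    value_cols = [c for c in df.columns if c not in ("case", "pattern")]
    overall = df[value_cols].mean().to_frame().T
    overall.insert(0, "pattern", "overall")
    overall.insert(1, "n_cases", len(df))
    if not group_by_pattern:
        return overall.reset_index(drop=True)
    per = (df.groupby("pattern")[value_cols].mean().reset_index())
    per.insert(1, "n_cases", df.groupby("pattern").size().values)
    return pd.concat([overall, per], ignore_index=True)
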