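"""ROC-based diagnostic performance of conspicuity metrics.

For each quantitative or ordinal descriptor the package reports the AUC with
a bootstrap CI, the classification threshold that maximizes the Youden index
J = sensitivity + specificity - 1, confusion metrics at that threshold, and
Fagan post-test probabilities from the likelihood ratios

    LR+ = sens / (1 - spec),   LR- = (1 - sens) / spec,
    post-test odds = pre-test odds x LR.

Scores are direction-normalized so that *higher* always indicates malignancy;
%RSD, where malignancy shows lower (wash-out) values, is negated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .records import (
    CONSPICUITY_RANK,
    PATTERN_RANK,
    CohortManifest,
    Histology,
    Pattern,
)

__all__ = [
    "DiagnosticsError",
    "DiagnosticSummary",
    "roc_auc",
    "youden_threshold",
    "confusion_metrics",
    "fagan_posttest",
    "auc_ci",
    "evaluate_all",
    "summaries_to_frame",
]

HIGHER_IS_MALIGNANT = "higher_is_malignant"
LOWER_IS_MALIGNANT = "lower_is_malignant"


class DiagnosticsError(ValueError):
    """Raised for degenerate score/label inputs."""


@dataclass(frozen=True)
class DiagnosticSummary:
    """Tables-3/4-style row: one metric, one comparison."""

    metric_name: str
    comparison: str          # "benign_vs_malignant" | "bpe_vs_malignant"
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float       # percent
    specificity: float       # percent
    accuracy: float          # percent
    lr_pos: float
    lr_neg: float
    posttest_p_malignancy: float   # percent
    posttest_p_benignity: float    # percent
    direction: str
    n_negative: int = 0
    n_positive: int = 0


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DiagnosticsError("scores and labels must be equal-length 1-D")
    if not np.all(np.isfinite(scores)):
        raise DiagnosticsError("scores must be finite")
    if labels.all() or not labels.any():
        raise DiagnosticsError("both classes must be present")
    return scores, labels


def _orient(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == HIGHER_IS_MALIGNANT:
        return scores
    if direction == LOWER_IS_MALIGNANT:
        return -scores
    raise DiagnosticsError(f"unknown direction {direction!r}")


def roc_auc(scores, labels, direction: str = HIGHER_IS_MALIGNANT) -> float:
    """AUC as the Mann-Whitney probability estimate (ties count 1/2)."""
    scores, labels = _validate(scores, labels)
    return float(roc_auc_score(labels, _orient(scores, direction)))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus -inf and +inf."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _rates(scores: np.ndarray, labels: np.ndarray,
           threshold: float) -> tuple[float, float, float]:
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    sens = tp / int(labels.sum())
    spec = tn / int((~labels).sum())
    acc = (tp + tn) / labels.size
    return sens, spec, acc


def youden_threshold(
    scores, labels, direction: str = HIGHER_IS_MALIGNANT
) -> tuple[float, float, float]:
    """Threshold maximizing J over all candidate cutpoints.

    Classification is ``score >= threshold -> positive`` after direction
    normalization; J ties resolve to the lowest qualifying threshold
    (favoring sensitivity).  Returns ``(threshold, sensitivity, specificity)``
    with the rates in percent.
    """
    scores, labels = _validate(scores, labels)
    oriented = _orient(scores, direction)
    best = None
    for thr in _candidate_thresholds(oriented):
        sens, spec, _ = _rates(oriented, labels, thr)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    if direction == LOWER_IS_MALIGNANT:
        thr = -thr
    return float(thr), 100.0 * sens, 100.0 * spec


def confusion_metrics(
    scores, labels, threshold: float, direction: str = HIGHER_IS_MALIGNANT
) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy (percent) at a fixed threshold."""
    scores, labels = _validate(scores, labels)
    oriented = _orient(scores, direction)
    thr = -threshold if direction == LOWER_IS_MALIGNANT else threshold
    sens, spec, acc = _rates(oriented, labels, thr)
    return 100.0 * sens, 100.0 * spec, 100.0 * acc


def fagan_posttest(
    pretest_p: float, sensitivity: float, specificity: float
) -> tuple[float, float]:
    """Fagan-nomogram post-test probabilities, in percent.

    ``posttest_p_malignancy`` is the probability of malignancy after a
    positive test (via LR+); ``posttest_p_benignity`` is the probability of
    benignity after a negative test, i.e. 1 minus the post-test probability
    of malignancy under LR-.  A perfectly specific test (spec == 1) gives an
    infinite LR+ and a post-test probability of 100%.
    """
    if not 0.0 < pretest_p < 1.0:
        raise DiagnosticsError("pretest probability must be in (0, 1)")
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise DiagnosticsError("sensitivity/specificity must be in [0, 1]")
    pre_odds = pretest_p / (1.0 - pretest_p)
    if specificity == 1.0:
        post_pos = 100.0
    else:
        lr_pos = sensitivity / (1.0 - specificity)
        odds = pre_odds * lr_pos
        post_pos = 100.0 * odds / (1.0 + odds)
    if specificity == 0.0:
        post_neg_malignancy = 1.0  # LR- infinite: a negative test is certain malignancy
    else:
        lr_neg = (1.0 - sensitivity) / specificity
        odds = pre_odds * lr_neg
        post_neg_malignancy = odds / (1.0 + odds)
    post_benignity = 100.0 * (1.0 - post_neg_malignancy)
    return post_pos, post_benignity


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """(LR+, LR-) from fractional sensitivity/specificity; inf where undefined."""
    lr_pos = np.inf if specificity == 1.0 else sensitivity / (1.0 - specificity)
    lr_neg = np.inf if specificity == 0.0 else (1.0 - sensitivity) / specificity
    return float(lr_pos), float(lr_neg)


def auc_ci(
    scores, labels, direction: str = HIGHER_IS_MALIGNANT,
    n_boot: int = 2000, seed: int = 0, level: float = 0.95,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC, deterministic per seed."""
    scores, labels = _validate(scores, labels)
    if n_boot < 200:
        raise DiagnosticsError("n_boot must be >= 200")
    if int(labels.sum()) < 2 or int((~labels).sum()) < 2:
        raise DiagnosticsError("each class needs >= 2 members for the bootstrap")
    oriented = _orient(scores, direction)
    pos = oriented[labels]
    neg = oriented[~labels]
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        bs = np.concatenate([bn, bp])
        bl = np.concatenate([np.zeros(bn.size, bool), np.ones(bp.size, bool)])
        if np.unique(bs).size == 1:
            stats[b] = 0.5
        else:
            stats[b] = roc_auc_score(bl, bs)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# Whole-manifest evaluation (Tables 3-4 layout)
# --------------------------------------------------------------------------

METRIC_DIRECTIONS = {
    "conspicuity_ordinal": HIGHER_IS_MALIGNANT,
    "pattern_ordinal": HIGHER_IS_MALIGNANT,
    "ce_early": HIGHER_IS_MALIGNANT,
    "ce_late": HIGHER_IS_MALIGNANT,
    "rsd": LOWER_IS_MALIGNANT,
}

COMPARISON_NEGATIVE_CLASS = {
    "benign_vs_malignant": (Histology.BENIGN,),
    "bpe_vs_malignant": (Histology.BPE,),
}


def _metric_scores(records, metric: str) -> np.ndarray:
    if metric == "conspicuity_ordinal":
        return np.array([CONSPICUITY_RANK[r.conspicuity] for r in records], float)
    if metric == "pattern_ordinal":
        return np.array([PATTERN_RANK[r.pattern] for r in records], float)
    if metric == "ce_early":
        return np.array([r.ce_early for r in records], float)
    if metric == "ce_late":
        return np.array([r.ce_late for r in records], float)
    if metric == "rsd":
        return np.array([r.rsd_percent for r in records], float)
    raise DiagnosticsError(f"unknown metric {metric!r}")


def evaluate_all(
    manifest: CohortManifest,
    metrics: Sequence[str] = tuple(METRIC_DIRECTIONS),
    comparisons: Sequence[str] = tuple(COMPARISON_NEGATIVE_CLASS),
    n_boot: int = 2000,
    seed: int = 0,
) -> list[DiagnosticSummary]:
    """One :class:`DiagnosticSummary` per metric x comparison.

    Non-enhancing lesions and B3 (uncertain-malignant-potential) lesions are
    excluded before analysis.  The Fagan pre-test probability is the
    malignant prevalence within the comparison subset.
    """
    eligible = [r for r in manifest.records
                if r.enhancing and r.histology is not Histology.B3]
    out: list[DiagnosticSummary] = []
    for comparison in comparisons:
        neg_classes = COMPARISON_NEGATIVE_CLASS[comparison]
        records = [r for r in eligible
                   if r.malignant or r.histology in neg_classes]
        labels = np.array([r.malignant for r in records], bool)
        if not labels.any() or labels.all():
            raise DiagnosticsError(
                f"{comparison}: a class is empty after exclusions")
        pretest = float(labels.mean())
        for metric in metrics:
            direction = METRIC_DIRECTIONS[metric]
            scores = _metric_scores(records, metric)
            auc = roc_auc(scores, labels, direction)
            ci = auc_ci(scores, labels, direction, n_boot=n_boot, seed=seed)
            thr, sens, spec = youden_threshold(scores, labels, direction)
            _, _, acc = confusion_metrics(scores, labels, thr, direction)
            lr_pos, lr_neg = likelihood_ratios(sens / 100.0, spec / 100.0)
            post_mal, post_ben = fagan_posttest(pretest, sens / 100.0,
                                                spec / 100.0)
            out.append(DiagnosticSummary(
                metric_name=metric,
                comparison=comparison,
                auc=auc,
                auc_ci=ci,
                threshold=thr,
                sensitivity=sens,
                specificity=spec,
                accuracy=acc,
                lr_pos=lr_pos,
                lr_neg=lr_neg,
                posttest_p_malignancy=post_mal,
                posttest_p_benignity=post_ben,
                direction=direction,
                n_negative=int((~labels).sum()),
                n_positive=int(labels.sum()),
            ))
    return out


def summaries_to_frame(summaries: Sequence[DiagnosticSummary]) -> pd.DataFrame:
    """Render summaries as a tidy DataFrame (one row per metric x comparison)."""
    rows = []
    for s in summaries:
        rows.append({
            "comparison": s.comparison,
            "metric": s.metric_name,
            "n_negative": s.n_negative,
            "n_positive": s.n_positive,
            "auc": s.auc,
            "auc_ci_lo": s.auc_ci[0],
            "auc_ci_hi": s.auc_ci[1],
            "threshold": s.threshold,
            "sensitivity_pct": s.sensitivity,
            "specificity_pct": s.specificity,
            "accuracy_pct": s.accuracy,
            "lr_pos": s.lr_pos,
            "lr_neg": s.lr_neg,
            "posttest_p_malignancy_pct": s.posttest_p_malignancy,
            "posttest_p_benignity_pct": s.posttest_p_benignity,
        })
    return pd.DataFrame(rows)
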