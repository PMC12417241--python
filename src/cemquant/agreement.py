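"""Conspicuity grading and inter-rater / inter-modality agreement.

Conspicuity is the ordinal BI-RADS CEM descriptor of lesion enhancement
relative to background parenchymal enhancement (BPE): *low* for enhancement
comparable to BPE, *high* for enhancement much greater than BPE, *moderate*
in between.  For simulated readers the verbal scale is operationalised as
ratio thresholds on lesion CE over a BPE reference CE.

Agreement statistics:

* Kendall's coefficient of concordance W (tie-corrected) across >= 2 raters
  of ordinal ratings, in [0, 1];
* Cohen's unweighted kappa between two categorical label sets, in [-1, 1],
  including a one-vs-rest collapse for per-class agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import cohen_kappa_score

from .records import Conspicuity

__all__ = [
    "AgreementError",
    "AgreementResult",
    "grade_conspicuity",
    "kendall_w",
    "cohen_kappa",
    "per_class_kappa",
]


class AgreementError(ValueError):
    """Raised for degenerate or malformed rating inputs."""


@dataclass(frozen=True)
class AgreementResult:
    statistic: str           # "kendall_w" | "cohen_kappa"
    value: float
    n_items: int
    n_raters_or_pair: int


def grade_conspicuity(
    lesion_ce: float,
    bpe_ce: float,
    ratio_thresholds: tuple[float, float] = (1.5, 3.0),
) -> Conspicuity:
    """Map a lesion-to-BPE contrast ratio onto the ordinal conspicuity scale.

    With ``r = lesion_ce / bpe_ce`` and thresholds ``(t_mod, t_high)``:
    r < 1 -> none (sub-BPE enhancement is not called a lesion),
    1 <= r < t_mod -> low, t_mod <= r < t_high -> moderate, r >= t_high -> high.
    The thresholds are simulator conventions, not published constants.
    """
    if bpe_ce <= 0:
        raise AgreementError(f"BPE reference CE must be positive, got {bpe_ce}")
    t_mod, t_high = ratio_thresholds
    if not t_mod < t_high:
        raise AgreementError("thresholds must satisfy t_mod < t_high")
    r = lesion_ce / bpe_ce
    if r < 1.0:
        return Conspicuity.NONE
    if r < t_mod:
        return Conspicuity.LOW
    if r < t_high:
        return Conspicuity.MODERATE
    return Conspicuity.HIGH


def kendall_w(ratings: np.ndarray) -> AgreementResult:
    """Kendall's W over an ``items x raters`` ordinal matrix, tie-corrected.

    W = 12 S / (m^2 (n^3 - n) - m T) where S is the sum of squared deviations
    of item rank sums, m the number of raters, n the number of items, and
    T = sum over raters of sum over tie groups of (t^3 - t).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise AgreementError("ratings must be a 2-D items x raters matrix")
    n, m = ratings.shape
    if n < 2 or m < 2:
        raise AgreementError("need >= 2 items and >= 2 raters")
    ranks = np.empty_like(ratings)
    tie_term = 0.0
    for j in range(m):
        col = ratings[:, j]
        ranks[:, j] = rankdata(col)          # average ranks for ties
        _, counts = np.unique(col, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        raise AgreementError(
            "degenerate ratings: every rater gives a constant rating; W undefined")
    rank_sums = ranks.sum(axis=1)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    w = 12.0 * s / denom
    return AgreementResult("kendall_w", float(np.clip(w, 0.0, 1.0)), n, m)


def _as_labels(x: Sequence) -> np.ndarray:
    return np.asarray([getattr(v, "value", v) for v in x], dtype=object)


def cohen_kappa(
    labels_a: Sequence,
    labels_b: Sequence,
    categories: Optional[Sequence] = None,
) -> AgreementResult:
    """Unweighted Cohen's kappa = (p_o - p_e) / (1 - p_e) for paired labels."""
    a, b = _as_labels(labels_a), _as_labels(labels_b)
    if len(a) != len(b):
        raise AgreementError("paired label vectors must have equal length")
    if len(a) == 0:
        raise AgreementError("empty label vectors")
    cats = (_as_labels(categories) if categories is not None
            else np.unique(np.concatenate([a, b])))
    # p_e == 1 happens iff both raters use a single (common) category.
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1 and a[0] == b[0]:
        raise AgreementError("chance agreement is 1; kappa undefined")
    value = cohen_kappa_score(a, b, labels=list(cats))
    return AgreementResult("cohen_kappa", float(value), len(a), 2)


def per_class_kappa(
    labels_a: Sequence,
    labels_b: Sequence,
    target_class,
) -> AgreementResult:
    """Binary kappa after one-vs-rest collapse onto ``target_class``."""
    target = getattr(target_class, "value", target_class)
    a = np.where(_as_labels(labels_a) == target, target, "other")
    b = np.where(_as_labels(labels_b) == target, target, "other")
    return cohen_kappa(a, b, categories=[target, "other"])
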