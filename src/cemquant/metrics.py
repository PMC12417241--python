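"""Quantitative enhancement metrics on recombined-view ROIs.

The contrast of a lesion against background parenchyma is

    CE = (Sa - Sb) / Sb

where ``Sa`` is the maximum pixel value inside the lesion ROI and ``Sb`` the
mean of a background ROI placed on non-enhancing (fatty) tissue.  The
two-timepoint kinetic statistic is the percent relative signal difference

    %RSD = 100 * (CE_late - CE_early) / CE_early

computed from the temporally early (CC) and late (MLO) recombined views, and
thresholded into progressive (> 10), plateau ([-10, 10], boundaries
inclusive) and wash-out (< -10) kinetic patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .records import Pattern

__all__ = [
    "MetricError",
    "ReaderMeasurement",
    "measure_roi",
    "compute_ce",
    "average_readers",
    "compute_rsd",
    "classify_pattern",
]

#: Plateau band half-width for kinetic pattern classification, in %RSD units.
PATTERN_THRESHOLD = 10.0


class MetricError(ValueError):
    """Raised for division-unsafe or malformed ROI statistics."""


@dataclass(frozen=True)
class ReaderMeasurement:
    """One reader's ROI statistics on one view.

    ``s_a`` is the lesion-ROI maximum, ``s_b`` the background-ROI mean and
    ``ce`` the derived contrast (Sa - Sb)/Sb.
    """

    reader_id: str
    view: str  # "early" | "late"
    s_a: float
    s_b: float

    def __post_init__(self) -> None:
        if self.view not in ("early", "late"):
            raise MetricError(f"unknown view {self.view!r}")
        if self.s_b <= 0:
            raise MetricError("background mean must be positive")

    @property
    def ce(self) -> float:
        return compute_ce(self.s_a, self.s_b)


def measure_roi(image: np.ndarray, lesion_mask: np.ndarray,
                background_mask: np.ndarray) -> tuple[float, float]:
    """Return ``(s_a, s_b)``: lesion-ROI maximum and background-ROI mean."""
    image = np.asarray(image, dtype=float)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not np.all(np.isfinite(image)):
        raise MetricError("image contains non-finite pixels")
    if not lesion_mask.any():
        raise MetricError("empty lesion mask")
    if not background_mask.any():
        raise MetricError("empty background mask")
    if (lesion_mask & background_mask).any():
        raise MetricError("lesion and background masks overlap")
    s_a = float(image[lesion_mask].max())
    s_b = float(image[background_mask].mean())
    if s_b == 0:
        raise MetricError("background mean is zero (division-unsafe)")
    return s_a, s_b


def compute_ce(s_a: float, s_b: float) -> float:
    """Contrast enhancement (Sa - Sb)/Sb; requires a positive background mean."""
    if s_b <= 0:
        raise MetricError(f"background mean must be positive, got {s_b}")
    return (s_a - s_b) / s_b


def average_readers(
    measurements: Iterable[ReaderMeasurement],
) -> tuple[float, float]:
    """Average per-reader CE values for each view -> ``(ce_early, ce_late)``.

    Averaging is over the derived CE values, not over the raw Sa/Sb.
    """
    by_view: dict[str, list[float]] = {"early": [], "late": []}
    for m in measurements:
        by_view[m.view].append(m.ce)
    for view, values in by_view.items():
        if not values:
            raise MetricError(f"no measurements for view {view!r}")
    return (
        float(np.mean(by_view["early"])),
        float(np.mean(by_view["late"])),
    )


def compute_rsd(ce_early: float, ce_late: float) -> float:
    """Percent relative signal difference 100 * (CE_late - CE_early)/CE_early.

    Undefined when ``ce_early == 0`` (a non-enhancing region): kinetics
    cannot be classified and the caller should record pattern ``none``.
    """
    if ce_early == 0:
        raise MetricError("%RSD undefined for ce_early == 0 (non-enhancing)")
    return 100.0 * (ce_late - ce_early) / ce_early


def classify_pattern(rsd_percent: float) -> Pattern:
    """Threshold %RSD into a kinetic pattern; the plateau band is inclusive."""
    if not math.isfinite(rsd_percent):
        raise MetricError(f"non-finite %RSD: {rsd_percent}")
    if rsd_percent > PATTERN_THRESHOLD:
        return Pattern.PROGRESSIVE
    if rsd_percent < -PATTERN_THRESHOLD:
        return Pattern.WASHOUT
    return Pattern.PLATEAU
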