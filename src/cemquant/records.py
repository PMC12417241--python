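"""Lesion-level records and cohort manifests.

A :class:`LesionRecord` is one lesion as it enters the statistical analysis:
its histopathology class, the consensus conspicuity grade (an ordinal
BI-RADS CEM descriptor of enhancement relative to background parenchymal
enhancement, BPE), the enhancement type (mass / non-mass), the reader-averaged
contrast values from the early and late recombined views, and the kinetic
pattern derived from the percent relative signal difference (%RSD).

Manifests round-trip losslessly through CSV (comma-separated, UTF-8, header
row, ``NA`` for nulls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

__all__ = [
    "Histology",
    "Conspicuity",
    "EnhancementType",
    "Pattern",
    "LesionRecord",
    "CohortManifest",
    "ManifestError",
    "write_manifest",
    "read_manifest",
]


class Histology(str, Enum):
    BPE = "BPE"            # background parenchymal enhancement (B1 / normal)
    BENIGN = "benign"      # B2
    B3 = "B3"              # uncertain malignant potential
    INVASIVE = "invasive"
    NON_INVASIVE = "non_invasive"


MALIGNANT_CLASSES = frozenset({Histology.INVASIVE, Histology.NON_INVASIVE})
NORMAL_BENIGN_CLASSES = frozenset({Histology.BPE, Histology.BENIGN})


class Conspicuity(str, Enum):
    NONE = "none"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


#: Ordinal rank of each conspicuity grade (used when scoring the descriptor).
CONSPICUITY_RANK = {
    Conspicuity.NONE: 0,
    Conspicuity.LOW: 1,
    Conspicuity.MODERATE: 2,
    Conspicuity.HIGH: 3,
}


class EnhancementType(str, Enum):
    MASS = "mass"
    NON_MASS = "non_mass"
    NONE = "none"


class Pattern(str, Enum):
    PROGRESSIVE = "progressive"
    PLATEAU = "plateau"
    WASHOUT = "washout"
    NONE = "none"


#: Ordinal rank used when scoring the kinetic pattern as a malignancy marker
#: (progressive < plateau < wash-out).
PATTERN_RANK = {
    Pattern.PROGRESSIVE: 1,
    Pattern.PLATEAU: 2,
    Pattern.WASHOUT: 3,
}


class ManifestError(ValueError):
    """Raised for malformed manifests or violated record invariants."""


@dataclass(frozen=True)
class LesionRecord:
    """One lesion with its consensus qualitative and quantitative descriptors.

    ``ce_early`` / ``ce_late`` are the reader-averaged contrast values
    (Sa − Sb)/Sb from the early and late recombined views; ``rsd_percent``
    is 100 × (CE_late − CE_early)/CE_early, null for non-enhancing lesions.
    """

    lesion_id: str
    histology: Histology
    conspicuity: Conspicuity
    enh_type: EnhancementType
    ce_early: float
    ce_late: float
    rsd_percent: Optional[float]
    pattern: Pattern
    size_mm: Optional[float] = None

    @property
    def malignant(self) -> bool:
        return self.histology in MALIGNANT_CLASSES

    @property
    def enhancing(self) -> bool:
        return self.pattern is not Pattern.NONE

    def validate(self) -> None:
        none_flags = {
            "pattern": self.pattern is Pattern.NONE,
            "conspicuity": self.conspicuity is Conspicuity.NONE,
            "enh_type": self.enh_type is EnhancementType.NONE,
            "rsd_percent": self.rsd_percent is None,
        }
        if len(set(none_flags.values())) != 1:
            raise ManifestError(
                f"{self.lesion_id}: non-enhancing flags disagree: {none_flags}"
            )
        if self.ce_early < -1 or self.ce_late < -1:
            raise ManifestError(f"{self.lesion_id}: contrast ratio below -1")


_COLUMNS = [
    "lesion_id",
    "histology",
    "malignant",
    "conspicuity",
    "enh_type",
    "ce_early",
    "ce_late",
    "rsd_percent",
    "pattern",
    "size_mm",
]


@dataclass
class CohortManifest:
    """A collection of lesion records plus provenance metadata."""

    records: list[LesionRecord]
    provenance: str = "simulated"  # "simulated" | "paper_fixture"
    seed: Optional[int] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.lesion_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate lesion_id in manifest")
        for r in self.records:
            r.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortManifest):
            return NotImplemented
        return self.records == other.records and self.provenance == other.provenance

    def subset(self, predicate) -> "CohortManifest":
        return CohortManifest(
            records=[r for r in self.records if predicate(r)],
            provenance=self.provenance,
            seed=self.seed,
            params=self.params,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "lesion_id": r.lesion_id,
                    "histology": r.histology.value,
                    "malignant": r.malignant,
                    "conspicuity": r.conspicuity.value,
                    "enh_type": r.enh_type.value,
                    "ce_early": r.ce_early,
                    "ce_late": r.ce_late,
                    "rsd_percent": r.rsd_percent,
                    "pattern": r.pattern.value,
                    "size_mm": r.size_mm,
                }
            )
        return pd.DataFrame(rows, columns=_COLUMNS)


def write_manifest(manifest: CohortManifest, path) -> None:
    """Write a manifest as CSV (UTF-8, header row, ``NA`` for nulls)."""
    frame = manifest.to_frame()
    # shortest round-trip float representation so read(write(m)) == m exactly
    frame.to_csv(path, index=False, na_rep="NA",
                 float_format=lambda v: repr(float(v)))


def _parse_record(row: pd.Series, line: int) -> LesionRecord:
    def opt_float(v):
        return None if pd.isna(v) else float(v)

    try:
        return LesionRecord(
            lesion_id=str(row["lesion_id"]),
            histology=Histology(row["histology"]),
            conspicuity=Conspicuity(row["conspicuity"]),
            enh_type=EnhancementType(row["enh_type"]),
            ce_early=float(row["ce_early"]),
            ce_late=float(row["ce_late"]),
            rsd_percent=opt_float(row["rsd_percent"]),
            pattern=Pattern(row["pattern"]),
            size_mm=opt_float(row["size_mm"]),
        )
    except (ValueError, KeyError, TypeError) as exc:
        raise ManifestError(f"line {line}: {exc}") from exc


def read_manifest(path, provenance: str = "simulated") -> CohortManifest:
    """Read a manifest CSV; raises :class:`ManifestError` with the offending line."""
    try:
        frame = pd.read_csv(path, keep_default_na=False, na_values=["NA"],
                            float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ManifestError(f"unreadable manifest CSV: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ManifestError(f"line 1: missing required columns {missing}")
    records = [
        _parse_record(row, line)
        for line, (_, row) in enumerate(frame.iterrows(), start=2)
    ]
    return CohortManifest(records=records, provenance=provenance)
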