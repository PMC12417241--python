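"""Cohort generation: stochastic simulation and a deterministic count fixture.

Two generators share the :class:`~cemquant.records.LesionRecord` schema:

``simulate_cohort``
    Draws lesions class-conditionally.  Early-view contrast (CE_early) is
    log-normal per histology class — strictly positive and right-skewed, with
    BPE ≈ benign < malignant locations — and the kinetic statistic %RSD is
    drawn from a per-class mixture over progressive / plateau / wash-out
    bands (benign and BPE lesions mostly progressive, cancers mostly plateau
    or wash-out).  Three simulated readers measure each lesion with
    multiplicative noise; the recorded metrics are the reader averages.

``build_paper_fixture``
    A deterministic 143-lesion cohort whose histology, conspicuity and
    kinetic-pattern margins — and every published joint count — reproduce
    the printed count structure of the study the package models.

``build_exclusion_fixture``
    The 237-candidate screening funnel (suboptimal quality, missing
    histopathology, not visualized on both views) that yields the 143
    analyzed lesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import grade_conspicuity
from .metrics import classify_pattern
from .records import (
    CohortManifest,
    Conspicuity,
    EnhancementType,
    Histology,
    LesionRecord,
    Pattern,
)

__all__ = [
    "ClassParams",
    "SimulationParams",
    "simulate_cohort",
    "build_paper_fixture",
    "build_exclusion_fixture",
    "DEFAULT_PARAMS",
]


# --------------------------------------------------------------------------
# Stochastic simulation
# --------------------------------------------------------------------------

#: %RSD bands the mixture draws from, matching the pattern thresholds.
RSD_BANDS = {
    Pattern.PROGRESSIVE: (10.0, 60.0),
    Pattern.PLATEAU: (-10.0, 10.0),
    Pattern.WASHOUT: (-60.0, -10.0),
}


@dataclass(frozen=True)
class ClassParams:
    """Per-histology-class generative parameters."""

    prevalence: float
    log_ce_mu: float          # log-scale location of CE_early
    log_ce_sigma: float       # log-scale spread of CE_early
    pattern_weights: tuple[float, float, float]  # progressive, plateau, washout
    p_nonenhancing: float = 0.0
    p_non_mass: float = 0.3   # enhancement type mix among enhancing lesions

    def validate(self, name: str) -> None:
        if self.log_ce_sigma <= 0:
            raise ValueError(f"{name}: log_ce_sigma must be > 0")
        if not math.isclose(sum(self.pattern_weights), 1.0, abs_tol=1e-9):
            raise ValueError(
                f"{name}: pattern mixture weights must sum to 1, "
                f"got {self.pattern_weights}"
            )
        if any(w < 0 for w in self.pattern_weights):
            raise ValueError(f"{name}: negative mixture weight")
        if not 0 <= self.p_nonenhancing <= 1:
            raise ValueError(f"{name}: p_nonenhancing outside [0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter set for a simulated cohort.

    Reader noise is a per-reader multiplicative log-normal factor applied to
    that reader's contrast measurements.  The factor is shared between the
    early and late views of a given reader — each reader draws one background
    ROI per examination, so their scaling bias carries to both views — which
    keeps each reader's %RSD equal to the lesion's true %RSD.
    """

    classes: dict[str, ClassParams]
    n_lesions: int = 143
    n_readers: int = 3
    reader_noise_sigma: float = 0.2
    bpe_reference_ce: float = 0.04    # typical BPE contrast the graders compare to
    conspicuity_thresholds: tuple[float, float] = (1.5, 3.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.n_readers < 1:
            raise ValueError("n_readers must be >= 1")
        if self.reader_noise_sigma < 0:
            raise ValueError("reader_noise_sigma must be >= 0")
        total = 0.0
        for name, cp in self.classes.items():
            cp.validate(name)
            total += cp.prevalence
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class prevalences must sum to 1, got {total}")


def _default_classes() -> dict[str, ClassParams]:
    # Locations: BPE ~ benign ~ median CE 0.04; malignant classes share a
    # higher location chosen from the equal-sigma log-normal AUC identity
    # AUC = Phi(dmu / (sigma * sqrt(2))), targeting 0.83 before reader noise.
    mu_benign = math.log(0.04)
    mu_malignant = mu_benign + 0.6746
    sigma = 0.5
    return {
        "BPE": ClassParams(48 / 143, mu_benign, sigma,
                           (54 / 76, 15 / 76, 7 / 76),
                           p_nonenhancing=0.0, p_non_mass=40 / 76),
        "benign": ClassParams(34 / 143, mu_benign, sigma,
                              (54 / 76, 15 / 76, 7 / 76),
                              p_nonenhancing=6 / 34, p_non_mass=40 / 76),
        "B3": ClassParams(4 / 143, math.log(0.05), sigma,
                          (0.5, 0.5, 0.0), p_nonenhancing=0.5, p_non_mass=0.0),
        "invasive": ClassParams(49 / 143, mu_malignant, sigma,
                                (10 / 48, 22 / 48, 16 / 48),
                                p_nonenhancing=1 / 49, p_non_mass=10 / 55),
        "non_invasive": ClassParams(8 / 143, mu_malignant, sigma,
                                    (1.0, 0.0, 0.0),
                                    p_nonenhancing=1 / 8, p_non_mass=10 / 55),
    }


DEFAULT_PARAMS = SimulationParams(classes=_default_classes())


def simulate_cohort(
    params: SimulationParams = DEFAULT_PARAMS,
    return_readers: bool = False,
):
    """Draw a stochastic cohort; reproducible for a fixed seed.

    With ``return_readers=True`` also returns a DataFrame of per-reader
    CE_early values and conspicuity grades (columns ``lesion_id``,
    ``reader_id``, ``ce_early``, ``grade``) for agreement analyses.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    class_names = list(params.classes)
    prevalences = np.array([params.classes[c].prevalence for c in class_names])
    prevalences = prevalences / prevalences.sum()

    t_mod, t_high = params.conspicuity_thresholds
    records: list[LesionRecord] = []
    reader_rows: list[dict] = []

    draws = rng.choice(len(class_names), size=params.n_lesions, p=prevalences)
    for i, ci in enumerate(draws):
        name = class_names[ci]
        cp = params.classes[name]
        lesion_id = f"sim-{i:04d}"
        if rng.random() < cp.p_nonenhancing:
            records.append(LesionRecord(
                lesion_id=lesion_id,
                histology=Histology(name),
                conspicuity=Conspicuity.NONE,
                enh_type=EnhancementType.NONE,
                ce_early=0.0, ce_late=0.0,
                rsd_percent=None, pattern=Pattern.NONE,
                size_mm=float(rng.integers(3, 40)),
            ))
            continue

        ce_true = float(rng.lognormal(cp.log_ce_mu, cp.log_ce_sigma))
        pattern_drawn = rng.choice(3, p=np.asarray(cp.pattern_weights))
        lo, hi = RSD_BANDS[list(RSD_BANDS)[pattern_drawn]]
        rsd = float(rng.uniform(lo, hi))

        # Per-reader multiplicative factors, shared across the two views.
        factors = np.exp(rng.normal(0.0, params.reader_noise_sigma,
                                    size=params.n_readers))
        ce_early_readers = ce_true * factors
        ce_early = float(ce_early_readers.mean())
        ce_late = ce_early * (1.0 + rsd / 100.0)
        pattern = classify_pattern(rsd)

        grade = grade_conspicuity(ce_early, params.bpe_reference_ce,
                                  (t_mod, t_high))
        if grade is Conspicuity.NONE:
            grade = Conspicuity.LOW  # an enhancing lesion is by definition >= BPE

        if return_readers:
            for r, ce_r in enumerate(ce_early_readers):
                g = grade_conspicuity(float(ce_r), params.bpe_reference_ce,
                                      (t_mod, t_high))
                if g is Conspicuity.NONE:
                    g = Conspicuity.LOW
                reader_rows.append({
                    "lesion_id": lesion_id,
                    "reader_id": f"R{r + 1}",
                    "ce_early": float(ce_r),
                    "grade": g.value,
                })

        enh = (EnhancementType.NON_MASS if rng.random() < cp.p_non_mass
               else EnhancementType.MASS)
        records.append(LesionRecord(
            lesion_id=lesion_id,
            histology=Histology(name),
            conspicuity=grade,
            enh_type=enh,
            ce_early=ce_early,
            ce_late=ce_late,
            rsd_percent=rsd,
            pattern=pattern,
            size_mm=float(rng.integers(3, 40)),
        ))

    manifest = CohortManifest(records=records, provenance="simulated",
                              seed=params.seed, params={"n": params.n_lesions})
    if return_readers:
        return manifest, pd.DataFrame(reader_rows)
    return manifest


# --------------------------------------------------------------------------
# Deterministic paper fixture
# --------------------------------------------------------------------------

# Per-histology allocation of the 143 analyzed lesions.  Rows are
# (histology, conspicuity, pattern, enh_type, count) for enhancing lesions;
# non-enhancing lesions are listed separately.  Margins and every published
# joint count are satisfied:
#   histology   BPE 48 | benign 34 | B3 4 | invasive 49 | non_invasive 8
#   conspicuity low 60 | moderate 64 | high 9 | none 10
#   pattern     progressive 72 | plateau 38 | washout 23 | none 10
#   enh type    mass 83 | non-mass 50 | none 10
# joint: low∩(BPE∪benign)=49; malignant∩(mod∪high)=44; high∩invasive=9 (all);
#   non_invasive∩moderate=6; non_invasive∩none=1; malignant∩none=2; B3∩none=2;
#   B3∩moderate=2; (BPE∪benign)∩none=6; normal/benign∩progressive=54;
#   malignant∩(plateau∪washout)=38.
# Cells beyond the published joints are a deterministic free allocation.
_FIXTURE_ENHANCING: dict[str, dict] = {
    "BPE": {
        "n": 48,
        "conspicuity": [("low", 30), ("moderate", 18)],
        "pattern": [("progressive", 34), ("plateau", 10), ("washout", 4)],
        "enh_type": [("non_mass", 26), ("mass", 22)],
    },
    "benign": {
        "n": 28,
        "conspicuity": [("low", 19), ("moderate", 9)],
        "pattern": [("progressive", 20), ("plateau", 5), ("washout", 3)],
        "enh_type": [("non_mass", 14), ("mass", 14)],
    },
    "B3": {
        "n": 2,
        "conspicuity": [("moderate", 2)],
        "pattern": [("progressive", 1), ("plateau", 1)],
        "enh_type": [("mass", 2)],
    },
    "invasive": {
        "n": 48,
        "conspicuity": [("low", 10), ("moderate", 29), ("high", 9)],
        "pattern": [("progressive", 10), ("plateau", 22), ("washout", 16)],
        "enh_type": [("non_mass", 9), ("mass", 39)],
    },
    "non_invasive": {
        "n": 7,
        "conspicuity": [("low", 1), ("moderate", 6)],
        "pattern": [("progressive", 7)],
        "enh_type": [("non_mass", 1), ("mass", 6)],
    },
}

# The ten non-enhancing lesions (per the published footnote): six benign,
# two B3, one invasive (tubular) and one non-invasive (DCIS).
_FIXTURE_NON_ENHANCING = [("benign", 6), ("B3", 2), ("invasive", 1),
                          ("non_invasive", 1)]

# Deterministic CE_early base level per conspicuity grade; a small
# index-proportional offset makes values distinct without overlapping grades.
_CE_BASE = {"low": (0.030, 0.0004), "moderate": (0.080, 0.0007),
            "high": (0.200, 0.0020)}
# Deterministic %RSD per pattern: base plus index-dependent offset, kept
# strictly inside the classification bands.
_RSD_RULE = {"progressive": (12.0, 1.1, 45.0), "plateau": (-9.0, 1.0, 18.0),
             "washout": (-12.0, -1.3, 45.0)}


def _expand(pairs: list[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for value, count in pairs:
        out.extend([value] * count)
    return out


def build_paper_fixture() -> CohortManifest:
    """Deterministic 143-lesion cohort reproducing the published counts.

    Raises ``AssertionError`` naming the violated constraint if the internal
    allocation table is inconsistent.
    """
    records: list[LesionRecord] = []
    idx = 0
    grade_counter: dict[str, int] = {}
    pattern_counter: dict[str, int] = {}

    for histology, spec in _FIXTURE_ENHANCING.items():
        consp = _expand(spec["conspicuity"])
        patt = _expand(spec["pattern"])
        enh = _expand(spec["enh_type"])
        assert len(consp) == spec["n"], (
            f"{histology}: conspicuity cells sum to {len(consp)}, want {spec['n']}")
        assert len(patt) == spec["n"], (
            f"{histology}: pattern cells sum to {len(patt)}, want {spec['n']}")
        assert len(enh) == spec["n"], (
            f"{histology}: enh_type cells sum to {len(enh)}, want {spec['n']}")
        for grade, pattern, enh_type in zip(consp, patt, enh):
            gi = grade_counter.get(grade, 0)
            grade_counter[grade] = gi + 1
            base, step = _CE_BASE[grade]
            ce_early = round(base + step * gi, 6)

            pi = pattern_counter.get(pattern, 0)
            pattern_counter[pattern] = pi + 1
            b, s, mod = _RSD_RULE[pattern]
            rsd = round(b + (s * pi) % mod * math.copysign(1.0, s), 4)
            ce_late = round(ce_early * (1.0 + rsd / 100.0), 8)

            records.append(LesionRecord(
                lesion_id=f"fx-{idx:03d}",
                histology=Histology(histology),
                conspicuity=Conspicuity(grade),
                enh_type=EnhancementType(enh_type),
                ce_early=ce_early,
                ce_late=ce_late,
                rsd_percent=rsd,
                pattern=Pattern(pattern),
                size_mm=float(5 + (idx % 30)),
            ))
            idx += 1

    for histology, count in _FIXTURE_NON_ENHANCING:
        for _ in range(count):
            records.append(LesionRecord(
                lesion_id=f"fx-{idx:03d}",
                histology=Histology(histology),
                conspicuity=Conspicuity.NONE,
                enh_type=EnhancementType.NONE,
                ce_early=0.0, ce_late=0.0,
                rsd_percent=None, pattern=Pattern.NONE,
                size_mm=float(5 + (idx % 30)),
            ))
            idx += 1

    manifest = CohortManifest(records=records, provenance="paper_fixture")
    _check_fixture(manifest)
    return manifest


def _count(manifest: CohortManifest, pred) -> int:
    return sum(1 for r in manifest.records if pred(r))


def _check_fixture(m: CohortManifest) -> None:
    """Assert every published marginal and joint count, naming the violation."""
    H, C, P = Histology, Conspicuity, Pattern
    checks: list[tuple[str, int, int]] = [
        ("total lesions", len(m), 143),
        ("histology BPE", _count(m, lambda r: r.histology is H.BPE), 48),
        ("histology benign", _count(m, lambda r: r.histology is H.BENIGN), 34),
        ("histology B3", _count(m, lambda r: r.histology is H.B3), 4),
        ("histology invasive", _count(m, lambda r: r.histology is H.INVASIVE), 49),
        ("histology non_invasive",
         _count(m, lambda r: r.histology is H.NON_INVASIVE), 8),
        ("conspicuity low", _count(m, lambda r: r.conspicuity is C.LOW), 60),
        ("conspicuity moderate",
         _count(m, lambda r: r.conspicuity is C.MODERATE), 64),
        ("conspicuity high", _count(m, lambda r: r.conspicuity is C.HIGH), 9),
        ("conspicuity none", _count(m, lambda r: r.conspicuity is C.NONE), 10),
        ("pattern progressive",
         _count(m, lambda r: r.pattern is P.PROGRESSIVE), 72),
        ("pattern plateau", _count(m, lambda r: r.pattern is P.PLATEAU), 38),
        ("pattern washout", _count(m, lambda r: r.pattern is P.WASHOUT), 23),
        ("pattern none", _count(m, lambda r: r.pattern is P.NONE), 10),
        ("low ∩ normal/benign",
         _count(m, lambda r: r.conspicuity is C.LOW
                and r.histology in (H.BPE, H.BENIGN)), 49),
        ("malignant ∩ moderate/high",
         _count(m, lambda r: r.malignant
                and r.conspicuity in (C.MODERATE, C.HIGH)), 44),
        ("high ∩ invasive",
         _count(m, lambda r: r.conspicuity is C.HIGH
                and r.histology is H.INVASIVE), 9),
        ("high ∩ non-invasive-or-benign",
         _count(m, lambda r: r.conspicuity is C.HIGH
                and r.histology is not H.INVASIVE), 0),
        ("non_invasive ∩ moderate",
         _count(m, lambda r: r.histology is H.NON_INVASIVE
                and r.conspicuity is C.MODERATE), 6),
        ("non_invasive ∩ none",
         _count(m, lambda r: r.histology is H.NON_INVASIVE
                and r.conspicuity is C.NONE), 1),
        ("malignant ∩ none",
         _count(m, lambda r: r.malignant and r.conspicuity is C.NONE), 2),
        ("B3 ∩ none",
         _count(m, lambda r: r.histology is H.B3
                and r.conspicuity is C.NONE), 2),
        ("B3 ∩ moderate",
         _count(m, lambda r: r.histology is H.B3
                and r.conspicuity is C.MODERATE), 2),
        ("normal/benign ∩ none",
         _count(m, lambda r: r.histology in (H.BPE, H.BENIGN)
                and r.conspicuity is C.NONE), 6),
        ("normal/benign ∩ progressive",
         _count(m, lambda r: r.histology in (H.BPE, H.BENIGN)
                and r.pattern is P.PROGRESSIVE), 54),
        ("malignant ∩ plateau/washout",
         _count(m, lambda r: r.malignant
                and r.pattern in (P.PLATEAU, P.WASHOUT)), 38),
    ]
    for name, got, want in checks:
        assert got == want, f"fixture constraint violated: {name}: {got} != {want}"
    for r in m.records:
        if r.enhancing:
            assert classify_pattern(r.rsd_percent) is r.pattern, (
                f"fixture constraint violated: %RSD/pattern mismatch {r.lesion_id}")


# --------------------------------------------------------------------------
# Exclusion funnel
# --------------------------------------------------------------------------

EXCLUSION_REASONS = ("suboptimal_quality", "missing_histopathology",
                     "not_visualized_both_views")
_EXCLUSION_COUNTS = {"suboptimal_quality": 16, "missing_histopathology": 29,
                     "not_visualized_both_views": 49}


def build_exclusion_fixture() -> tuple[CohortManifest, dict]:
    """Screening funnel: 237 candidates filtered in order to 143 survivors.

    Returns the surviving manifest plus a report with per-reason exclusion
    counts and the overall exclusion percentage (one decimal).
    """
    flags = ["ok"] * 143
    for reason, n in _EXCLUSION_COUNTS.items():
        flags.extend([reason] * n)
    n_candidates = len(flags)

    remaining = list(flags)
    report_counts: dict[str, int] = {}
    for reason in EXCLUSION_REASONS:   # filters applied in order
        before = len(remaining)
        remaining = [f for f in remaining if f != reason]
        report_counts[reason] = before - len(remaining)

    survivors = build_paper_fixture()
    assert len(survivors) == len(remaining), (
        f"exclusion fixture: {len(remaining)} survivors flagged but "
        f"{len(survivors)} records built")

    n_excluded = n_candidates - len(remaining)
    report = {
        "n_candidates": n_candidates,
        "n_survivors": len(remaining),
        "n_excluded": n_excluded,
        "excluded_percent": round(100.0 * n_excluded / n_candidates, 1),
        "reason_counts": report_counts,
    }
    return survivors, report
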