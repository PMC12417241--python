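"""End-to-end orchestration: cohort -> metrics -> evaluation -> report bundle.

Three modes share a :class:`RunConfig`:

* ``fixture``  — deterministic cohort reproducing the published count
  structure, run through the full statistical evaluation;
* ``simulate`` — stochastic cohort with three noisy readers, adding
  inter-reader agreement to the report;
* ``phantom``  — synthetic image pairs measured end-to-end on pixels,
  reporting programmed vs recovered contrast.

Each stage writes its artifact (CSV) before the next stage reads it, so a
run can be resumed from any intermediate, and identical config + seed give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import stats as st
from .cohort import (
    DEFAULT_PARAMS,
    SimulationParams,
    build_exclusion_fixture,
    simulate_cohort,
)
from .diagnostics import evaluate_all, summaries_to_frame
from .metrics import compute_ce, measure_roi
from .phantom import generate_phantom
from .records import (
    CONSPICUITY_RANK,
    CohortManifest,
    Histology,
    read_manifest,
    write_manifest,
)

__all__ = ["PipelineError", "RunConfig", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class RunConfig:
    mode: str = "fixture"            # fixture | simulate | phantom
    seed: int = 0
    out_dir: str = "cemquant_run"
    n_lesions: int = 143
    n_boot: int = 1000
    phantom_peaks: tuple[float, ...] = (0.05, 0.2, 0.5, 1.0)
    phantom_noise_scale: float = 0.01

    def validate(self) -> None:
        if self.mode not in ("fixture", "simulate", "phantom"):
            raise PipelineError(f"config: unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.seed is None:
            raise PipelineError("config: simulate mode requires a seed")


def load_config(path) -> RunConfig:
    """Read a flat key/value YAML config file into a :class:`RunConfig`."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise PipelineError("config: expected flat key/value mappings")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise PipelineError(f"config: unknown keys {sorted(unknown)}")
    if "phantom_peaks" in data:
        data["phantom_peaks"] = tuple(float(v) for v in data["phantom_peaks"])
    return RunConfig(**data)


def _pkg_version() -> str:
    try:
        return version("cemquant")
    except PackageNotFoundError:
        return "unknown"


def _association_report(manifest: CohortManifest) -> pd.DataFrame:
    """Association tests linking conspicuity, histology and the metrics."""
    enhancing = [r for r in manifest.records if r.enhancing]
    consp_rank = np.array([CONSPICUITY_RANK[r.conspicuity] for r in enhancing])
    ce_early = np.array([r.ce_early for r in enhancing])
    ce_late = np.array([r.ce_late for r in enhancing])
    rsd = np.array([r.rsd_percent for r in enhancing])
    malignant = np.array([r.malignant for r in enhancing])

    # conspicuity x malignancy contingency over the whole cohort (4 grades).
    grades = ["none", "low", "moderate", "high"]
    table = np.array([
        [sum(1 for r in manifest.records
             if r.conspicuity.value == g and not r.malignant) for g in grades],
        [sum(1 for r in manifest.records
             if r.conspicuity.value == g and r.malignant) for g in grades],
    ])
    rows = []
    chi = st.chi_square(table)
    rows.append(("conspicuity_x_malignant_chi2", chi.statistic, chi.p_value, chi.n))
    for name, values in (("ce_early", ce_early), ("ce_late", ce_late),
                         ("rsd", rsd)):
        tau = st.kendall_tau_b(consp_rank, values)
        rows.append((f"conspicuity_vs_{name}_tau_b", tau.statistic,
                     tau.p_value, tau.n))
        mw = st.mann_whitney(values[~malignant], values[malignant])
        rows.append((f"{name}_benign_bpe_vs_malignant_mann_whitney",
                     mw.statistic, mw.p_value, mw.n))
    frame = pd.DataFrame(rows, columns=["test", "statistic", "p_value", "n"])
    frame["p_holm"] = st.holm_correct(frame["p_value"].tolist())
    return frame


def _phantom_report(config: RunConfig) -> pd.DataFrame:
    rows = []
    for i, peak in enumerate(config.phantom_peaks):
        case = generate_phantom(
            peak_early=peak, peak_late=peak,
            noise_scale=config.phantom_noise_scale,
            seed=config.seed + i,
        )
        for view, img in (("early", case.early_image), ("late", case.late_image)):
            s_a, s_b = measure_roi(img, case.lesion_mask, case.background_mask)
            rows.append({
                "case": i, "view": view, "programmed_ce": peak,
                "measured_ce": compute_ce(s_a, s_b),
                "s_a": s_a, "s_b": s_b,
                "noise_scale": config.phantom_noise_scale,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages for ``config``; returns a dict of output paths/objects."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"cemquant {_pkg_version()}", f"mode: {config.mode}",
                 f"seed: {config.seed}"]
    outputs: dict = {"out_dir": str(out)}

    if config.mode == "phantom":
        try:
            report = _phantom_report(config)
        except Exception as exc:
            raise PipelineError(f"stage phantom_measurement failed: {exc}") from exc
        path = out / "phantom_report.csv"
        report.to_csv(path, index=False)
        outputs["phantom_report"] = str(path)
        log_lines.append(f"phantom cases: {len(config.phantom_peaks)}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        return outputs

    reader_table = None
    try:
        if config.mode == "fixture":
            manifest, excl = build_exclusion_fixture()
            pd.DataFrame(
                [{"reason": k, "n_excluded": v}
                 for k, v in excl["reason_counts"].items()]
            ).to_csv(out / "exclusion_report.csv", index=False)
            log_lines.append(
                f"exclusions: {excl['n_excluded']}/{excl['n_candidates']} "
                f"({excl['excluded_percent']}%) -> {excl['n_survivors']} analyzed")
            outputs["exclusion_report"] = excl
        else:
            params = SimulationParams(
                classes=DEFAULT_PARAMS.classes,
                n_lesions=config.n_lesions,
                seed=config.seed,
            )
            manifest, reader_table = simulate_cohort(params, return_readers=True)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage cohort failed: {exc}") from exc

    manifest_path = out / "manifest.csv"
    write_manifest(manifest, manifest_path)
    outputs["manifest"] = str(manifest_path)
    manifest = read_manifest(manifest_path, provenance=manifest.provenance)

    try:
        summaries = evaluate_all(manifest, n_boot=config.n_boot,
                                 seed=config.seed)
    except Exception as exc:
        raise PipelineError(f"stage diagnostics failed: {exc}") from exc
    diag = summaries_to_frame(summaries)
    diag_path = out / "diagnostic_summaries.csv"
    diag.to_csv(diag_path, index=False)
    outputs["diagnostics"] = str(diag_path)

    try:
        assoc = _association_report(manifest)
    except Exception as exc:
        raise PipelineError(f"stage association failed: {exc}") from exc
    assoc_path = out / "association_tests.csv"
    assoc.to_csv(assoc_path, index=False)
    outputs["association"] = str(assoc_path)

    if reader_table is not None and not reader_table.empty:
        try:
            grid = reader_table.pivot(index="lesion_id", columns="reader_id",
                                      values="grade")
            rank = grid.map(lambda g: {"none": 0, "low": 1, "moderate": 2,
                                       "high": 3}[g])
            w = agr.kendall_w(rank.to_numpy())
            pd.DataFrame([{
                "statistic": w.statistic, "value": w.value,
                "n_items": w.n_items, "n_raters": w.n_raters_or_pair,
            }]).to_csv(out / "agreement.csv", index=False)
            outputs["kendall_w"] = w.value
            log_lines.append(f"inter-reader conspicuity W: {w.value:.3f}")
        except Exception as exc:
            raise PipelineError(f"stage agreement failed: {exc}") from exc

    log_lines.append(f"lesions: {len(manifest)}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    outputs["summaries"] = summaries
    return outputs
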