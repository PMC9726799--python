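"""End-to-end orchestration: simulate -> preprocess -> select -> fit ->
evaluate, with reproducible artifacts and a content-hash manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .cascade import label_samples, run_cascade
from .cohort import CohortConfig, simulate_cohort
from .errors import ConfigurationError
from .evaluate import (evaluate_scorer, evaluation_report,
                       reference_marker_rows, timeline_report)
from .matrix import sheet_index
from .panels import MAX_PANEL_SIZE, panel_scores, select_best_panels
from .preprocess import preprocess_chain, qc_report

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either ``matrix_path``/``sheet_path`` point at existing inputs, or a
    cohort is simulated from ``cohort`` (whose seed is overridden by
    ``seed`` so that one number controls the whole run).
    """

    outdir: str = "mirpanel-run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    matrix_path: str | None = None
    sheet_path: str | None = None
    alpha: float = 0.05
    paired: bool = False
    reelevation_fraction: float = 0.5
    correction: str | None = None
    k_max: int = 3
    trim_fraction: float = 0.05

    def validated(self) -> "RunConfig":
        if not (1 <= self.k_max):
            raise ConfigurationError("k_max must be >= 1")
        if self.k_max > MAX_PANEL_SIZE:
            warnings.warn(f"k_max={self.k_max} exceeds the conventional "
                          f"panel-size range 1..{MAX_PANEL_SIZE}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline; returns the artifact directory.

    Artifacts: raw matrix + sheet (+ truth when simulated), QC report,
    preprocessed matrix, per-phase JSON results and a per-marker summary,
    panel leaderboard and models, evaluation table, timeline report, and
    a manifest with the configuration and the SHA-256 of every artifact.
    Reruns with an identical configuration are bit-identical.
    """
    config.validated()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # -- inputs --------------------------------------------------------
    truth = None
    if config.matrix_path is not None:
        matrix = mio.read_matrix(config.matrix_path)
        sheet = mio.read_sheet(config.sheet_path)
    else:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        matrix, sheet, truth = simulate_cohort(cohort_cfg)
        written += mio.write_matrix(matrix, outdir / "raw_matrix")
        written.append(mio.write_sheet(sheet, outdir / "sample_sheet.tsv"))
        written.append(mio.write_json(truth, outdir / "truth.json"))

    # -- preprocessing -------------------------------------------------
    batches = sheet_index(sheet)["batch"]
    normalized, calls = preprocess_chain(matrix, batches=batches,
                                         trim_fraction=config.trim_fraction)
    qc = qc_report(calls)
    qc.to_csv(outdir / "qc_report.tsv", sep="\t")
    written.append(outdir / "qc_report.tsv")
    written += mio.write_matrix(normalized, outdir / "normalized_matrix")

    # -- cascade ---------------------------------------------------------
    phases = run_cascade(normalized, sheet, alpha=config.alpha,
                         paired=config.paired,
                         reelevation_fraction=config.reelevation_fraction,
                         correction=config.correction)
    summary_frames = []
    for ph in phases:
        written.append(mio.write_json(ph.to_dict(), outdir / f"phase_{ph.phase}.json"))
        if not ph.table.empty:
            t = ph.table.copy()
            t.columns = [f"{ph.phase}.{c}" for c in t.columns]
            summary_frames.append(t)
    if summary_frames:
        summary = pd.concat(summary_frames, axis=1)
        summary.to_csv(outdir / "marker_summary.tsv", sep="\t")
        written.append(outdir / "marker_summary.tsv")

    candidates = phases[-1].survivors
    labeling = label_samples(sheet)

    # -- panels ----------------------------------------------------------
    best, leaderboard = select_best_panels(normalized, labeling, candidates,
                                           k_max=config.k_max)
    leaderboard.to_csv(outdir / "leaderboard.tsv", sep="\t", index=False)
    written.append(outdir / "leaderboard.tsv")
    written.append(mio.write_json(
        {str(k): model.to_dict() for k, (model, _) in best.items()},
        outdir / "panels.json"))
    if not candidates:
        warnings.warn("pipeline: cascade yielded no candidate markers; "
                      "leaderboard is empty")

    # -- evaluation ------------------------------------------------------
    refs = reference_marker_rows(sheet, labeling)
    rows = list(refs.values())
    for m in candidates:
        rows.append(evaluate_scorer(normalized.values.loc[m], labeling,
                                    cutoff="auto", inclusive=False, name=m))
    for k, (model, _) in sorted(best.items()):
        scores = panel_scores(model, normalized)
        rows.append(evaluate_scorer(scores, labeling, cutoff=0.0,
                                    inclusive=True,
                                    name=f"panel_{k}({','.join(model.members)})"))
    report = evaluation_report(rows, labeling, reference=refs["cea"])
    report.to_csv(outdir / "evaluation_report.tsv", sep="\t", index=False)
    written.append(outdir / "evaluation_report.tsv")

    # -- timelines -------------------------------------------------------
    if best:
        k = max(best)
        model, roc = best[k]
        scores = panel_scores(model, normalized)
        timeline, leads = timeline_report(scores, sheet, cutoff=0.0,
                                          inclusive=True)
        timeline.to_csv(outdir / "timeline_report.tsv", sep="\t")
        written.append(outdir / "timeline_report.tsv")
        written.append(mio.write_json(
            {"panel": list(model.members), "lead_times_months": leads},
            outdir / "lead_times.json"))

    # -- manifest --------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "phases": {ph.phase: {"n_survivors": len(ph.survivors),
                              "params": ph.params} for ph in phases},
        "artifacts": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    mio.write_json(manifest, outdir / "manifest.json")
    return outdir
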