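"""Synthetic longitudinal serum-marker cohorts.

Generates probe x sample microarray-like signal matrices with the
statistical structure the downstream analysis assumes:

* a CRC arm with preoperative sampling for every patient, chronological
  postoperative follow-up (1M/3M/6M/1Y/2Y) for a subset, and a smaller
  "paired" subset sampled only preop and at one month;
* a healthy-control arm sampled once;
* recurrence cases whose tumor burden regrows before clinical recurrence,
  with scheduled visits truncated at the recurrence time plus one
  unscheduled draw at recurrence detection;
* a small planted set of tumor-burden-driven marker probes riding on
  probe-specific baselines, plus negative-control probes drawn from a
  background distribution independent of group;
* batch effects (additive location shift and multiplicative scale on the
  log2 scale, assigned by sample accrual order), an optional hemolysis
  confounder, and residual log2 noise;
* reference tumor-marker columns (CEA-like, CA19-9-like) with a weaker
  association to tumor burden, calibrated so the clinical cut-offs
  (5.0 ng/mL, 37.0 U/mL) give sensitivity/specificity in the range
  conventionally reported for these markers.

All randomness flows from ``CohortConfig.seed`` through named sub-streams,
so regeneration with the same configuration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DataError
from .matrix import (LINEAR, PREOP, RECURRENCE_VISIT, SHEET_COLUMNS,
                     SignalMatrix)

__all__ = [
    "CohortConfig",
    "TumorBurdenTrajectory",
    "burden_at",
    "simulate_cohort",
    "timepoint_label",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Design parameters of a simulated cohort.

    The defaults reproduce the study design the pipeline targets:
    91 CRC patients (71 with chronological perioperative sampling, 20 with
    paired preop/1-month samples only), 71 healthy controls, 13 recurrence
    cases with time-to-recurrence ~ Normal(15.6, 7.4) months truncated at
    4 months, and 2555 probes of which 12 are planted tumor-derived markers
    and 50 are negative controls.
    """

    # cohort structure
    n_crc: int = 91
    n_crc_chronological: int = 71
    n_normal: int = 71
    n_recurrence: int = 13
    # probe structure
    n_probes: int = 2555
    n_true_markers: int = 12
    n_negative_controls: int = 50
    # sampling design
    timepoints_months: tuple[float, ...] = (1.0, 3.0, 6.0, 12.0, 24.0)
    visit_attendance: float = 0.71
    # recurrence timing (truncated normal, months after surgery)
    recurrence_time_mean_months: float = 15.6
    recurrence_time_sd_months: float = 7.4
    recurrence_time_min_months: float = 4.0
    # tumor-burden trajectory
    regrowth_lead_months: float = 9.0
    regrowth_start_level: float = 0.05
    detection_level: float = 1.0
    residual_burden: float = 0.0
    # signal model (log2 scale)
    effect_size: float = 2.5
    noise_sd: float = 0.5
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 1.5
    background_mean_log2: float = 4.0
    background_sd_log2: float = 0.4
    # batch structure
    batch_count: int = 4
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.05
    # hemolysis confounder
    hemolysis_rate: float = 0.05
    n_hemolysis_markers: int = 1
    hemolysis_shift: float = 2.0
    # reference tumor markers (log-normal models of burden association)
    cea_baseline: float = 2.0
    cea_burden_coef: float = 0.75
    cea_log_sd: float = 0.55
    ca19_9_baseline: float = 10.0
    ca19_9_burden_coef: float = 0.27
    ca19_9_log_sd: float = 1.02
    # randomness
    seed: int = 0

    # -- validation ----------------------------------------------------
    def validate(self) -> "CohortConfig":
        def bad(msg: str) -> ConfigurationError:
            return ConfigurationError(f"invalid cohort configuration: {msg}")

        if not (0 <= self.n_recurrence <= self.n_crc_chronological <= self.n_crc):
            raise bad("requires n_recurrence <= n_crc_chronological <= n_crc")
        if self.n_true_markers + self.n_negative_controls > self.n_probes:
            raise bad("requires n_true_markers + n_negative_controls <= n_probes")
        if self.n_normal < 0 or self.n_probes <= 0:
            raise bad("requires n_normal >= 0 and n_probes > 0")
        for name in ("recurrence_time_sd_months", "noise_sd", "batch_shift_sd",
                     "batch_scale_sd", "baseline_sd_log2", "background_sd_log2",
                     "cea_log_sd", "ca19_9_log_sd"):
            if getattr(self, name) < 0:
                raise bad(f"requires {name} >= 0")
        if not (0.0 <= self.hemolysis_rate <= 1.0):
            raise bad("requires hemolysis_rate in [0, 1]")
        if not (0.0 <= self.visit_attendance <= 1.0):
            raise bad("requires visit_attendance in [0, 1]")
        if self.n_hemolysis_markers > self.n_true_markers:
            raise bad("requires n_hemolysis_markers <= n_true_markers")
        if self.batch_count < 1:
            raise bad("requires batch_count >= 1")
        if list(self.timepoints_months) != sorted(self.timepoints_months) or \
                any(t <= 0 for t in self.timepoints_months):
            raise bad("timepoints_months must be positive and increasing")
        if not (0 < self.regrowth_start_level < 1):
            raise bad("requires regrowth_start_level in (0, 1)")
        return self


# ---------------------------------------------------------------------------
# tumor-burden trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorBurdenTrajectory:
    """Deterministic tumor-burden curve for one subject.

    Burden is normalized to 1 preoperatively.  After curative resection it
    drops to ``residual`` (0 by default).  For recurrence subjects the
    burden regrows exponentially from ``start_level * detection_level`` at
    ``recurrence_time - lead_months`` up to ``detection_level`` at the
    clinical recurrence time, and stays at detection level afterwards.
    """

    subject_id: str
    recurrence_time_months: float | None = None
    residual: float = 0.0
    lead_months: float = 9.0
    start_level: float = 0.05
    detection_level: float = 1.0

    def burden(self, t_months: float | None) -> float:
        return burden_at(self, t_months)


def burden_at(trajectory: TumorBurdenTrajectory, t_months: float | None) -> float:
    """Evaluate a trajectory at ``t_months`` after surgery.

    ``t_months`` may be the preop sentinel (``None`` or ``"preop"``), which
    returns 1 by normalization.  Negative times are a domain error.
    """
    if t_months is None or (isinstance(t_months, str) and t_months == PREOP):
        return 1.0
    t = float(t_months)
    if math.isnan(t):
        return 1.0  # months_postop is NaN for preop rows in the sheet
    if t < 0:
        raise DataError(f"negative postoperative time: {t_months!r}")
    t_rec = trajectory.recurrence_time_months
    if t_rec is None:
        return trajectory.residual
    if t >= t_rec:
        return trajectory.detection_level
    t_start = max(0.0, t_rec - trajectory.lead_months)
    if t <= t_start:
        return trajectory.residual
    # exponential regrowth: start_level*d at t_start, d at t_rec
    frac = (t_rec - t) / (t_rec - t_start)
    return trajectory.detection_level * trajectory.start_level ** frac


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_TIMEPOINT_NAMES = {1.0: "1M", 3.0: "3M", 6.0: "6M", 12.0: "1Y", 24.0: "2Y"}


def timepoint_label(months: float) -> str:
    """Human-readable label for a scheduled postoperative visit."""
    return _TIMEPOINT_NAMES.get(float(months), f"{months:g}M")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Named sub-streams: one master SeedSequence, one child per module stage."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_cohort(config: CohortConfig) -> tuple[SignalMatrix, pd.DataFrame, dict]:
    """Simulate a full cohort.

    Returns
    -------
    matrix
        Linear-scale :class:`SignalMatrix` (probes x samples) including
        negative-control probes.
    sheet
        Sample sheet with the documented columns (see
        :data:`mirpanel.matrix.SHEET_COLUMNS`).
    truth
        Ground-truth record: planted marker identities, hemolysis markers
        and affected samples, per-subject trajectories, per-sample tumor
        burden, and realized sample totals.
    """
    config.validate()
    (rng_subj, rng_rec, rng_visits, rng_probes, rng_signal,
     rng_batch, rng_hemo, rng_ref) = _spawn(config.seed, 8)

    # -- subjects ------------------------------------------------------
    crc_ids = [f"CRC-{i + 1:03d}" for i in range(config.n_crc)]
    chron_ids = crc_ids[:config.n_crc_chronological]
    paired_ids = crc_ids[config.n_crc_chronological:]
    nc_ids = [f"NC-{i + 1:03d}" for i in range(config.n_normal)]

    rec_ids = list(rng_rec.choice(chron_ids, size=config.n_recurrence,
                                  replace=False)) if config.n_recurrence else []
    rec_times: dict[str, float] = {}
    if rec_ids:
        lo = ((config.recurrence_time_min_months - config.recurrence_time_mean_months)
              / max(config.recurrence_time_sd_months, 1e-12))
        draws = sps.truncnorm.rvs(lo, np.inf,
                                  loc=config.recurrence_time_mean_months,
                                  scale=config.recurrence_time_sd_months,
                                  size=len(rec_ids), random_state=rng_rec)
        rec_times = dict(zip(rec_ids, map(float, draws)))

    trajectories = {
        sid: TumorBurdenTrajectory(
            subject_id=sid,
            recurrence_time_months=rec_times.get(sid),
            residual=config.residual_burden,
            lead_months=config.regrowth_lead_months,
            start_level=config.regrowth_start_level,
            detection_level=config.detection_level,
        )
        for sid in crc_ids
    }

    # accrual times (months from study start) drive batch assignment
    accrual = {sid: float(rng_subj.uniform(0.0, 24.0)) for sid in crc_ids + nc_ids}

    # -- sample rows ---------------------------------------------------
    rows: list[dict] = []

    def add_sample(subject: str, cohort: str, tp_label: str,
                   months: float | None) -> None:
        traj = trajectories.get(subject)
        burden = burden_at(traj, None if months is None else months) if traj else 0.0
        rows.append({
            "sample_id": f"{subject}-{tp_label}",
            "subject_id": subject,
            "group": "CRC" if subject.startswith("CRC") else "NC",
            "cohort": cohort,
            "timepoint": tp_label,
            "months_postop": np.nan if months is None else float(months),
            "recurrence": subject in rec_times,
            "recurrence_months": rec_times.get(subject, np.nan),
            "_burden": burden,
            "_accrual": accrual[subject] + (0.0 if months is None else months),
        })

    for sid in chron_ids:
        add_sample(sid, "chronological", PREOP, None)
        t_rec = rec_times.get(sid)
        for tp in config.timepoints_months:
            if t_rec is not None and tp > t_rec:
                continue
            if rng_visits.random() < config.visit_attendance:
                add_sample(sid, "chronological", timepoint_label(tp), tp)
        if t_rec is not None:
            # unscheduled draw at clinical recurrence detection
            add_sample(sid, "chronological", RECURRENCE_VISIT, t_rec)
    for sid in paired_ids:
        add_sample(sid, "paired", PREOP, None)
        add_sample(sid, "paired", timepoint_label(config.timepoints_months[0]),
                   config.timepoints_months[0])
    for sid in nc_ids:
        add_sample(sid, "control", "NC", None)

    sheet = pd.DataFrame(rows)

    # -- batches by accrual order -------------------------------------
    order = np.argsort(sheet["_accrual"].to_numpy(), kind="stable")
    batch_labels = np.empty(len(sheet), dtype=object)
    for b, chunk in enumerate(np.array_split(order, config.batch_count)):
        batch_labels[chunk] = f"B{b + 1}"
    sheet["batch"] = batch_labels

    # -- probes --------------------------------------------------------
    n_regular = config.n_probes - config.n_negative_controls
    probe_ids = [f"miR-sim-{i + 1:04d}" for i in range(n_regular)]
    nc_probe_ids = [f"NEGCTRL-{i + 1:03d}" for i in range(config.n_negative_controls)]
    planted = sorted(rng_probes.choice(probe_ids, size=config.n_true_markers,
                                       replace=False))
    hemo_markers = planted[:config.n_hemolysis_markers]

    baseline = rng_probes.normal(config.baseline_mean_log2,
                                 config.baseline_sd_log2, size=n_regular)

    # -- signals (log2 latent expression) ------------------------------
    n_samples = len(sheet)
    burden = sheet["_burden"].to_numpy(float)
    x = baseline[:, None] + rng_signal.normal(0.0, config.noise_sd,
                                              size=(n_regular, n_samples))
    planted_idx = np.array([probe_ids.index(p) for p in planted], dtype=int)
    if len(planted_idx):
        x[planted_idx, :] += config.effect_size * burden[None, :]

    hemolysed = rng_hemo.random(n_samples) < config.hemolysis_rate
    hemo_idx = np.array([probe_ids.index(p) for p in hemo_markers], dtype=int)
    if len(hemo_idx) and hemolysed.any():
        x[np.ix_(hemo_idx, np.flatnonzero(hemolysed))] += config.hemolysis_shift

    # batch effects: additive location shift + multiplicative scale on log2
    batches = sheet["batch"].to_numpy()
    uniq_batches = [f"B{b + 1}" for b in range(config.batch_count)]
    shifts = rng_batch.normal(0.0, config.batch_shift_sd, size=config.batch_count)
    scales = np.abs(rng_batch.normal(1.0, config.batch_scale_sd,
                                     size=config.batch_count))
    for b, (sh, sc) in enumerate(zip(shifts, scales)):
        cols = np.flatnonzero(batches == uniq_batches[b])
        x[:, cols] = sh + sc * x[:, cols]

    # linear-scale raw signal: expression plus additive optical background
    background = 2.0 ** rng_signal.normal(config.background_mean_log2,
                                          config.background_sd_log2,
                                          size=(n_regular, n_samples))
    raw_regular = 2.0 ** x + background
    raw_nc = 2.0 ** rng_signal.normal(config.background_mean_log2,
                                      config.background_sd_log2,
                                      size=(config.n_negative_controls, n_samples))

    values = pd.DataFrame(np.vstack([raw_regular, raw_nc]),
                          index=pd.Index(probe_ids + nc_probe_ids, name="probe_id"),
                          columns=sheet["sample_id"].to_numpy())
    probe_meta = pd.DataFrame(
        {"is_negative_control": [False] * n_regular + [True] * len(nc_probe_ids)},
        index=values.index)
    matrix = SignalMatrix(values=values, probe_meta=probe_meta, scale=LINEAR,
                          meta={"generator": "mirpanel.cohort", "seed": config.seed})

    # -- reference tumor markers ---------------------------------------
    sheet["cea"] = np.exp(np.log(config.cea_baseline)
                          + config.cea_burden_coef * burden
                          + rng_ref.normal(0.0, config.cea_log_sd, n_samples))
    sheet["ca19_9"] = np.exp(np.log(config.ca19_9_baseline)
                             + config.ca19_9_burden_coef * burden
                             + rng_ref.normal(0.0, config.ca19_9_log_sd, n_samples))

    # -- truth record ---------------------------------------------------
    cohort_counts = sheet["cohort"].value_counts().to_dict()
    truth = {
        "config": asdict(config),
        "planted_markers": list(planted),
        "hemolysis_markers": list(hemo_markers),
        "hemolysed_samples": sheet.loc[hemolysed, "sample_id"].tolist(),
        "recurrence_subjects": sorted(rec_times),
        "recurrence_times_months": {k: rec_times[k] for k in sorted(rec_times)},
        "trajectories": {
            sid: {
                "recurrence_time_months": rec_times.get(sid),
                "residual": config.residual_burden,
                "lead_months": config.regrowth_lead_months,
            } for sid in crc_ids
        },
        "burden_by_sample": dict(zip(sheet["sample_id"], map(float, burden))),
        "batches_by_sample": dict(zip(sheet["sample_id"], sheet["batch"])),
        "realized_totals": {
            "n_samples": int(len(sheet)),
            "n_chronological": int(cohort_counts.get("chronological", 0)),
            "n_paired": int(cohort_counts.get("paired", 0)),
            "n_control": int(cohort_counts.get("control", 0)),
        },
    }

    sheet = sheet.drop(columns=["_burden", "_accrual"])
    sheet = sheet[list(SHEET_COLUMNS)]
    return matrix, sheet, truth


def trajectories_from_truth(truth: Mapping) -> dict[str, TumorBurdenTrajectory]:
    """Rebuild trajectory objects from a serialized truth record."""
    cfg = truth.get("config", {})
    out = {}
    for sid, rec in truth["trajectories"].items():
        out[sid] = TumorBurdenTrajectory(
            subject_id=sid,
            recurrence_time_months=rec["recurrence_time_months"],
            residual=rec.get("residual", 0.0),
            lead_months=rec.get("lead_months", 9.0),
            start_level=cfg.get("regrowth_start_level", 0.05),
            detection_level=cfg.get("detection_level", 1.0),
        )
    return out
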