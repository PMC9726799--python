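"""Three-phase longitudinal marker-selection cascade.

* **Screening** — markers significantly upregulated in preoperative CRC
  serum relative to healthy controls.
* **Discovery** — among screening survivors, markers significantly higher
  preoperatively than at one month after surgery.
* **Validation (decline)** — restricted to non-recurrence subjects with
  chronological follow-up, markers whose preoperative level exceeds every
  postoperative timepoint's level (a separate test per timepoint, all of
  which must pass).
* **Validation (re-elevation)** — markers that, in at least a configurable
  fraction of recurrence subjects, fall below their ROC-derived cut-off
  after surgery and then rise back above it by the time of clinical
  recurrence.

All phases default to one-sided rank-sum tests at alpha = 0.05 without
multiplicity correction ("upregulated" is a directional claim, so the
direction is part of the test); a Benjamini-Hochberg flag and a paired
signed-rank option for the discovery phase are available.  Later phases
only ever test survivors of earlier phases, so the surviving sets are
nested by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DataError
from .matrix import PREOP, SignalMatrix, sheet_index
from .stats import benjamini_hochberg, roc_curve, select_cutoff, signed_rank_test

__all__ = [
    "PhaseResult",
    "label_samples",
    "run_screening",
    "run_discovery",
    "run_validation_decline",
    "run_validation_reelevation",
    "run_cascade",
]

CRC_PRESENT = "crc_present"
CRC_ABSENT = "crc_absent"
EXCLUDED = "excluded"


@dataclass
class PhaseResult:
    """Markers surviving one cascade phase, with per-marker statistics."""

    phase: str
    survivors: list[str]
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"phase": self.phase, "survivors": list(self.survivors),
                "params": self.params,
                "table": self.table.reset_index().to_dict(orient="records")}


# ---------------------------------------------------------------------------
# sample labeling
# ---------------------------------------------------------------------------

def label_samples(sheet: pd.DataFrame) -> pd.Series:
    """Classify samples as tumor-bearing, tumor-free, or excluded.

    Preoperative CRC samples are always ``crc_present``; postoperative
    samples of non-recurrence subjects are ``crc_absent``; samples of
    recurrence subjects drawn at or after the recurrence time are
    ``crc_present``; earlier postoperative samples of recurrence subjects
    are ``excluded`` (their tumor status is ambiguous), as are healthy
    controls (the labeling serves recurrence monitoring within the CRC
    arm).
    """
    s = sheet_index(sheet)
    labels = pd.Series(EXCLUDED, index=s.index, name="label")
    crc = s["group"] == "CRC"
    preop = s["timepoint"] == PREOP
    labels[crc & preop] = CRC_PRESENT
    postop = crc & s["months_postop"].notna()

    rec = s["recurrence"].astype(bool)
    if (rec & postop & s["recurrence_months"].isna()).any():
        bad = s.index[rec & postop & s["recurrence_months"].isna()][0]
        raise DataError(f"recurrence subject lacks a recurrence time: sample {bad!r}")
    labels[postop & ~rec] = CRC_ABSENT
    after = postop & rec & (s["months_postop"] >= s["recurrence_months"] - 1e-9)
    labels[after] = CRC_PRESENT
    return labels


# ---------------------------------------------------------------------------
# vectorized one-sided rank-sum helper
# ---------------------------------------------------------------------------

def _rank_sum_matrix(a: np.ndarray, b: np.ndarray, alternative: str) -> np.ndarray:
    """Row-wise Mann-Whitney p-values (tie-corrected normal approximation).

    Degenerate rows (all values tied) get p = 1.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = sps.mannwhitneyu(a, b, axis=1, alternative=alternative,
                             method="asymptotic", use_continuity=True).pvalue
    return np.where(np.isnan(p), 1.0, p)


def _marker_frame(matrix: SignalMatrix, markers) -> pd.DataFrame:
    values = matrix.values.loc[list(markers)]
    return values


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def run_screening(matrix: SignalMatrix, sheet: pd.DataFrame,
                  alpha: float = 0.05, alternative: str = "greater",
                  correction: str | None = None) -> PhaseResult:
    """Markers upregulated in preoperative CRC serum vs healthy controls."""
    s = sheet_index(sheet)
    crc_preop = s.index[(s["group"] == "CRC") & (s["timepoint"] == PREOP)]
    nc = s.index[s["group"] == "NC"]
    if len(crc_preop) == 0 or len(nc) == 0:
        raise ConfigurationError(
            "screening requires >=1 CRC preoperative and >=1 control sample")
    markers = matrix.regular_probe_ids
    a = matrix.values.loc[markers, crc_preop].to_numpy(float)
    b = matrix.values.loc[markers, nc].to_numpy(float)
    p = _rank_sum_matrix(a, b, alternative)
    med_crc = np.median(a, axis=1)
    med_nc = np.median(b, axis=1)
    p_eff = benjamini_hochberg(p) if correction == "bh" else p
    up = med_crc > med_nc
    pass_mask = (p_eff < alpha) & up
    table = pd.DataFrame({"p_value": p, "p_adjusted": p_eff,
                          "median_crc_preop": med_crc, "median_nc": med_nc,
                          "upregulated": up, "survives": pass_mask},
                         index=pd.Index(markers, name="marker"))
    return PhaseResult(
        phase="screening",
        survivors=[m for m, ok in zip(markers, pass_mask) if ok],
        table=table,
        params={"alpha": alpha, "test": "mann-whitney-u", "alternative": alternative,
                "correction": correction, "n_crc_preop": int(len(crc_preop)),
                "n_nc": int(len(nc))})


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def run_discovery(matrix: SignalMatrix, sheet: pd.DataFrame, survivors,
                  alpha: float = 0.05, paired: bool = False,
                  postop_timepoint: str = "1M",
                  alternative: str = "greater") -> PhaseResult:
    """Among screening survivors, markers higher preop than 1 month postop."""
    survivors = list(survivors)
    if not survivors:
        raise ConfigurationError("discovery phase received no screening survivors")
    s = sheet_index(sheet)
    crc = s[s["group"] == "CRC"]
    pre = crc[crc["timepoint"] == PREOP].set_index("subject_id")["sample_id"]
    post = crc[crc["timepoint"] == postop_timepoint].set_index("subject_id")["sample_id"]
    subjects = pre.index.intersection(post.index)
    if len(subjects) == 0:
        raise ConfigurationError(
            f"no subjects with both preoperative and {postop_timepoint} samples")
    pre_cols = pre.loc[subjects].to_numpy()
    post_cols = post.loc[subjects].to_numpy()
    values = _marker_frame(matrix, survivors)
    a = values[pre_cols].to_numpy(float)
    b = values[post_cols].to_numpy(float)

    if paired:
        p = np.array([signed_rank_test(a[i], b[i], alternative=alternative).p_value
                      for i in range(a.shape[0])])
        test = "wilcoxon-signed-rank"
    else:
        p = _rank_sum_matrix(a, b, alternative)
        test = "mann-whitney-u"
    up = np.median(a, axis=1) > np.median(b, axis=1)
    pass_mask = (p < alpha) & up
    table = pd.DataFrame({"p_value": p, "median_preop": np.median(a, axis=1),
                          "median_postop": np.median(b, axis=1),
                          "upregulated": up, "survives": pass_mask},
                         index=pd.Index(survivors, name="marker"))
    return PhaseResult(
        phase="discovery",
        survivors=[m for m, ok in zip(survivors, pass_mask) if ok],
        table=table,
        params={"alpha": alpha, "test": test, "alternative": alternative,
                "paired": paired, "postop_timepoint": postop_timepoint,
                "n_subjects": int(len(subjects))})


# ---------------------------------------------------------------------------
# validation: sustained postoperative decline
# ---------------------------------------------------------------------------

def run_validation_decline(matrix: SignalMatrix, sheet: pd.DataFrame, survivors,
                           alpha: float = 0.05, alternative: str = "greater",
                           strict_timepoints: bool = False) -> PhaseResult:
    """Markers higher preop than at *every* postoperative timepoint
    (non-recurrence subjects only)."""
    survivors = list(survivors)
    if not survivors:
        raise ConfigurationError("validation phase received no discovery survivors")
    s = sheet_index(sheet)
    nr = s[(s["cohort"] == "chronological") & (~s["recurrence"].astype(bool))]
    if nr.empty:
        raise ConfigurationError("no non-recurrence chronological subjects")
    pre_cols = nr.index[nr["timepoint"] == PREOP]
    postop = nr[nr["months_postop"].notna()]
    timepoints = (postop[["timepoint", "months_postop"]].drop_duplicates()
                  .sort_values("months_postop")["timepoint"].tolist())

    values = _marker_frame(matrix, survivors)
    a = values[pre_cols].to_numpy(float)
    p_by_tp: dict[str, np.ndarray] = {}
    for tp in timepoints:
        cols = postop.index[postop["timepoint"] == tp]
        if len(cols) == 0:
            msg = f"validation decline: timepoint {tp!r} has no samples"
            if strict_timepoints:
                raise ConfigurationError(msg)
            warnings.warn(msg + "; skipped")
            continue
        b = values[cols].to_numpy(float)
        p = _rank_sum_matrix(a, b, alternative)
        up = np.median(a, axis=1) > np.median(b, axis=1)
        p_by_tp[tp] = np.where(up, p, 1.0)
    if not p_by_tp:
        raise ConfigurationError("validation decline: no postoperative timepoints")

    stacked = np.stack(list(p_by_tp.values()))
    pass_mask = (stacked < alpha).all(axis=0)
    table = pd.DataFrame({f"p_{tp}": p for tp, p in p_by_tp.items()},
                         index=pd.Index(survivors, name="marker"))
    table["p_max"] = stacked.max(axis=0)
    table["survives"] = pass_mask
    return PhaseResult(
        phase="validation_decline",
        survivors=[m for m, ok in zip(survivors, pass_mask) if ok],
        table=table,
        params={"alpha": alpha, "alternative": alternative,
                "timepoints": list(p_by_tp),
                "n_subjects": int(nr["subject_id"].nunique())})


# ---------------------------------------------------------------------------
# validation: re-elevation before recurrence
# ---------------------------------------------------------------------------

def run_validation_reelevation(matrix: SignalMatrix, sheet: pd.DataFrame, survivors,
                               labeling: pd.Series | None = None,
                               fraction: float = 0.5) -> PhaseResult:
    """Markers that cross back above their cut-off before recurrence.

    For each marker the cut-off is taken from the ROC of tumor-bearing vs
    tumor-free samples (minimum corner distance).  A recurrence subject is
    flagged when some postoperative sample drawn at or before the
    recurrence time exceeds the cut-off *after* at least one earlier
    postoperative sample was below it; the marker survives when the
    flagged fraction reaches ``fraction``.
    """
    survivors = list(survivors)
    if not survivors:
        raise ConfigurationError("re-elevation phase received no survivors")
    s = sheet_index(sheet)
    if labeling is None:
        labeling = label_samples(sheet)
    rec = s[s["recurrence"].astype(bool)]
    rec_subjects = sorted(rec["subject_id"].unique())
    if not rec_subjects:
        raise ConfigurationError("re-elevation requires recurrence subjects")

    present_cols = labeling.index[labeling == CRC_PRESENT]
    absent_cols = labeling.index[labeling == CRC_ABSENT]
    values = _marker_frame(matrix, survivors)

    cutoffs, fractions, flags_per_marker = [], [], []
    for m in survivors:
        row = values.loc[m]
        roc = roc_curve(row[present_cols].to_numpy(), row[absent_cols].to_numpy())
        cut = select_cutoff(roc)
        flagged = 0
        for subj in rec_subjects:
            samp = rec[(rec["subject_id"] == subj) & rec["months_postop"].notna()]
            t_rec = samp["recurrence_months"].iloc[0] if len(samp) else np.nan
            samp = samp[samp["months_postop"] <= t_rec + 1e-9]
            samp = samp.sort_values("months_postop")
            seen_below = False
            hit = False
            for v in row[samp.index].to_numpy():
                if seen_below and v > cut:
                    hit = True
                    break
                if v < cut:
                    seen_below = True
            flagged += int(hit)
        cutoffs.append(cut)
        flags_per_marker.append(flagged)
        fractions.append(flagged / len(rec_subjects))

    fractions = np.asarray(fractions)
    pass_mask = fractions >= fraction
    table = pd.DataFrame({"cutoff": cutoffs, "n_flagged": flags_per_marker,
                          "fraction_flagged": fractions, "survives": pass_mask},
                         index=pd.Index(survivors, name="marker"))
    return PhaseResult(
        phase="validation_reelevation",
        survivors=[m for m, ok in zip(survivors, pass_mask) if ok],
        table=table,
        params={"fraction_threshold": fraction,
                "n_recurrence_subjects": len(rec_subjects),
                "cutoff_rule": "min-corner-distance"})


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_cascade(matrix: SignalMatrix, sheet: pd.DataFrame,
                alpha: float = 0.05, paired: bool = False,
                reelevation_fraction: float = 0.5,
                correction: str | None = None) -> list[PhaseResult]:
    """Run screening -> discovery -> decline -> re-elevation in order.

    An empty survivor set at any stage short-circuits: the remaining
    phases are reported as empty rather than raising, so a vacuous
    threshold (e.g. alpha = 0) still yields a complete, well-formed run.
    """
    results = [run_screening(matrix, sheet, alpha=alpha, correction=correction)]
    labeling = label_samples(sheet)
    steps = [
        lambda surv: run_discovery(matrix, sheet, surv, alpha=alpha, paired=paired),
        lambda surv: run_validation_decline(matrix, sheet, surv, alpha=alpha),
        lambda surv: run_validation_reelevation(matrix, sheet, surv,
                                                labeling=labeling,
                                                fraction=reelevation_fraction),
    ]
    names = ["discovery", "validation_decline", "validation_reelevation"]
    for name, step in zip(names, steps):
        prev = results[-1].survivors
        if not prev:
            warnings.warn(f"cascade: no survivors entering {name}; phase is empty")
            results.append(PhaseResult(phase=name, survivors=[],
                                       table=pd.DataFrame(), params={"empty": True}))
            continue
        results.append(step(prev))
    return results
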