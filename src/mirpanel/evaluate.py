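"""Diagnostic evaluation of markers and panels against reference markers.

Produces the familiar one-row-per-marker table (AUC, sensitivity,
specificity, accuracy at the chosen cut-off, p-values against a reference
scorer) on the tumor-bearing / tumor-free sample labeling, plus
per-subject timeline classifications with lead times for recurrence
subjects.

Cut-off conventions: panels classify tumor-bearing at index >= cut-off
(the diagnostic index rule is boundary-inclusive at 0), while raw markers
at fixed clinical cut-offs classify at value > cut-off (CEA 5.0 ng/mL and
CA19-9 37.0 U/mL are exceedance rules).  Reference markers always use
their fixed clinical cut-offs and are never auto-optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import CRC_ABSENT, CRC_PRESENT
from .errors import DataError
from .matrix import sheet_index
from .stats import (TestResult, delong_paired_auc_test, mcnemar_test,
                    roc_curve, select_cutoff)

__all__ = [
    "EvaluationRow",
    "CLINICAL_CUTOFFS",
    "evaluate_scorer",
    "reference_marker_rows",
    "compare_scorers",
    "evaluation_report",
    "timeline_report",
]

#: Fixed clinical cut-offs for the reference serum tumor markers.
CLINICAL_CUTOFFS = {"cea": 5.0, "ca19_9": 37.0}


@dataclass
class EvaluationRow:
    """One evaluated scorer: confusion counts and derived rates."""

    name: str
    auc: float
    cutoff: float
    cutoff_rule: str            # "auto" or "fixed-clinical"
    inclusive: bool             # True: predict positive at score >= cutoff
    tp: int
    fp: int
    tn: int
    fn: int
    scores: pd.Series = field(repr=False, default=None)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else np.nan

    def predictions(self) -> pd.Series:
        if self.inclusive:
            return self.scores >= self.cutoff
        return self.scores > self.cutoff

    def to_dict(self) -> dict:
        return {"name": self.name, "auc": float(self.auc),
                "cutoff": float(self.cutoff), "cutoff_rule": self.cutoff_rule,
                "inclusive": self.inclusive,
                "sensitivity": float(self.sensitivity),
                "specificity": float(self.specificity),
                "accuracy": float(self.accuracy),
                "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def evaluate_scorer(scores: pd.Series, labeling: pd.Series,
                    cutoff: float | str = "auto", inclusive: bool = True,
                    name: str = "scorer") -> EvaluationRow:
    """Evaluate a per-sample score against the tumor-bearing labeling.

    ``cutoff="auto"`` selects the minimum-corner-distance ROC cut-off;
    a numeric cut-off (e.g. a clinical threshold) is honored as given.
    ``inclusive`` controls whether equality with the cut-off counts as a
    positive call.
    """
    present_ids = labeling.index[labeling == CRC_PRESENT]
    absent_ids = labeling.index[labeling == CRC_ABSENT]
    eligible = present_ids.union(absent_ids)
    missing = eligible.difference(scores.index)
    if len(missing) or scores.reindex(eligible).isna().any():
        bad = missing[0] if len(missing) else \
            scores.reindex(eligible).index[scores.reindex(eligible).isna()][0]
        raise DataError(f"missing score for non-excluded sample {bad!r}")
    scores = scores.loc[eligible].astype(float)
    roc = roc_curve(scores.loc[present_ids].to_numpy(),
                    scores.loc[absent_ids].to_numpy())
    if cutoff == "auto":
        cut = select_cutoff(roc)
        rule = "auto"
    else:
        cut = float(cutoff)
        rule = "fixed-clinical"
    preds = (scores >= cut) if inclusive else (scores > cut)
    tp = int(preds.loc[present_ids].sum())
    fn = int(len(present_ids) - tp)
    fp = int(preds.loc[absent_ids].sum())
    tn = int(len(absent_ids) - fp)
    return EvaluationRow(name=name, auc=roc.auc, cutoff=cut, cutoff_rule=rule,
                         inclusive=inclusive, tp=tp, fp=fp, tn=tn, fn=fn,
                         scores=scores)


def reference_marker_rows(sheet: pd.DataFrame, labeling: pd.Series
                          ) -> dict[str, EvaluationRow]:
    """CEA and CA19-9 rows at their fixed clinical cut-offs."""
    s = sheet_index(sheet)
    out = {}
    for col, cut in CLINICAL_CUTOFFS.items():
        out[col] = evaluate_scorer(s[col], labeling, cutoff=cut,
                                   inclusive=False, name=col.upper())
    return out


def compare_scorers(row_a: EvaluationRow, row_b: EvaluationRow,
                    labeling: pd.Series) -> dict[str, TestResult]:
    """Paired comparison of two evaluated scorers on the same samples.

    Returns McNemar tests on per-sample correctness among tumor-bearing
    samples (a sensitivity comparison) and among tumor-free samples
    (specificity), plus the DeLong test on the AUC difference.
    """
    if not row_a.scores.index.equals(row_b.scores.index):
        raise DataError("scorers were evaluated on different sample sets")
    idx = row_a.scores.index
    present = idx[labeling.loc[idx] == CRC_PRESENT]
    absent = idx[labeling.loc[idx] == CRC_ABSENT]
    preds_a, preds_b = row_a.predictions(), row_b.predictions()

    def discordance(samples, positive_is_correct: bool):
        ca = preds_a.loc[samples] == positive_is_correct
        cb = preds_b.loc[samples] == positive_is_correct
        return int((ca & ~cb).sum()), int((~ca & cb).sum())

    b_sens, c_sens = discordance(present, True)
    b_spec, c_spec = discordance(absent, False)
    labels = labeling.loc[idx].eq(CRC_PRESENT).astype(int).to_numpy()
    return {
        "mcnemar_sensitivity": mcnemar_test(b_sens, c_sens),
        "mcnemar_specificity": mcnemar_test(b_spec, c_spec),
        "delong_auc": delong_paired_auc_test(row_a.scores.to_numpy(),
                                             row_b.scores.to_numpy(), labels),
    }


def evaluation_report(rows: list[EvaluationRow], labeling: pd.Series,
                      reference: EvaluationRow | None = None) -> pd.DataFrame:
    """Assemble the per-marker/panel evaluation table.

    When ``reference`` is given (typically the CEA row), each row gains
    McNemar (sensitivity) and DeLong (AUC) p-values against it.
    """
    records = []
    for row in rows:
        rec = row.to_dict()
        rec.pop("tp"), rec.pop("fp"), rec.pop("tn"), rec.pop("fn")
        rec.update({"tp": row.tp, "fp": row.fp, "tn": row.tn, "fn": row.fn})
        if reference is not None and row is not reference:
            try:
                cmp = compare_scorers(row, reference, labeling)
                rec["p_vs_reference_mcnemar_sens"] = cmp["mcnemar_sensitivity"].p_value
                rec["p_vs_reference_mcnemar_spec"] = cmp["mcnemar_specificity"].p_value
                rec["p_vs_reference_delong_auc"] = cmp["delong_auc"].p_value
            except DataError:
                pass
        records.append(rec)
    return pd.DataFrame(records)


def timeline_report(scores: pd.Series, sheet: pd.DataFrame, cutoff: float,
                    inclusive: bool = True, sustain: int = 1
                    ) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Per-subject chronological classification against a cut-off.

    Returns a long-format timeline (subject, timepoint, months, value,
    above flag) for chronological subjects, and per recurrence subject the
    lead time: recurrence time minus the earliest postoperative time at
    which the score was above the cut-off for ``sustain`` consecutive
    samples (None when never above).
    """
    s = sheet_index(sheet)
    chron = s[s["cohort"] == "chronological"].copy()
    chron["_order"] = chron["months_postop"].fillna(-1.0)
    chron = chron.sort_values(["subject_id", "_order"])
    vals = scores.reindex(chron.index)
    above = (vals >= cutoff) if inclusive else (vals > cutoff)
    timeline = pd.DataFrame({
        "subject_id": chron["subject_id"].to_numpy(),
        "timepoint": chron["timepoint"].to_numpy(),
        "months_postop": chron["months_postop"].to_numpy(),
        "value": vals.to_numpy(),
        "above_cutoff": above.to_numpy(),
        "recurrence": chron["recurrence"].astype(bool).to_numpy(),
    }, index=chron.index).rename_axis("sample_id")

    lead_times: dict[str, float | None] = {}
    for subj, g in timeline.groupby("subject_id", sort=True):
        if not g["recurrence"].any():
            continue
        t_rec = chron.loc[g.index, "recurrence_months"].iloc[0]
        post = g[g["months_postop"].notna()]
        lead = None
        run = 0
        for _, r in post.iterrows():
            run = run + 1 if r["above_cutoff"] else 0
            if run >= sustain:
                lead = float(t_rec - r["months_postop"])
                break
        lead_times[subj] = lead
    return timeline, lead_times
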