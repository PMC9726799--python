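"""Fisher linear discriminant panels and exhaustive small-subset search.

A panel is a set of 1-5 markers with two-class Fisher weights

    w = S_pooled^{-1} (mu_present - mu_absent)

and an equal-prior diagnostic index

    index(x) = w.x - w.(mu_present + mu_absent)/2,

so a sample lying at the midpoint of the class means scores exactly 0.
An index of at least 0 declares a tumor-bearing condition (the boundary
is inclusive).  The exhaustive search fits every subset of the candidate
markers up to size k and ranks panels by training AUC on the
tumor-bearing / tumor-free labeling; no cross-validation is applied by
default, so the leaderboard AUCs are training (apparent) AUCs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cascade import CRC_ABSENT, CRC_PRESENT
from .errors import DataError, FitError
from .matrix import SignalMatrix
from .stats import RocResult, roc_curve, select_cutoff

__all__ = [
    "PanelModel",
    "fit_panel",
    "diagnostic_index",
    "panel_scores",
    "enumerate_panels",
    "select_best_panels",
]

log = logging.getLogger(__name__)

MAX_PANEL_SIZE = 5
TUMOR_BEARING = "tumor-bearing"
NON_TUMOR_BEARING = "non-tumor-bearing"


@dataclass
class PanelModel:
    """A fitted marker panel: members, Fisher weights and centering offset."""

    members: tuple[str, ...]
    weights: np.ndarray
    offset: float
    mean_present: np.ndarray
    mean_absent: np.ndarray
    pooled_cov: np.ndarray
    n_present: int
    n_absent: int
    meta: dict = field(default_factory=dict)

    def index_of(self, values: np.ndarray) -> float:
        return float(self.weights @ np.asarray(values, dtype=float) - self.offset)

    def to_dict(self) -> dict:
        return {"members": list(self.members),
                "weights": [float(w) for w in self.weights],
                "offset": float(self.offset),
                "mean_present": [float(v) for v in self.mean_present],
                "mean_absent": [float(v) for v in self.mean_absent],
                "pooled_cov": [[float(v) for v in row] for row in self.pooled_cov],
                "n_present": self.n_present, "n_absent": self.n_absent,
                "centering": "equal-prior midpoint", **self.meta}


def _class_matrices(matrix: SignalMatrix, labeling: pd.Series,
                    members: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    values = matrix.values.loc[list(members)]
    present = labeling.index[labeling == CRC_PRESENT]
    absent = labeling.index[labeling == CRC_ABSENT]
    return (values[present].to_numpy(float).T,   # samples x members
            values[absent].to_numpy(float).T)


def fit_panel(matrix: SignalMatrix, labeling: pd.Series,
              members: Iterable[str]) -> PanelModel:
    """Fit a Fisher linear discriminant on the given markers.

    Raises :class:`FitError` when the pooled covariance is singular
    (collinear members) and :class:`ValueError` for size violations.
    """
    members = tuple(members)
    k = len(members)
    if not (1 <= k <= MAX_PANEL_SIZE):
        raise ValueError(f"panel size must be 1..{MAX_PANEL_SIZE}, got {k}")
    xp, xa = _class_matrices(matrix, labeling, members)
    n1, n0 = xp.shape[0], xa.shape[0]
    if n1 <= k or n0 <= k:
        raise FitError(f"need more than {k} samples per class, have {n1}/{n0}")
    mu1 = xp.mean(axis=0)
    mu0 = xa.mean(axis=0)
    s1 = np.cov(xp, rowvar=False, ddof=1).reshape(k, k)
    s0 = np.cov(xa, rowvar=False, ddof=1).reshape(k, k)
    pooled = ((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2)
    # condition check: a numerically singular pooled covariance means
    # (near-)collinear members and an unidentifiable weight vector
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        raise FitError(f"singular pooled covariance; collinear members {members}")
    weights = np.linalg.solve(pooled, mu1 - mu0)
    offset = float(weights @ (mu1 + mu0) / 2.0)
    return PanelModel(members=members, weights=weights, offset=offset,
                      mean_present=mu1, mean_absent=mu0, pooled_cov=pooled,
                      n_present=n1, n_absent=n0)


def diagnostic_index(model: PanelModel,
                     sample_values: Mapping[str, float]) -> tuple[float, str]:
    """Diagnostic index of one sample and its class call.

    An index of not less than 0 indicates a tumor-bearing condition.
    """
    try:
        x = np.array([float(sample_values[m]) for m in model.members])
    except KeyError as exc:
        raise DataError(f"sample lacks a value for panel member {exc.args[0]!r}")
    idx = model.index_of(x)
    return idx, TUMOR_BEARING if idx >= 0 else NON_TUMOR_BEARING


def panel_scores(model: PanelModel, matrix: SignalMatrix,
                 samples=None) -> pd.Series:
    """Diagnostic index for every (or the given) sample column."""
    values = matrix.values.loc[list(model.members)]
    if samples is not None:
        values = values[list(samples)]
    scores = model.weights @ values.to_numpy(float) - model.offset
    return pd.Series(scores, index=values.columns, name="diagnostic_index")


def enumerate_panels(candidates: Iterable[str], k_max: int) -> list[tuple[str, ...]]:
    """All candidate subsets of size 1..k_max, ordered by size then
    lexicographically."""
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("no candidate markers to enumerate")
    if not (1 <= k_max <= len(candidates)):
        raise ValueError(f"k_max must be in 1..{len(candidates)}, got {k_max}")
    out: list[tuple[str, ...]] = []
    for k in range(1, k_max + 1):
        out.extend(itertools.combinations(candidates, k))
    return out


def select_best_panels(matrix: SignalMatrix, labeling: pd.Series,
                       candidates: Iterable[str], k_max: int = MAX_PANEL_SIZE,
                       ) -> tuple[dict[int, tuple[PanelModel, RocResult]], pd.DataFrame]:
    """Exhaustively fit all panels up to size k_max and rank by training AUC.

    Returns the best panel per exact size (ties broken lexicographically
    on the sorted member tuple) and a full leaderboard; the leaderboard
    also carries the running best over sizes <= k, which is nondecreasing
    by construction.  Panels whose fit fails (collinear members) are
    skipped and logged.
    """
    candidates = sorted(set(candidates))
    rows = []
    best: dict[int, tuple[PanelModel, RocResult]] = {}
    present = labeling.index[labeling == CRC_PRESENT]
    absent = labeling.index[labeling == CRC_ABSENT]
    if not candidates:
        return best, pd.DataFrame(
            columns=["size", "members", "auc", "cutoff", "sensitivity",
                     "specificity", "accuracy"])
    for members in enumerate_panels(candidates, min(k_max, len(candidates))):
        try:
            model = fit_panel(matrix, labeling, members)
        except FitError as exc:
            log.warning("skipping panel %s: %s", members, exc)
            continue
        scores = panel_scores(model, matrix)
        roc = roc_curve(scores[present].to_numpy(), scores[absent].to_numpy())
        select_cutoff(roc)
        k = len(members)
        rows.append({"size": k, "members": ",".join(members), "auc": roc.auc,
                     "cutoff": roc.cutoff, "sensitivity": roc.sens_at_cutoff,
                     "specificity": roc.spec_at_cutoff,
                     "accuracy": roc.accuracy_at_cutoff})
        if k not in best or roc.auc > best[k][1].auc + 1e-15:
            best[k] = (model, roc)
    leaderboard = pd.DataFrame(rows)
    if not leaderboard.empty:
        leaderboard = leaderboard.sort_values(
            ["size", "auc", "members"], ascending=[True, False, True],
            kind="stable").reset_index(drop=True)
        best_by_size = leaderboard.groupby("size")["auc"].max()
        leaderboard["best_auc_upto_size"] = leaderboard["size"].map(
            best_by_size.cummax())
    return best, leaderboard
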