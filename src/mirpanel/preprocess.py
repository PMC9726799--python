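"""Microarray signal preprocessing.

The chain implemented here mirrors standard two-color miRNA oligo-chip
practice:

1. **Detection call** — a probe is called present in a sample when its raw
   signal strictly exceeds ``mean + 2*SD`` of the sample's negative-control
   signals, after removing the top and bottom 5% of negative controls by
   rank.
2. **Background subtraction** — the trimmed negative-control mean is
   subtracted on the linear scale and the result log2-transformed.
   Undetected probes, and probes whose subtracted signal is not positive,
   are floored at (per-sample minimum of the successfully subtracted log2
   values) - 0.1, keeping the matrix rectangular.
3. **Quantile normalization** — every sample is forced onto the
   cross-sample mean of sorted values; ties receive the mean of the
   reference quantiles they span.
4. **Batch adjustment** — parametric empirical-Bayes location/scale
   adjustment (the ComBat model): per-probe standardization, per-batch
   location/scale estimates shrunk toward batch-level priors, adjust and
   restore scale.

Subtraction happens on the linear scale with log2 applied afterwards,
because the floor rule is defined on the log2 scale; the scale flag of the
output records this.  "Lowest signal intensity on the microarray" is read
as the per-sample minimum of successfully subtracted log2 values, since
the rule replaces per-array missing values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError
from .matrix import LINEAR, LOG2, SignalMatrix

__all__ = [
    "DetectionCall",
    "trimmed_negative_controls",
    "detection_call",
    "subtract_background",
    "quantile_normalize",
    "batch_adjust",
    "preprocess_chain",
    "qc_report",
]

DEFAULT_TRIM_FRACTION = 0.05
FLOOR_OFFSET = 0.1  # log2 units below the per-sample minimum


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def trimmed_negative_controls(nc_signals, trim_fraction: float = DEFAULT_TRIM_FRACTION
                              ) -> np.ndarray:
    """Drop the ``floor(n*trim_fraction)`` lowest and highest NC signals.

    Removal is by rank, so the result is independent of input order; the
    returned array is sorted ascending.
    """
    values = np.asarray(nc_signals, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("no negative-control signals supplied")
    if not (0.0 <= trim_fraction < 0.5):
        raise ConfigurationError(f"trim_fraction must be in [0, 0.5): {trim_fraction}")
    k = math.floor(values.size * trim_fraction)
    if 2 * k >= values.size:
        raise DegenerateInputError(
            f"trimming {k} from each end would empty {values.size} negative controls")
    values = np.sort(values)
    return values[k:values.size - k] if k else values


@dataclass
class DetectionCall:
    """Per-sample detection thresholds and per-probe detected flags.

    ``threshold[s] = mean + 2*sd`` of sample ``s``'s trimmed negative
    controls (sample standard deviation, ddof=1); a probe is detected iff
    its signal is strictly greater than the threshold.  The trimmed NC
    mean is stored because background subtraction reuses it.
    """

    detected: pd.DataFrame          # bool, probes x samples (regular probes)
    thresholds: pd.Series           # per sample
    nc_means: pd.Series             # trimmed NC mean per sample
    trim_fraction: float
    n_controls_used: pd.Series      # NC count after trimming, per sample


def detection_call(matrix: SignalMatrix,
                   trim_fraction: float = DEFAULT_TRIM_FRACTION) -> DetectionCall:
    """Call probe presence against trimmed negative controls, per sample."""
    if matrix.scale != LINEAR:
        raise ConfigurationError("detection_call expects a linear-scale raw matrix")
    nc_ids = matrix.negative_control_ids
    if len(nc_ids) == 0:
        raise ConfigurationError("matrix has no negative-control probes")
    nc = matrix.values.loc[nc_ids]
    regular = matrix.values.loc[matrix.regular_probe_ids]

    thresholds, means, counts = {}, {}, {}
    for s in matrix.sample_ids:
        trimmed = trimmed_negative_controls(nc[s].to_numpy(), trim_fraction)
        mu = float(trimmed.mean())
        sd = float(trimmed.std(ddof=1)) if trimmed.size > 1 else 0.0
        thresholds[s] = mu + 2.0 * sd
        means[s] = mu
        counts[s] = int(trimmed.size)
    thresholds = pd.Series(thresholds, name="detection_threshold")
    detected = regular.gt(thresholds, axis=1)
    return DetectionCall(detected=detected, thresholds=thresholds,
                         nc_means=pd.Series(means, name="nc_mean"),
                         trim_fraction=trim_fraction,
                         n_controls_used=pd.Series(counts, name="n_controls_used"))


# ---------------------------------------------------------------------------
# background subtraction and flooring
# ---------------------------------------------------------------------------

def subtract_background(matrix: SignalMatrix, calls: DetectionCall) -> SignalMatrix:
    """Subtract the trimmed NC mean, log2-transform, and floor failures.

    Negative-control probes are carried through the same rule (they are
    essentially always floored) so the matrix stays rectangular.
    """
    if matrix.scale != LINEAR:
        raise ConfigurationError("subtract_background expects a linear-scale matrix")
    values = matrix.values
    sub = values.sub(calls.nc_means, axis=1)
    detected = calls.detected.reindex(index=values.index, fill_value=False)
    ok = detected & (sub > 0)

    out = np.full(values.shape, np.nan)
    ok_np = ok.to_numpy()
    out[ok_np] = np.log2(sub.to_numpy()[ok_np])

    floors = {}
    for j, s in enumerate(values.columns):
        col = out[:, j]
        good = col[~np.isnan(col)]
        if good.size == 0:
            raise DegenerateInputError(
                f"sample {s!r}: no probe with positive background-subtracted signal")
        floors[s] = float(good.min()) - FLOOR_OFFSET
        col[np.isnan(col)] = floors[s]
    result = pd.DataFrame(out, index=values.index, columns=values.columns)
    return matrix.with_values(result, scale=LOG2,
                              background_subtracted=True,
                              floor_values={k: floors[k] for k in floors})


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Force every sample onto the cross-sample mean of sorted values.

    Ties within a sample receive the mean of the reference quantiles they
    span, so tied inputs stay tied.  A single-sample matrix is returned
    unchanged with a warning (there is nothing to normalize against).
    """
    values = matrix.values
    if values.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return matrix.with_values(values.copy(), quantile_normalized=True)
    v = values.to_numpy(float)
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average reference values across tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    result = pd.DataFrame(out, index=values.index, columns=values.columns)
    return matrix.with_values(result, quantile_normalized=True)


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment (parametric ComBat)
# ---------------------------------------------------------------------------

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2

def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4, max_iter: int = 500
            ) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution for the EB batch-effect posteriors (one batch).

    ``z`` is the standardized data restricted to the batch (probes x
    samples); returns posterior location and scale per probe.
    """
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    for _ in range(max_iter):
        if change <= conv:
            break
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max()
                     if np.abs(g_old).max() > 0 else 0.0,
                     np.abs(d_new - d_old).max() / np.abs(d_old).max())
        g_old, d_old = g_new, d_new
    return g_old, d_old


def batch_adjust(matrix: SignalMatrix, batches, *,
                 small_batch: str = "error") -> SignalMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Parameters
    ----------
    batches
        Per-sample batch labels, aligned with the matrix columns (a
        sequence or a mapping/Series indexed by sample ID).
    small_batch
        ``"error"`` (default) raises when any batch has fewer than two
        samples; ``"warn"`` returns the input unchanged with a warning.

    A single-batch input is returned unchanged (with a warning): with no
    second batch there is no batch effect to remove, and running the
    shrinkage machinery would only inject estimation noise.
    """
    if matrix.scale != LOG2:
        raise ConfigurationError("batch_adjust expects a log2-scale matrix")
    values = matrix.values
    if isinstance(batches, (pd.Series, dict)):
        batches = pd.Series(batches).reindex(values.columns)
        if batches.isna().any():
            missing = values.columns[batches.isna()][0]
            raise ConfigurationError(f"no batch label for sample {missing!r}")
        batches = batches.to_numpy()
    else:
        batches = np.asarray(batches)
        if batches.shape[0] != values.shape[1]:
            raise ConfigurationError("batch labels must align with matrix samples")

    labels, inverse = np.unique(batches, return_inverse=True)
    if len(labels) == 1:
        warnings.warn("batch_adjust: single batch, returning input unchanged")
        return matrix.with_values(values.copy(), batch_adjusted=False)
    counts = np.bincount(inverse)
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        if small_batch == "warn":
            warnings.warn(f"batch_adjust: batches with <2 samples {small}; "
                          "returning input unchanged")
            return matrix.with_values(values.copy(), batch_adjusted=False)
        raise ConfigurationError(
            f"batches with <2 samples cannot be variance-adjusted: {small}")

    x = values.to_numpy(float)
    n_probes, n_samples = x.shape
    n_batches = len(labels)

    # per-probe batch means and the accrual-weighted grand mean
    batch_means = np.stack([x[:, inverse == b].mean(axis=1)
                            for b in range(n_batches)], axis=1)
    weights = counts / n_samples
    grand_mean = batch_means @ weights
    fitted = batch_means[:, inverse]
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-18)

    z = (x - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    adjusted = np.empty_like(z)
    for b in range(n_batches):
        cols = inverse == b
        zb = z[:, cols]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        s2 = float(d_hat.var(ddof=1))
        # relative degeneracy check: on noise-free constructed inputs the
        # cross-probe spread of the estimates is pure floating-point jitter
        # and the EB iteration has nothing meaningful to shrink
        t2_floor = 1e-12 * max(1.0, float(np.mean(g_hat ** 2)))
        s2_floor = 1e-24 * max(1.0, float(np.mean(d_hat ** 2)))
        if t2 <= t2_floor or s2 <= s2_floor or not np.isfinite(_aprior(d_hat)):
            # no spread across probes: shrinkage targets equal the estimates
            g_star, d_star = g_hat, np.maximum(d_hat, 1e-18)
        else:
            g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2,
                                     _aprior(d_hat), _bprior(d_hat))
            d_star = np.maximum(d_star, 1e-18)
        adjusted[:, cols] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    result = adjusted * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    out = pd.DataFrame(result, index=values.index, columns=values.columns)
    return matrix.with_values(out, batch_adjusted=True)


# ---------------------------------------------------------------------------
# convenience chain + QC
# ---------------------------------------------------------------------------

def preprocess_chain(matrix: SignalMatrix, batches=None,
                     trim_fraction: float = DEFAULT_TRIM_FRACTION,
                     ) -> tuple[SignalMatrix, DetectionCall]:
    """Run detection -> subtraction -> quantile normalization -> ComBat."""
    calls = detection_call(matrix, trim_fraction)
    logm = subtract_background(matrix, calls)
    normed = quantile_normalize(logm)
    if batches is not None:
        normed = batch_adjust(normed, batches)
    return normed, calls


def qc_report(calls: DetectionCall) -> pd.DataFrame:
    """Per-sample QC table: NC summaries, thresholds, detected counts."""
    return pd.DataFrame({
        "nc_mean": calls.nc_means,
        "detection_threshold": calls.thresholds,
        "n_controls_used": calls.n_controls_used,
        "n_detected": calls.detected.sum(axis=0),
        "fraction_detected": calls.detected.mean(axis=0),
    }).rename_axis("sample_id")
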