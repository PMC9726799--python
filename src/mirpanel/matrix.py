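"""In-memory containers shared across the pipeline.

The central object is :class:`SignalMatrix`: a probe x sample table of
microarray signals together with probe metadata (negative-control flags)
and a scale flag distinguishing raw linear-scale signals from log2
normalized values.

The sample sheet is a plain :class:`pandas.DataFrame` with the documented
columns in :data:`SHEET_COLUMNS`; helper accessors live in
:mod:`mirpanel.cohort` and :mod:`mirpanel.cascade`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConfigurationError

#: Scale flags for SignalMatrix.values
LINEAR = "linear"
LOG2 = "log2"

#: Timepoint label used for preoperative samples.  Preop is a sentinel, not
#: month 0: the months_postop column is NaN for preop (and control) samples.
PREOP = "preop"

#: Timepoint label for the unscheduled blood draw at recurrence detection.
RECURRENCE_VISIT = "REC"

#: Documented sample-sheet columns.
SHEET_COLUMNS = (
    "sample_id",      # unique sample identifier
    "subject_id",     # subject the sample was drawn from
    "group",          # "CRC" or "NC"
    "cohort",         # "chronological", "paired" or "control"
    "timepoint",      # "preop", "1M", "3M", "6M", "1Y", "2Y", "REC" or "NC"
    "months_postop",  # months since surgery (NaN for preop / control)
    "batch",          # processing batch label (input to ComBat)
    "recurrence",     # bool: subject experienced recurrence
    "recurrence_months",  # months to clinical recurrence (NaN otherwise)
    "cea",            # reference tumor marker, ng/mL
    "ca19_9",         # reference tumor marker, U/mL
)


@dataclass
class SignalMatrix:
    """Probe x sample signal table with probe metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with sample IDs as columns.
    probe_meta
        DataFrame indexed by probe ID with at least the boolean column
        ``is_negative_control``.
    scale
        Either ``"linear"`` (raw, nonnegative) or ``"log2"`` (normalized).
    """

    values: pd.DataFrame
    probe_meta: pd.DataFrame
    scale: str = LINEAR
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ConfigurationError("signal matrix must have >=1 probe and >=1 sample")
        if v.index.hasnans or v.columns.hasnans:
            raise ConfigurationError("probe/sample identifiers must not be missing")
        if not v.index.is_unique:
            dup = v.index[v.index.duplicated()][0]
            raise ConfigurationError(f"duplicate probe identifier: {dup!r}")
        if not v.columns.is_unique:
            dup = v.columns[v.columns.duplicated()][0]
            raise ConfigurationError(f"duplicate sample identifier: {dup!r}")
        if self.scale not in (LINEAR, LOG2):
            raise ConfigurationError(f"unknown scale flag: {self.scale!r}")
        if "is_negative_control" not in self.probe_meta.columns:
            raise ConfigurationError("probe_meta must carry an is_negative_control column")
        if not self.probe_meta.index.equals(v.index):
            raise ConfigurationError("probe_meta index must match the value matrix probes")
        if self.scale == LINEAR and (v.to_numpy() < 0).any():
            raise ConfigurationError("linear-scale signals must be nonnegative")

    # -- convenience ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def negative_control_ids(self) -> pd.Index:
        mask = self.probe_meta["is_negative_control"].astype(bool)
        return self.probe_meta.index[mask]

    @property
    def regular_probe_ids(self) -> pd.Index:
        mask = ~self.probe_meta["is_negative_control"].astype(bool)
        return self.probe_meta.index[mask]

    def with_values(self, values: pd.DataFrame, scale: str | None = None,
                    **meta) -> "SignalMatrix":
        """Return a copy carrying new values (and optionally a new scale)."""
        new_meta = {**self.meta, **meta}
        return SignalMatrix(values=values, probe_meta=self.probe_meta.copy(),
                            scale=self.scale if scale is None else scale,
                            meta=new_meta)

    def copy(self) -> "SignalMatrix":
        return replace(self, values=self.values.copy(),
                       probe_meta=self.probe_meta.copy(), meta=dict(self.meta))


def validate_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet for the documented columns and unique IDs."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ConfigurationError(f"sample sheet lacks required columns: {missing}")
    if not sheet["sample_id"].is_unique:
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ConfigurationError(f"duplicate sample_id in sheet: {dup!r}")
    return sheet


def sheet_index(sheet: pd.DataFrame) -> pd.DataFrame:
    """Return the sheet indexed by sample_id (kept as a column too)."""
    return sheet.set_index("sample_id", drop=False)
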