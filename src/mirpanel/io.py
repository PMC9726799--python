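"""Tab-separated readers and writers for matrices, sheets and results.

A signal matrix on disk is three files sharing a base path:

* ``<base>.tsv``          — values, first column ``probe_id``, header row of
  sample IDs;
* ``<base>.probes.tsv``   — probe metadata (``probe_id``,
  ``is_negative_control``);
* ``<base>.meta.json``    — sidecar header: scale flag plus any processing
  metadata.

Reading and writing round-trip to full float precision (shortest
round-trip decimal representation).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .matrix import LINEAR, SignalMatrix, validate_sheet

__all__ = ["write_matrix", "read_matrix", "write_sheet", "read_sheet",
           "write_json", "read_json"]


def _paths(base) -> tuple[Path, Path, Path]:
    base = Path(base)
    if base.suffix == ".tsv":
        base = base.with_suffix("")
    return (base.with_suffix(".tsv"), Path(f"{base}.probes.tsv"),
            Path(f"{base}.meta.json"))


def write_matrix(matrix: SignalMatrix, base) -> list[Path]:
    """Write a SignalMatrix as <base>.tsv + probe metadata + JSON sidecar."""
    values_path, probes_path, meta_path = _paths(base)
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(values_path, sep="\t")
    pm = matrix.probe_meta.copy()
    pm.index.name = "probe_id"
    pm.to_csv(probes_path, sep="\t")
    meta = {"scale": matrix.scale, **matrix.meta}
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
    return [values_path, probes_path, meta_path]


def read_matrix(base) -> SignalMatrix:
    """Read a SignalMatrix written by :func:`write_matrix`.

    Duplicate identifiers, ragged rows, and non-numeric cells raise
    :class:`ParseError` with file/location context.
    """
    values_path, probes_path, meta_path = _paths(base)
    if not values_path.exists():
        raise ParseError(f"no such matrix file: {values_path}")
    with open(values_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ParseError(f"{values_path}: duplicated sample column {name!r}")
        seen.add(name)
    try:
        raw = pd.read_csv(values_path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{values_path}: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ParseError(f"{values_path}: empty matrix (no probes or no samples)")
    if not raw.index.is_unique:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{values_path}: duplicated probe row {dup!r}")
    if raw.isna().any().any():
        col = raw.columns[raw.isna().any()][0]
        row = raw.index[raw[col].isna()][0]
        raise ParseError(f"{values_path}: missing cell at probe {row!r}, "
                         f"sample {col!r} (ragged row?)")
    try:
        values = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            bad = pd.to_numeric(raw[col], errors="coerce")
            if bad.isna().any():
                row = raw.index[bad.isna()][0]
                raise ParseError(f"{values_path}: non-numeric cell "
                                 f"{raw.loc[row, col]!r} at probe {row!r}, "
                                 f"sample {col!r}")
        raise  # pragma: no cover - unreachable

    scale = LINEAR
    meta: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        scale = meta.pop("scale", LINEAR)
    if probes_path.exists():
        probe_meta = pd.read_csv(probes_path, sep="\t", index_col=0)
        probe_meta["is_negative_control"] = probe_meta["is_negative_control"].astype(bool)
    else:
        probe_meta = pd.DataFrame({"is_negative_control": False},
                                  index=values.index)
    if not probe_meta.index.equals(values.index):
        raise ParseError(f"{probes_path}: probe metadata does not match "
                         f"the value matrix probes")
    return SignalMatrix(values=values, probe_meta=probe_meta, scale=scale,
                        meta=meta)


def write_sheet(sheet: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_sheet(sheet)
    sheet.to_csv(path, sep="\t", index=False)
    return path


def read_sheet(path) -> pd.DataFrame:
    path = Path(path)
    try:
        sheet = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if sheet["recurrence"].dtype == object:  # "True"/"False" strings
        sheet["recurrence"] = sheet["recurrence"].map(
            {"True": True, "False": False, True: True, False: False})
    sheet["recurrence"] = sheet["recurrence"].astype(bool)
    return validate_sheet(sheet)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    return str(obj)
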