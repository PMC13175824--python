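"""Readers and writers for score tables, labels, weights and reports.

Interchange format: UTF-8 comma-separated tables with a header row.
A score table has columns ``sample_id`` followed by the C class names;
probabilities are written with 17 significant digits so write/read
round-trips are exact to text precision.  A label table has columns
``sample_id,label`` with labels given either as class names or integer
indices.  Class order is defined by the header of the first score
table; all other inputs are validated and aligned against it by
sample_id.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import ScoreTensor
from .simplex import WeightVector

__all__ = [
    "ScoreTableError",
    "read_score_tables",
    "write_score_tables",
    "read_labels",
    "write_labels",
    "read_weights",
    "write_weights",
]

logger = logging.getLogger("ospreyfuse")

#: rows whose probabilities deviate from sum 1 by more than this are
#: renormalized with a logged warning ...
RENORM_WARN_TOL = 1e-3
#: ... and beyond this absolute deviation the file is rejected outright
ROW_SUM_HARD_TOL = 0.05
#: tolerance on individual probability cells around [0, 1]
CELL_TOL = 1e-9


class ScoreTableError(ValueError):
    """A score or label table failed validation."""


def _read_one_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise ScoreTableError(f"score table not found: {path}")
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "sample_id" or df.shape[1] < 3:
        raise ScoreTableError(
            f"{path}: expected header 'sample_id' plus >= 2 class columns, "
            f"got {list(df.columns)}"
        )
    return df


def read_score_tables(paths) -> ScoreTensor:
    """Load K score tables into a validated (K, N, C) tensor.

    All tables must share the class-name header of the first and hold
    the same sample_id set; rows of later tables are re-aligned to the
    first table's order.  Cells must be finite probabilities in
    [-1e-9, 1+1e-9]; rows are renormalized to sum exactly one, with a
    warning when the deviation exceeds 1e-3 and a hard error beyond
    0.05.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ScoreTableError("need at least one score table")
    frames = [_read_one_table(p) for p in paths]
    class_names = tuple(frames[0].columns[1:])
    ref_ids = frames[0]["sample_id"].tolist()
    if len(set(ref_ids)) != len(ref_ids):
        raise ScoreTableError(f"{paths[0]}: duplicate sample_id values")
    n_renorm_warnings = 0
    blocks = []
    for path, df in zip(paths, frames):
        if tuple(df.columns[1:]) != class_names:
            raise ScoreTableError(
                f"{path}: class-name header {list(df.columns[1:])} does not "
                f"match first table {list(class_names)}"
            )
        ids = df["sample_id"].tolist()
        if set(ids) != set(ref_ids) or len(ids) != len(ref_ids):
            raise ScoreTableError(
                f"{path}: sample_id set does not match {paths[0]}"
            )
        df = df.set_index("sample_id").loc[ref_ids]
        vals = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ScoreTableError(
                f"{path}: non-finite probability at row {ref_ids[r]!r}, "
                f"column {class_names[c]!r}"
            )
        bad = np.argwhere((vals < -CELL_TOL) | (vals > 1.0 + CELL_TOL))
        if bad.size:
            r, c = bad[0]
            raise ScoreTableError(
                f"{path}: probability {vals[r, c]} out of range [0, 1] at "
                f"row {ref_ids[r]!r}, column {class_names[c]!r}"
            )
        vals = np.clip(vals, 0.0, 1.0)
        sums = vals.sum(axis=1)
        dev = np.abs(sums - 1.0)
        worst = np.argmax(dev)
        if dev[worst] > ROW_SUM_HARD_TOL:
            raise ScoreTableError(
                f"{path}: row {ref_ids[worst]!r} probabilities sum to "
                f"{sums[worst]:.4f} (deviation > {ROW_SUM_HARD_TOL})"
            )
        loose = dev > RENORM_WARN_TOL
        if loose.any():
            n_renorm_warnings += int(loose.sum())
            logger.warning(
                "%s: renormalized %d row(s) with probability sums off by "
                "more than %g (worst %.4f)",
                path,
                int(loose.sum()),
                RENORM_WARN_TOL,
                sums[worst],
            )
        vals = vals / sums[:, None]
        blocks.append(vals)
    tensor = ScoreTensor(
        values=np.stack(blocks),
        model_ids=tuple(p.stem for p in paths),
        class_names=class_names,
        sample_ids=tuple(ref_ids),
    )
    if n_renorm_warnings:
        logger.info("ingest complete with %d renormalization warning(s)",
                    n_renorm_warnings)
    return tensor


def write_score_tables(tensor: ScoreTensor, out_dir, prefix: str = "scores") -> list:
    """Write one CSV per model; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = list(tensor.sample_ids) or [f"s{j:06d}" for j in range(tensor.n_samples)]
    paths = []
    for m, mid in enumerate(tensor.model_ids):
        df = pd.DataFrame(tensor.values[m], columns=list(tensor.class_names))
        df.insert(0, "sample_id", ids)
        path = out_dir / f"{prefix}_{mid}.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        paths.append(path)
    return paths


def read_labels(path, class_names) -> np.ndarray:
    """Load a two-column (sample_id, label) table as integer indices.

    Labels may be class names (mapped by header order) or integer
    indices already in range.  Rows are returned in file order; align
    them to a tensor with :func:`align_labels`.
    """
    path = Path(path)
    if not path.exists():
        raise ScoreTableError(f"labels file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ScoreTableError(
            f"{path}: expected header 'sample_id,label', got {list(df.columns)}"
        )
    name_to_idx = {name: i for i, name in enumerate(class_names)}
    out = np.empty(len(df), dtype=np.int64)
    for j, lab in enumerate(df["label"]):
        if lab in name_to_idx:
            out[j] = name_to_idx[lab]
        else:
            try:
                v = int(lab)
            except (TypeError, ValueError):
                raise ScoreTableError(
                    f"{path}: unknown label {lab!r} (not a class name or index)"
                ) from None
            if not 0 <= v < len(class_names):
                raise ScoreTableError(
                    f"{path}: label index {v} outside [0, {len(class_names) - 1}]"
                )
            out[j] = v
    return _Labels(out, tuple(df["sample_id"].tolist()))


class _Labels(np.ndarray):
    """Label vector that remembers its sample ids (for alignment)."""

    def __new__(cls, values, sample_ids):
        obj = np.asarray(values, dtype=np.int64).view(cls)
        obj.sample_ids = tuple(sample_ids)
        return obj

    def __array_finalize__(self, obj):
        if obj is not None:
            self.sample_ids = getattr(obj, "sample_ids", ())


def align_labels(labels: _Labels, tensor: ScoreTensor) -> np.ndarray:
    """Reorder a labeled vector to a tensor's sample order by sample_id."""
    ids = getattr(labels, "sample_ids", ())
    if not ids or not tensor.sample_ids:
        if len(labels) != tensor.n_samples:
            raise ScoreTableError(
                f"label count {len(labels)} does not match sample count "
                f"{tensor.n_samples}"
            )
        return np.asarray(labels, dtype=np.int64)
    pos = {sid: j for j, sid in enumerate(ids)}
    missing = [sid for sid in tensor.sample_ids if sid not in pos]
    if missing:
        raise ScoreTableError(f"labels missing sample id(s): {missing[:5]}")
    order = [pos[sid] for sid in tensor.sample_ids]
    return np.asarray(labels, dtype=np.int64)[order]


def write_labels(y, sample_ids, class_names, path) -> None:
    names = list(class_names)
    df = pd.DataFrame(
        {"sample_id": list(sample_ids), "label": [names[v] for v in y]}
    )
    df.to_csv(path, index=False)


def read_weights(path) -> WeightVector:
    return WeightVector.from_json(Path(path).read_text())


def write_weights(weights: WeightVector, path) -> None:
    Path(path).write_text(weights.to_json() + "\n")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
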