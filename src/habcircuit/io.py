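"""CSV/JSON I/O for traces and designs.

Trace files are wide CSV: one row per cell with ``cell_id``, ``region``,
optional ``true_subtype`` and ``z`` columns, followed by time columns named
``t<seconds>`` (e.g. ``t0``, ``t1.5``).  Round trips are lossless.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .synthetic import TraceMatrix

__all__ = ["write_traces", "read_traces", "write_design", "read_design"]

_META_COLS = ("cell_id", "region", "true_subtype", "z")


def write_traces(tm: TraceMatrix, path) -> None:
    df = tm.cell_meta.copy()
    for col in df.columns:
        if col not in _META_COLS:
            raise ValueError(f"unexpected metadata column {col!r}")
    tcols = [f"t{t:g}" for t in tm.time_axis]
    data = pd.DataFrame(tm.values, columns=tcols)
    pd.concat([df.reset_index(drop=True), data], axis=1).to_csv(
        path, index=False, float_format="%.10g")


def read_traces(path) -> TraceMatrix:
    df = pd.read_csv(path)
    if "region" not in df.columns:
        raise ValueError(f"{path}: missing required 'region' column")
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'cell_id' column")
    meta_cols = [c for c in _META_COLS if c in df.columns]
    tcols = [c for c in df.columns if c not in _META_COLS]
    bad = [c for c in tcols if not c.startswith("t")]
    if bad:
        raise ValueError(f"{path}: malformed time columns {bad[:5]}")
    try:
        times = np.array([float(c[1:]) for c in tcols])
    except ValueError as e:
        raise ValueError(f"{path}: unparseable time column header: {e}") from None
    if times.size > 1:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: non-uniform time axis")
    if len(df) == 0:
        warnings.warn(f"{path}: file contains 0 cells")
        return TraceMatrix(np.empty((0, times.size)), times,
                           pd.DataFrame(columns=meta_cols))
    meta = df[meta_cols].copy()
    if "true_subtype" in meta:
        meta["true_subtype"] = meta["true_subtype"].fillna("")
    return TraceMatrix(df[tcols].to_numpy(dtype=float), times, meta)


def write_design(design, dirpath) -> None:
    """Write X/y as CSV plus a JSON manifest of orderings and baselines."""
    import pathlib

    d = pathlib.Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(design.X, columns=list(design.columns))
    df["raphe"] = design.y
    df["condition"] = [design.conditions[i] for i in design.condition_index]
    df.to_csv(d / "design.csv", index=False, float_format="%.12g")
    manifest = {
        "conditions": list(design.conditions),
        "columns": list(design.columns),
        "n_rows": int(design.X.shape[0]),
        "meta": design.meta,
    }
    with open(d / "design_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_design(dirpath):
    import pathlib

    from .response import StackedDesign

    d = pathlib.Path(dirpath)
    with open(d / "design_manifest.json") as fh:
        manifest = json.load(fh)
    df = pd.read_csv(d / "design.csv")
    conditions = tuple(manifest["conditions"])
    columns = tuple(manifest["columns"])
    cond_idx = np.array([conditions.index(c) for c in df["condition"]])
    return StackedDesign(df[list(columns)].to_numpy(dtype=float),
                         df["raphe"].to_numpy(dtype=float),
                         cond_idx, conditions, columns, manifest.get("meta", {}))
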