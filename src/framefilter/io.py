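"""Delimited-text I/O for every artifact the pipeline produces.

All on-disk formats are plain text: time series and matrices as TSV/CSV
with header rows, framesets as newline-delimited 0-based integers,
templates as two-column TSV, results as JSON.  The time-series reader
auto-detects the delimiter.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from framefilter.core import FrameSet, RegionalTimeSeries
from framefilter.template_filter import Template

__all__ = [
    "read_timeseries", "write_timeseries", "read_matrix", "write_matrix",
    "read_frameset", "write_frameset", "read_template", "write_template",
    "read_table", "write_json", "read_json",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_timeseries(path, subject_id: str = "s0", run_id: str = "r0") -> RegionalTimeSeries:
    """Read a frames x nodes table; header row = node labels."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    return RegionalTimeSeries(
        data=df.to_numpy(dtype=float),
        subject_id=subject_id,
        run_id=run_id,
        node_labels=[str(c) for c in df.columns],
    )


def write_timeseries(ts: RegionalTimeSeries, path) -> None:
    pd.DataFrame(ts.data, columns=ts.node_labels).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> np.ndarray:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0).to_numpy(dtype=float)


def write_matrix(mat, path, labels=None) -> None:
    mat = np.asarray(getattr(mat, "data", mat), dtype=float)
    if labels is None:
        labels = [f"node{i}" for i in range(mat.shape[0])]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(path, sep="\t")


def read_frameset(path, T: int) -> FrameSet:
    idx = np.loadtxt(path, dtype=int, ndmin=1)
    return FrameSet(indices=idx, T=T)


def write_frameset(frames: FrameSet, path) -> None:
    np.savetxt(path, frames.indices, fmt="%d")


def read_template(path) -> Template:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if df.shape[1] != 2:
        raise ValueError("template file must have two columns: node_label, 0/1")
    return Template(labels=df.iloc[:, 1].to_numpy(dtype=int), name=path.stem)


def write_template(tpl: Template, path, node_labels=None) -> None:
    if node_labels is None:
        node_labels = [f"node{i}" for i in range(len(tpl))]
    pd.DataFrame({"node_label": node_labels, "label": tpl.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_table(path, key: str = "subject_id") -> pd.DataFrame:
    """Subjects x columns table keyed by subject_id."""
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_delimiter(path)).set_index(key)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
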