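"""Reading and writing the pipeline's plain-text formats.

Per-subject time series are delimited text (comma for ``.csv``, tab for
``.tsv``/``.txt``), T rows x R columns, no header by default.  The label
table is a two-column CSV ``subject_id,label`` whose class names are
mapped to +1/-1 (the positive class is declared, and the mapping is
recorded in every output).  Region names are one label per line, line
order = region ordinal order.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import ROITimeSeries
from .exceptions import InvalidInputError
from .regions import RegionTable

__all__ = [
    "read_time_series",
    "write_time_series",
    "read_labels",
    "write_labels",
    "read_region_names",
    "write_region_names",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_time_series(path, *, header: bool = False, subject_id: str | None = None) -> ROITimeSeries:
    """Read one subject's T x R signal matrix; subject id defaults to the stem."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"time-series file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), header=0 if header else None)
    except (pd.errors.ParserError, ValueError) as exc:
        raise InvalidInputError(f"{path}: cannot parse as delimited text ({exc})") from exc
    values = frame.to_numpy(dtype=float)
    return ROITimeSeries(subject_id=subject_id or path.stem, signals=values)


def write_time_series(ts: ROITimeSeries, path) -> None:
    path = Path(path)
    np.savetxt(path, ts.signals, delimiter=_sep_for(path), fmt="%.10g")


def read_labels(
    path, *, positive_class: str | None = None
) -> tuple[dict[str, int], dict[str, str]]:
    """Read the subject→label CSV.

    Returns ``(labels, mapping)``: ``labels`` maps subject id to +1/-1 and
    ``mapping`` records which class name became which sign.  Exactly two
    class names must occur; with no declared positive class the
    lexicographically smaller name is positive (deterministic and
    recorded).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"label file not found: {path}")
    frame = pd.read_csv(path, dtype=str)
    required = {"subject_id", "label"}
    if not required <= set(frame.columns):
        raise InvalidInputError(
            f"{path}: label table needs columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    if frame["subject_id"].duplicated().any():
        dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
        raise InvalidInputError(f"{path}: duplicate subject id(s): {dupes}")
    classes = sorted(frame["label"].unique())
    if len(classes) != 2:
        raise InvalidInputError(
            f"{path}: expected exactly 2 class names, found {classes}"
        )
    if positive_class is None:
        positive_class = classes[0]
    if positive_class not in classes:
        raise InvalidInputError(
            f"{path}: declared positive class {positive_class!r} not among {classes}"
        )
    negative_class = next(c for c in classes if c != positive_class)
    sign = {positive_class: 1, negative_class: -1}
    labels = {
        str(row.subject_id): sign[row.label] for row in frame.itertuples(index=False)
    }
    return labels, {"positive": positive_class, "negative": negative_class}


def write_labels(labels: dict[str, int], path, *, mapping: dict[str, str] | None = None) -> None:
    """Write a label CSV; signs are rendered through ``mapping`` if given."""
    name = {1: "pos", -1: "neg"}
    if mapping:
        name = {1: mapping["positive"], -1: mapping["negative"]}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label"])
        for sid, lab in labels.items():
            writer.writerow([sid, name[int(lab)]])


def read_region_names(path) -> RegionTable:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"region-name file not found: {path}")
    return RegionTable.from_lines(path.read_text().splitlines())


def write_region_names(table: RegionTable | Sequence[str], path) -> None:
    names: Iterable[str] = table.names if isinstance(table, RegionTable) else table
    Path(path).write_text("\n".join(names) + "\n")
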