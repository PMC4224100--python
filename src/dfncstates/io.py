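"""Delimited-text and JSON I/O for timecourses, motion files, and matrices."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dfncstates.preprocess import MotionParams, SubjectTimecourses

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_motion",
    "write_motion",
    "write_matrix",
    "read_matrix",
    "write_json",
    "read_json",
]


class ParseError(ValueError):
    pass


def read_timecourses(path: str | Path, TR: float | None = None) -> SubjectTimecourses:
    """Read a T x C delimited text file with a header row of component IDs.

    TR comes from a JSON sidecar (``<stem>.json`` with key ``TR``) or the
    ``TR`` argument; the argument wins when both are present.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as err:
        raise ParseError(f"{path}: {err}") from err
    if df.empty or df.shape[1] < 1:
        raise ParseError(f"{path}: no data")
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(d, np.number) for d in df.dtypes]
        ].tolist()
        raise ParseError(f"{path}: non-numeric cells in columns {bad}")
    if TR is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            TR = json.loads(sidecar.read_text()).get("TR")
    if TR is None:
        TR = 1.5
    return SubjectTimecourses(
        values=body, TR=float(TR), component_ids=list(df.columns)
    )


def write_timecourses(path: str | Path, tc: SubjectTimecourses) -> None:
    df = pd.DataFrame(tc.values, columns=tc.component_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    Path(path).with_suffix(".json").write_text(json.dumps({"TR": tc.TR}))


def read_motion(path: str | Path) -> MotionParams:
    arr = pd.read_csv(
        path, sep="\t", header=None, float_precision="round_trip"
    ).to_numpy(dtype=float)
    return MotionParams(values=arr)


def write_motion(path: str | Path, motion: np.ndarray | MotionParams) -> None:
    values = motion.values if isinstance(motion, MotionParams) else motion
    pd.DataFrame(values).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.17g"
    )


def write_matrix(path: str | Path, m: np.ndarray, names: list[str] | None = None) -> None:
    df = pd.DataFrame(m, columns=names)
    df.to_csv(
        path, sep="\t", index=False, header=names is not None,
        float_format="%.17g",
    )


def read_matrix(path: str | Path, header: bool = False) -> np.ndarray:
    return pd.read_csv(
        path, sep="\t", header=0 if header else None,
        float_precision="round_trip",
    ).to_numpy(dtype=float)


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
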