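"""Trajectory-table and results IO.

All tables are comma-delimited text with a header row; run metadata is a
JSON record carrying the configuration, the seed and the package
version, so every output is reproducible from its sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectories import Trajectory

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("frame", "id", "x", "y", "z")


class MissingColumnError(ValueError):
    """The trajectory table lacks one of the required columns."""


class NonNumericDataError(ValueError):
    """A coordinate or frame cell could not be parsed as a number."""


class DuplicateRecordError(ValueError):
    """The table contains more than one row for a (frame, id) pair."""


def read_trajectory_table(
    path: str | Path, frame_rate: float | None = None
) -> list[Trajectory]:
    """Read a delimited trajectory table into per-individual trajectories.

    Expects header columns ``frame, id, x, y, z`` (extra columns are
    ignored).  Rows are grouped by id; out-of-order frames are sorted
    with a warning; duplicated (frame, id) pairs are an error.  The frame
    rate is taken from the argument, else from a ``<path>.meta.json``
    sidecar, else defaults to 15 fps.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    numeric = df[list(REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric[["frame", "x", "y", "z"]].isna() & df[["frame", "x", "y", "z"]].notna()
    if bad.any().any() or numeric[["frame", "x", "y", "z"]].isna().any().any():
        rows = np.nonzero(numeric[["frame", "x", "y", "z"]].isna().any(axis=1).values)[0]
        raise NonNumericDataError(
            f"{path}: non-numeric or missing cell(s) in data row(s) {rows[:5].tolist()}"
        )
    if df.duplicated(subset=["frame", "id"]).any():
        dup = df[df.duplicated(subset=["frame", "id"])].iloc[0]
        raise DuplicateRecordError(
            f"{path}: duplicated (frame, id) pair ({int(dup['frame'])}, {dup['id']})"
        )
    if frame_rate is None:
        sidecar = path.with_name(path.name + ".meta.json")
        if sidecar.exists():
            frame_rate = json.loads(sidecar.read_text()).get("frame_rate", 15.0)
        else:
            frame_rate = 15.0
    trajectories = []
    for ind_id, group in df.groupby("id", sort=True):
        frames = numeric.loc[group.index, "frame"].to_numpy()
        if not np.all(np.diff(frames) > 0):
            logger.warning("id %r: out-of-order frames; sorting", ind_id)
            order = np.argsort(frames, kind="stable")
            group = group.iloc[order]
            frames = frames[order]
        trajectories.append(
            Trajectory(
                individual_id=ind_id,
                frame_rate=float(frame_rate),
                frames=frames.astype(int),
                positions=numeric.loc[group.index, ["x", "y", "z"]].to_numpy(),
            )
        )
    return trajectories


def write_trajectory_table(
    path: str | Path, trajs: Sequence[Trajectory], force: bool = False
) -> Path:
    """Write trajectories as a frame,id,x,y,z table (>= 10 significant digits)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    parts = [
        pd.DataFrame(
            {
                "frame": t.frames,
                "id": t.individual_id,
                "x": t.positions[:, 0],
                "y": t.positions[:, 1],
                "z": t.positions[:, 2],
            }
        )
        for t in trajs
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, float_format="%.12g")
    return path


def write_results(
    out_dir: str | Path,
    tables: Mapping[str, pd.DataFrame],
    metadata: Mapping,
    force: bool = False,
) -> dict[str, Path]:
    """Write named tables as CSV plus a metadata.json record.

    Numeric formatting keeps 12 significant digits; existing files are
    refused unless ``force`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    targets = {name: out_dir / f"{name}.csv" for name in tables}
    targets["metadata"] = out_dir / "metadata.json"
    for name, target in targets.items():
        if target.exists() and not force:
            raise FileExistsError(f"{target} exists; pass force=True to overwrite")
    for name, table in tables.items():
        table.to_csv(targets[name], index=False, float_format="%.12g")
        paths[name] = targets[name]
    targets["metadata"].write_text(json.dumps(_jsonable(metadata), indent=2))
    paths["metadata"] = targets["metadata"]
    return paths


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
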