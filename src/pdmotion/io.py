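"""Plain-text readers and writers for trajectories, feature tables and configs.

Trajectory files are long-format delimited UTF-8 text.  Each record starts
with a ``#``-prefixed header block carrying the video metadata, followed by
a column line and one row per (frame, keypoint):

    # participant_id: P000
    # assessment_index: 1
    # task: FTN
    # side: right
    # fps: 30
    # sma_score: 0
    frame,keypoint,x,y,z
    0,hip,0.5,0.9,2.0
    ...

Multiple records may be concatenated in one file.  Frames are 0-based and
must be contiguous per keypoint.  Floats are written with 17 significant
digits so a write→read round trip is exact.
"""

from __future__ import annotations

import logging
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .modeling import FeatureTable
from .simulate import LabeledTrajectorySet, SimConfig, TASKS

logger = logging.getLogger(__name__)

_HEADER_FIELDS = ("participant_id", "assessment_index", "task", "side", "fps", "sma_score")
_COLUMNS = "frame,keypoint,x,y,z"


class TrajectoryParseError(ValueError):
    """Raised with a file position when a trajectory file is malformed."""


def write_trajectories(trajectories: list[LabeledTrajectorySet], path) -> None:
    """Write one or more trajectory records to a single delimited text file."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in trajectories:
            fh.write(f"# participant_id: {t.participant_id}\n")
            fh.write(f"# assessment_index: {t.assessment_index}\n")
            fh.write(f"# task: {t.task}\n")
            fh.write(f"# side: {t.side}\n")
            fh.write(f"# fps: {t.fps!r}\n")
            fh.write(f"# sma_score: {t.sma_score}\n")
            fh.write(_COLUMNS + "\n")
            for name in t.trajectories:
                xyz = t.trajectories[name]
                for i in range(len(xyz)):
                    fh.write(
                        f"{i},{name},{xyz[i, 0]:.17g},{xyz[i, 1]:.17g},{xyz[i, 2]:.17g}\n"
                    )


def _finalize_record(header: dict, data: dict, start_line: int) -> LabeledTrajectorySet:
    for f in _HEADER_FIELDS:
        if f not in header:
            raise TrajectoryParseError(
                f"record starting at line {start_line}: missing header field '{f}'"
            )
    task = header["task"]
    if task not in TASKS:
        raise TrajectoryParseError(
            f"record starting at line {start_line}: unknown task {task!r}"
        )
    trajectories = {}
    for name, rows in data.items():
        frames = [r[0] for r in rows]
        if frames != list(range(len(frames))):
            raise TrajectoryParseError(
                f"record starting at line {start_line}: non-contiguous frames for "
                f"keypoint '{name}'"
            )
        trajectories[name] = np.array([r[1] for r in rows], dtype=float)
    return LabeledTrajectorySet(
        trajectories=trajectories,
        fps=float(header["fps"]),
        task=task,
        side=header["side"],
        participant_id=header["participant_id"],
        assessment_index=int(header["assessment_index"]),
        sma_score=int(header["sma_score"]),
    )


def read_trajectories(path) -> list[LabeledTrajectorySet]:
    """Parse a trajectory file written by :func:`write_trajectories`.

    An empty file yields an empty list with a logged warning; malformed
    content raises :class:`TrajectoryParseError` with a line number.
    """
    path = Path(path)
    records: list[LabeledTrajectorySet] = []
    header: dict = {}
    data: dict[str, list] = {}
    in_data = False
    start_line = 1
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if in_data:  # a new record begins
                    records.append(_finalize_record(header, data, start_line))
                    header, data, in_data = {}, {}, False
                    start_line = lineno
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError:
                    raise TrajectoryParseError(f"line {lineno}: malformed header line {line!r}")
                header[key.strip()] = value.strip()
                continue
            if line == _COLUMNS:
                in_data = True
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise TrajectoryParseError(f"line {lineno}: expected 5 fields, got {len(parts)}")
            try:
                frame = int(parts[0])
                xyz = (float(parts[2]), float(parts[3]), float(parts[4]))
            except ValueError:
                raise TrajectoryParseError(f"line {lineno}: could not parse numeric fields")
            data.setdefault(parts[1], []).append((frame, xyz))
            in_data = True
    if header or data:
        records.append(_finalize_record(header, data, start_line))
    if not records:
        logger.warning("no trajectory records in %s", path)
    return records


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a FeatureTable as delimited text (missing values as empty fields)."""
    path = Path(path)
    df = table.features.copy()
    df.insert(0, "participant_id", table.participants)
    df.insert(1, "label", table.labels)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# task: {table.task}\n")
        df.to_csv(fh, index_label="video_id", float_format="%.17g", lineterminator="\n")


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# task:"):
            raise ValueError(f"{path}: missing '# task:' header line")
        task = first.split(":", 1)[1].strip()
        df = pd.read_csv(fh, index_col="video_id", float_precision="round_trip")
    participants = df.pop("participant_id")
    labels = df.pop("label")
    return FeatureTable(features=df, labels=labels, participants=participants, task=task)


def load_sim_config(path) -> SimConfig:
    """Read a SimConfig from a YAML file whose keys are the config fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dc_fields(SimConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "segment_lengths" in raw:
        raw["segment_lengths"] = tuple(raw["segment_lengths"])
    return SimConfig(**raw)
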