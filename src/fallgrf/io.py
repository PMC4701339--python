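"""Plain-text cohort and table formats.

A cohort directory holds ``metadata.tsv`` (subject_id, group, weight_kg) and
one CSV per recording named ``<subject_id>_<activity>_<foot>_<axis>.csv`` with
columns ``t_index, force``. A single long-format table
(``cohort_long.tsv``) is supported as an alternative for pipelines that
prefer one file. Feature matrices travel as TSV with the eight canonical
entropy columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import FEATURE_NAMES, GrfRecording, Subject
from .exceptions import ParameterError

METADATA_FILE = "metadata.tsv"
LONG_FILE = "cohort_long.tsv"


def write_cohort(subjects: list[Subject], directory, long_format: bool = False) -> Path:
    """Write a cohort directory; returns its path.

    ``long_format=True`` additionally writes the single long-format TSV.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        [{"subject_id": s.subject_id, "group": s.group, "weight_kg": s.weight_kg}
         for s in subjects]
    )
    meta.to_csv(directory / METADATA_FILE, sep="\t", index=False)
    long_rows = []
    for s in subjects:
        for rec in s.recordings:
            name = f"{s.subject_id}_{rec.activity}_{rec.foot}_{rec.axis}.csv"
            frame = pd.DataFrame({
                "t_index": np.arange(rec.series.size), "force": rec.series,
            })
            frame.to_csv(directory / name, index=False)
            if long_format:
                frame = frame.assign(
                    subject_id=s.subject_id, activity=rec.activity,
                    foot=rec.foot, axis=rec.axis,
                )
                long_rows.append(frame)
    if long_format:
        pd.concat(long_rows, ignore_index=True)[
            ["subject_id", "activity", "foot", "axis", "t_index", "force"]
        ].to_csv(directory / LONG_FILE, sep="\t", index=False)
    return directory


def _subjects_from_meta(meta: pd.DataFrame) -> dict[str, Subject]:
    subjects = {}
    for row in meta.itertuples(index=False):
        subjects[str(row.subject_id)] = Subject(
            subject_id=str(row.subject_id), group=str(row.group),
            weight_kg=float(row.weight_kg),
        )
    return subjects


def read_cohort(directory) -> list[Subject]:
    """Read a cohort directory written by :func:`write_cohort`.

    Prefers the per-recording CSV layout; falls back to the long-format file.
    Subject order follows the metadata table.
    """
    directory = Path(directory)
    meta_path = directory / METADATA_FILE
    if not meta_path.exists():
        raise ParameterError(f"no {METADATA_FILE} in {directory}")
    meta = pd.read_csv(meta_path, sep="\t")
    subjects = _subjects_from_meta(meta)

    csv_files = sorted(
        p for p in directory.glob("*.csv") if p.name != METADATA_FILE
    )
    if csv_files:
        for path in csv_files:
            stem = path.stem
            try:
                sid, activity, foot, axis = stem.rsplit("_", 3)
            except ValueError:
                raise ParameterError(f"unrecognized recording filename {path.name!r}")
            if sid not in subjects:
                raise ParameterError(f"recording {path.name!r} has unknown subject")
            frame = pd.read_csv(path)
            subjects[sid].recordings.append(GrfRecording(
                subject_id=sid, activity=activity, foot=foot, axis=axis,
                series=frame["force"].to_numpy(dtype=float),
            ))
    elif (directory / LONG_FILE).exists():
        long = pd.read_csv(directory / LONG_FILE, sep="\t")
        for (sid, activity, foot, axis), block in long.groupby(
            ["subject_id", "activity", "foot", "axis"], sort=True
        ):
            sid = str(sid)
            if sid not in subjects:
                raise ParameterError(f"long-format row has unknown subject {sid!r}")
            block = block.sort_values("t_index")
            subjects[sid].recordings.append(GrfRecording(
                subject_id=sid, activity=str(activity), foot=str(foot),
                axis=str(axis), series=block["force"].to_numpy(dtype=float),
            ))
    else:
        raise ParameterError(f"no recordings found in {directory}")
    return list(subjects.values())


def write_features(features: pd.DataFrame, path) -> Path:
    """Write a feature table as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, sep="\t", index=False)
    return path


def read_features(path) -> pd.DataFrame:
    """Read a feature TSV, checking the canonical entropy columns exist."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject_id", "group", *FEATURE_NAMES)
               if c not in frame.columns]
    if missing:
        raise ParameterError(f"feature table missing columns: {missing}")
    return frame
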