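"""Reading and writing annotation JSON and long-format measurement CSV files.

Annotation files hold a list of per-measurement landmark objects under the
versioned schema tag ``maxdex-annotation-1``:

* ultrasound: ``{"schema": ..., "modality": "US", "patient_id", "rater_id",
  "repeat_index", "side", "arc_points": [[x, y], ...],
  "acromion_edge": [x, y]}``
* MRI: same identifiers with ``"modality": "MRI"`` and ``glenoid_x``,
  ``acromion_x``, ``humeral_lateral_x``.

Measurement tables are plain CSV with columns patient_id, sex, side,
rater_id, repeat_index, modality, value (plus any extras, e.g. ``true_*``
ground-truth columns from the simulator).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .geometry import InputError, MRILandmarks, Point2D, UltrasoundAnnotation
from .pipeline import REQUIRED_COLUMNS

SCHEMA = "maxdex-annotation-1"

Annotation = Union[UltrasoundAnnotation, MRILandmarks]

__all__ = [
    "SCHEMA",
    "read_annotations",
    "write_annotations",
    "read_measurements",
    "write_measurements",
]


def _annotation_from_dict(obj: dict) -> Annotation:
    if obj.get("schema") != SCHEMA:
        raise InputError(f"unsupported annotation schema {obj.get('schema')!r}")
    common = dict(
        side=obj["side"],
        patient_id=str(obj["patient_id"]),
        rater_id=str(obj["rater_id"]),
        repeat_index=int(obj["repeat_index"]),
    )
    modality = obj.get("modality")
    if modality == "US":
        return UltrasoundAnnotation(
            arc_points=tuple(Point2D(float(x), float(y)) for x, y in obj["arc_points"]),
            acromion_edge=Point2D(*map(float, obj["acromion_edge"])),
            **common,
        )
    if modality == "MRI":
        return MRILandmarks(
            glenoid_x=float(obj["glenoid_x"]),
            acromion_x=float(obj["acromion_x"]),
            humeral_lateral_x=float(obj["humeral_lateral_x"]),
            **common,
        )
    raise InputError(f"unknown modality {modality!r} in annotation file")


def _annotation_to_dict(ann: Annotation) -> dict:
    base = {
        "schema": SCHEMA,
        "patient_id": ann.patient_id,
        "rater_id": ann.rater_id,
        "repeat_index": ann.repeat_index,
        "side": ann.side,
    }
    if isinstance(ann, UltrasoundAnnotation):
        base["modality"] = "US"
        base["arc_points"] = [[p.x, p.y] for p in ann.arc_points]
        base["acromion_edge"] = [ann.acromion_edge.x, ann.acromion_edge.y]
    else:
        base["modality"] = "MRI"
        base["glenoid_x"] = ann.glenoid_x
        base["acromion_x"] = ann.acromion_x
        base["humeral_lateral_x"] = ann.humeral_lateral_x
    return base


def read_annotations(path: str | Path) -> list[Annotation]:
    """Load a list of annotations from a versioned JSON file."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [_annotation_from_dict(obj) for obj in data]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([_annotation_to_dict(a) for a in annotations], indent=2)
    )


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Load a long-format measurement CSV, checking the required columns."""
    df = pd.read_csv(path, dtype={"patient_id": str, "rater_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"measurement CSV missing columns: {missing}")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
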