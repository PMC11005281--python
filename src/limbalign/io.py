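"""Reading and writing landmark and angle tables.

Landmark tables are long-format CSV with columns
``image_id, side, landmark, x, y, spacing_mm`` (one row per landmark,
``landmark`` in v1..v10, ``spacing_mm`` blank when unknown), or an
equivalent JSON layout keyed by image then side.  Angle tables are one
row per limb: ``image_id, side, hka, jcla, ama, mldfa, mmpta, alignment``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    LANDMARK_NAMES,
    AlignmentAngles,
    LimbLandmarks,
    Point2D,
    classify_alignment,
)

__all__ = [
    "read_landmark_csv",
    "write_landmark_csv",
    "read_landmark_json",
    "write_landmark_json",
    "write_angle_csv",
    "read_angle_csv",
]

LANDMARK_COLUMNS = ["image_id", "side", "landmark", "x", "y", "spacing_mm"]
ANGLE_COLUMNS = ["image_id", "side", "hka", "jcla", "ama", "mldfa", "mmpta", "alignment"]


def write_landmark_csv(limbs, path: str | Path) -> None:
    """Write [(image_id, LimbLandmarks), ...] to the long-format CSV."""
    rows = []
    for image_id, lm in limbs:
        for name in LANDMARK_NAMES:
            p = lm.point(name)
            rows.append(
                {
                    "image_id": image_id,
                    "side": lm.side,
                    "landmark": name,
                    "x": p.x,
                    "y": p.y,
                    "spacing_mm": lm.pixel_spacing_mm,
                }
            )
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmark_csv(path: str | Path, strict: bool = False):
    """Read the long-format CSV into {(image_id, side): LimbLandmarks}.

    Limbs with missing/duplicate landmarks or invalid geometry are skipped
    with their keys collected separately (``strict=True`` raises instead).
    Returns ``(limbs, skipped)``.
    """
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    limbs: dict[tuple[str, str], LimbLandmarks] = {}
    skipped: list[tuple[tuple[str, str], str]] = []
    for (image_id, side), grp in df.groupby(["image_id", "side"], sort=False):
        key = (str(image_id), str(side))
        try:
            by_name = dict(zip(grp["landmark"], zip(grp["x"], grp["y"])))
            if set(by_name) != set(LANDMARK_NAMES) or len(grp) != 10:
                raise ValueError(
                    f"expected exactly v1..v10, got {sorted(grp['landmark'])}"
                )
            spacing = None
            if "spacing_mm" in grp.columns:
                vals = grp["spacing_mm"].dropna().unique()
                if len(vals) > 1:
                    raise ValueError("inconsistent spacing_mm within one limb")
                if len(vals) == 1:
                    spacing = float(vals[0])
            pts = {
                n: Point2D(float(by_name[n][0]), float(by_name[n][1]))
                for n in LANDMARK_NAMES
            }
            limbs[key] = LimbLandmarks(side=key[1], pixel_spacing_mm=spacing, **pts)
        except Exception as exc:
            if strict:
                raise
            skipped.append((key, str(exc)))
    return limbs, skipped


def write_landmark_json(limbs, path: str | Path) -> None:
    """JSON equivalent of the landmark table, keyed image_id -> side."""
    doc: dict = {}
    for image_id, lm in limbs:
        entry = doc.setdefault(str(image_id), {})
        entry[lm.side] = {
            "spacing_mm": lm.pixel_spacing_mm,
            "landmarks": {n: [lm.point(n).x, lm.point(n).y] for n in LANDMARK_NAMES},
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_landmark_json(path: str | Path):
    doc = json.loads(Path(path).read_text())
    limbs = {}
    for image_id, sides in doc.items():
        for side, entry in sides.items():
            pts = {
                n: Point2D(*map(float, entry["landmarks"][n])) for n in LANDMARK_NAMES
            }
            limbs[(image_id, side)] = LimbLandmarks(
                side=side, pixel_spacing_mm=entry.get("spacing_mm"), **pts
            )
    return limbs


def write_angle_csv(angles: dict, path: str | Path) -> None:
    """Write {(image_id, side): AlignmentAngles} to the per-limb CSV."""
    rows = []
    for (image_id, side), a in angles.items():
        rows.append(
            {
                "image_id": image_id,
                "side": side,
                **a.as_dict(),
                "alignment": classify_alignment(a.hka).value,
            }
        )
    pd.DataFrame(rows, columns=ANGLE_COLUMNS).to_csv(path, index=False)


def read_angle_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ANGLE_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"angle CSV missing columns: {sorted(missing)}")
    return df
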