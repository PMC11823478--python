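"""Yaw-angle scoring of fitted navigation lines against reference lines.

The yaw angle between a fitted and an annotated line is the acute angle
between their direction vectors (line directions are sign-ambiguous, so
the cosine is folded with an absolute value).  Aggregates over a record
set are

* MEA  — mean yaw angle (degrees),
* RMSE — root mean square of the yaw angles (degrees),
* MRE  — mean relative error of the fitted vs. annotated angles taken
  against the image-bottom horizontal (percent).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateError, InvalidInputError
from .geometry import Line


@dataclass(frozen=True)
class Annotation:
    """A manually annotated reference line for one image."""

    image_id: str
    x1: float
    y1: float
    x2: float
    y2: float

    def to_line(self, height: int | None = None) -> Line:
        return Line.from_endpoints((self.x1, self.y1), (self.x2, self.y2), height=height)


@dataclass
class EvalRecord:
    image_id: str
    yaw_deg: float
    angle_fit_deg: float
    angle_ann_deg: float


def yaw_angle(line1: Line, line2: Line) -> float:
    """Acute angle between two lines, in [0, 90] degrees."""
    v1 = np.asarray(line1.direction, dtype=np.float64)
    v2 = np.asarray(line2.direction, dtype=np.float64)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateError("zero-length direction vector")
    c = abs(float(np.dot(v1, v2))) / (n1 * n2)
    return math.degrees(math.acos(min(c, 1.0)))


def make_record(image_id: str, fitted: Line, annotation: Annotation) -> EvalRecord:
    ref = annotation.to_line(height=fitted.height)
    return EvalRecord(
        image_id=image_id,
        yaw_deg=yaw_angle(fitted, ref),
        angle_fit_deg=fitted.angle_deg,
        angle_ann_deg=ref.angle_deg,
    )


def aggregate_metrics(records: list[EvalRecord]) -> dict:
    """MEA, RMSE (degrees) and MRE (percent) over a record set.

    Records with a zero annotated angle are excluded from MRE with a
    warning (the relative error is undefined there).
    """
    if not records:
        raise InvalidInputError("need at least one record")
    yaw = np.array([r.yaw_deg for r in records], dtype=np.float64)
    mea = float(yaw.mean())
    rmse = float(np.sqrt((yaw ** 2).mean()))
    rel = []
    for r in records:
        if r.angle_ann_deg == 0.0:
            warnings.warn(f"{r.image_id}: annotated angle is 0; excluded from MRE",
                          stacklevel=2)
            continue
        rel.append(abs(r.angle_fit_deg - r.angle_ann_deg) / abs(r.angle_ann_deg))
    mre = float(np.mean(rel) * 100.0) if rel else 0.0
    return {"n": len(records), "MEA_deg": mea, "RMSE_deg": rmse, "MRE_pct": mre}


def read_annotations(path: str | Path) -> dict[str, Annotation]:
    """Read JSON-Lines annotations: {"image", "x1", "y1", "x2", "y2"} per line."""
    out: dict[str, Annotation] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw:
                continue
            rec = json.loads(raw)
            ann = Annotation(image_id=str(rec["image"]), x1=float(rec["x1"]),
                             y1=float(rec["y1"]), x2=float(rec["x2"]), y2=float(rec["y2"]))
            if (ann.x1, ann.y1) == (ann.x2, ann.y2):
                raise InvalidInputError(f"{ann.image_id}: annotation endpoints coincide")
            out[ann.image_id] = ann
    return out


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            d = asdict(ann)
            d["image"] = d.pop("image_id")
            fh.write(json.dumps(d) + "\n")


def format_report(metrics: dict, records: list[EvalRecord]) -> str:
    """Human-readable metrics table."""
    lines = [
        f"{'image':<28s} {'yaw':>8s} {'fit':>8s} {'ann':>8s}",
        "-" * 56,
    ]
    for r in records:
        lines.append(f"{r.image_id:<28s} {r.yaw_deg:8.3f} "
                     f"{r.angle_fit_deg:8.3f} {r.angle_ann_deg:8.3f}")
    lines.append("-" * 56)
    lines.append(f"n={metrics['n']}  MEA={metrics['MEA_deg']:.3f} deg  "
                 f"RMSE={metrics['RMSE_deg']:.3f} deg  MRE={metrics['MRE_pct']:.3f} %")
    return "\n".join(lines)
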