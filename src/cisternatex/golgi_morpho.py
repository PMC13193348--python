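"""Golgi cisterna morphometry from EM traces.

Curvature: traced edge points are joined by a cubic B-spline
(chord-length parameterised, interpolating by default since traces are
human-smoothed already) and the unsigned curvature
kappa = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2) is averaged uniformly over
arc length.

Width: the "integrated distance" between the two traced edges of a
cisterna — the mean of shortest point-to-polyline distances from samples
uniformly spaced along the shorter edge to the longer edge; its max-min
spread is the diameter range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep
from shapely.geometry import LineString, Point


@dataclass
class Trace:
    """Ordered trace points (nm) with grouping metadata."""

    points: np.ndarray
    role: str = "edge"
    stack_id: str | None = None
    cisterna_index: int | None = None
    condition: str | None = None
    unit: str = "nm"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("trace points must be (N, 2)")

    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))


def _dedup(points: np.ndarray) -> np.ndarray:
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(np.diff(points, axis=0) != 0, axis=1)
    return points[keep]


@dataclass
class BSplineCurve:
    """Parametric spline wrapper evaluable with derivatives."""

    tck: tuple
    u: np.ndarray

    def evaluate(self, t, der: int = 0) -> np.ndarray:
        x, y = splev(np.asarray(t, dtype=float), self.tck, der=der)
        return np.column_stack([x, y])


def fit_bspline(points, degree: int = 3, smoothing: float = 0.0) -> BSplineCurve:
    """Fit a chord-length-parameterised B-spline through trace points.

    smoothing=0 interpolates the points exactly (traces are already
    human-smoothed); larger values fit an approximating spline.
    """
    pts = _dedup(np.asarray(points, dtype=float))
    if len(pts) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct points for a degree-"
            f"{degree} spline, got {len(pts)}")
    tck, u = splprep([pts[:, 0], pts[:, 1]], k=degree, s=smoothing)
    return BSplineCurve(tck=tck, u=np.asarray(u))


@dataclass
class CurvatureResult:
    mean_abs_curvature: float  # nm^-1
    arc_length: float          # nm


def mean_curvature(curve: BSplineCurve, n_samples: int = 200) -> CurvatureResult:
    """Mean |kappa| sampled uniformly in arc length along the curve."""
    t_dense = np.linspace(0.0, 1.0, max(8 * n_samples, 800))
    p = curve.evaluate(t_dense)
    seg = np.hypot(*np.diff(p, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate zero-length curve")
    t_uniform = np.interp(np.linspace(0.0, total, n_samples), s, t_dense)
    d1 = curve.evaluate(t_uniform, der=1)
    d2 = curve.evaluate(t_uniform, der=2)
    speed2 = (d1 ** 2).sum(axis=1)
    ok = speed2 > 1e-12 * speed2.max()
    if not ok.all():
        warnings.warn("zero-speed parameter points skipped", stacklevel=2)
    num = np.abs(d1[ok, 0] * d2[ok, 1] - d1[ok, 1] * d2[ok, 0])
    kappa = num / speed2[ok] ** 1.5
    return CurvatureResult(mean_abs_curvature=float(kappa.mean()),
                           arc_length=float(total))


@dataclass
class WidthProfile:
    distances: np.ndarray  # nm, one per sample on the shorter edge
    mean_width: float
    width_range: float     # max - min


def integrated_distance(trace_a: Trace, trace_b: Trace,
                        n_samples: int = 100) -> WidthProfile:
    """Shortest-distance width profile between two traced edges.

    The shorter polyline (by arc length) is sampled at n_samples uniformly
    spaced points (endpoints included); each sample's minimum distance to
    the longer polyline is recorded.  Argument order is irrelevant.
    """
    for t in (trace_a, trace_b):
        if len(t.points) < 2:
            raise ValueError("polylines need at least 2 points")
        if t.arc_length() == 0:
            raise ValueError("degenerate zero-length polyline")
    if trace_a.arc_length() <= trace_b.arc_length():
        shorter, longer = trace_a, trace_b
    else:
        shorter, longer = trace_b, trace_a
    line_s = LineString(shorter.points)
    line_l = LineString(longer.points)
    ds = np.linspace(0.0, line_s.length, n_samples)
    dist = np.array([line_s.interpolate(d).distance(line_l) for d in ds])
    return WidthProfile(distances=dist, mean_width=float(dist.mean()),
                        width_range=float(dist.max() - dist.min()))


def cisterna_measurements(edge_a: Trace, edge_b: Trace,
                          n_samples: int = 100,
                          curvature_samples: int = 200) -> dict:
    """Width and curvature of one cisterna from its traced edge pair.

    Curvature is the average of the two edge curvatures (equal to the
    centerline curvature to second order in width/radius).
    """
    if edge_a.unit != edge_b.unit:
        raise ValueError("mixed units in trace pair")
    wp = integrated_distance(edge_a, edge_b, n_samples=n_samples)
    ks = [mean_curvature(fit_bspline(t.points), n_samples=curvature_samples)
          for t in (edge_a, edge_b)]
    return {"stack_id": edge_a.stack_id,
            "condition": edge_a.condition,
            "cisterna_index": edge_a.cisterna_index,
            "mean_width": wp.mean_width,
            "width_range": wp.width_range,
            "mean_curvature": float(np.mean([k.mean_abs_curvature
                                             for k in ks])),
            "arc_length": float(np.mean([k.arc_length for k in ks])),
            "unit": edge_a.unit}


def stack_summary(rows) -> pd.DataFrame:
    """Per-stack aggregates: mean cisternal width, mean diameter range and
    mean curvature, feeding the group statistics."""
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("empty stack: no cisterna measurements")
    if "unit" in df.columns and df["unit"].nunique() > 1:
        raise ValueError("mixed units across traces")
    out = (df.groupby(["stack_id"], dropna=False)
             .agg(condition=("condition", "first"),
                  n_cisternae=("mean_width", "size"),
                  mean_width=("mean_width", "mean"),
                  width_range=("width_range", "mean"),
                  mean_curvature=("mean_curvature", "mean"))
             .reset_index())
    return out


# -- trace IO ---------------------------------------------------------------

def traces_from_json(obj, pixel_size_nm: float = 1.0) -> list:
    """Load traces from a JSON-decoded list of records with ``points``
    (pixel or nm) and optional metadata; coordinates are scaled by
    ``pixel_size_nm``."""
    out = []
    for rec in obj:
        pts = np.asarray(rec["points"], dtype=float) * pixel_size_nm
        out.append(Trace(points=pts, role=rec.get("role", "edge"),
                         stack_id=rec.get("stack_id"),
                         cisterna_index=rec.get("cisterna_index"),
                         condition=rec.get("condition")))
    return out
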