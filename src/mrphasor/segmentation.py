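"""Phasor-space region selection and back-projection to image masks.

Regions of interest are simple polygons drawn in (Re, Im) coordinates; pixels
whose phasor falls inside a polygon are assigned that region's label.  The
assignment is a pure function of the phasor coordinates, so pixels anywhere
in the image with the same decay shape end up in the same segment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phasor_core import PhasorField, SignalStack

__all__ = [
    "PhasorROI",
    "SegmentMap",
    "segment_phasors",
    "mean_signal_per_segment",
    "backproject",
    "rois_to_json",
    "rois_from_json",
]

_BOUNDARY_EPS = 1e-12  # tolerance for the on-edge test (boundary is inside)

_DEFAULT_COLORS = ("red", "yellow", "green", "blue", "magenta", "cyan", "orange")


@dataclass(frozen=True)
class PhasorROI:
    """A labeled polygon in phasor space."""

    polygon: np.ndarray  # (n_vertices, 2)
    label: str
    color: str = "red"

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon must be an (n>=3, 2) vertex array")
        if not np.all(np.isfinite(poly)):
            raise ValueError("polygon vertices must be finite")
        if _self_intersects(poly):
            raise ValueError(f"ROI {self.label!r}: polygon is self-intersecting")
        object.__setattr__(self, "polygon", poly)
        poly.setflags(write=False)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Even-odd (ray casting) containment test, boundary inclusive."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = pts[:, 0], pts[:, 1]
        inside = np.zeros(len(pts), dtype=bool)
        on_edge = np.zeros(len(pts), dtype=bool)
        poly = self.polygon
        scale = max(np.abs(poly).max(), 1.0)
        eps = _BOUNDARY_EPS * scale
        n = poly.shape[0]
        for i in range(n):
            x1, y1 = poly[i]
            x2, y2 = poly[(i + 1) % n]
            cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
            within = ((np.minimum(x1, x2) - eps <= x) & (x <= np.maximum(x1, x2) + eps)
                      & (np.minimum(y1, y2) - eps <= y) & (y <= np.maximum(y1, y2) + eps))
            on_edge |= (np.abs(cross) <= eps * scale) & within
            crosses = (y1 > y) != (y2 > y)
            if crosses.any():
                with np.errstate(divide="ignore", invalid="ignore"):
                    x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                inside ^= crosses & (x < x_int)
        return inside | on_edge


def _self_intersects(poly: np.ndarray) -> bool:
    """O(n^2) proper-crossing test between non-adjacent edges."""
    n = poly.shape[0]
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (1, n - 1):  # adjacent edges share a vertex
                continue
            p1, p2 = edges[i]
            q1, q2 = edges[j]
            d1, d2 = cross(p1, p2, q1), cross(p1, p2, q2)
            d3, d4 = cross(q1, q2, p1), cross(q1, q2, p2)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return True
    return False


@dataclass
class SegmentMap:
    """Per-pixel integer segment labels; 0 means unassigned."""

    labels: np.ndarray
    legend: dict  # int label -> {"label": str, "color": str}

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def counts(self) -> dict:
        return {k: int((self.labels == k).sum()) for k in self.legend}


def segment_phasors(field: PhasorField, rois) -> SegmentMap:
    """Assign each valid pixel to the first ROI containing its phasor.

    Overlapping ROIs are resolved by ROI order (first match wins); a warning
    reports the overlap fraction when ROIs overlap on actual pixels.
    """
    rois = list(rois)
    if not rois:
        raise ValueError("need at least one ROI")
    pts = np.stack([field.re, field.im], axis=-1)
    flat = pts.reshape(-1, 2)
    finite = np.all(np.isfinite(flat), axis=1) & field.valid.ravel()

    labels = np.zeros(flat.shape[0], dtype=int)
    hits = np.zeros(flat.shape[0], dtype=int)
    legend = {}
    for k, roi in enumerate(rois, start=1):
        inside = np.zeros(flat.shape[0], dtype=bool)
        inside[finite] = roi.contains(flat[finite])
        hits += inside
        labels[inside & (labels == 0)] = k
        legend[k] = {"label": roi.label, "color": roi.color}
    overlap = (hits > 1).sum()
    if overlap:
        frac = overlap / max(int(finite.sum()), 1)
        warnings.warn(
            f"{overlap} pixels ({frac:.1%} of valid) fall in more than one ROI; "
            "assigned to the first matching ROI", stacklevel=2,
        )
    return SegmentMap(labels=labels.reshape(field.spatial_shape), legend=legend)


def mean_signal_per_segment(stack: SignalStack, seg: SegmentMap) -> pd.DataFrame:
    """Mean raw (unnormalized) signal per segment per non-spatial step.

    Returns a table with one row per defined segment label, a ``count``
    column, and one column per axis sample coordinate.  Empty segments give
    NaN rows with count 0.
    """
    if stack.spatial_shape != seg.labels.shape:
        raise ValueError("stack and segment map have inconsistent spatial shapes")
    flat = stack.data.reshape(-1, stack.axis.n)
    lab = seg.labels.ravel()
    rows = []
    for k, meta in seg.legend.items():
        sel = lab == k
        count = int(sel.sum())
        mean = flat[sel].mean(axis=0) if count else np.full(stack.axis.n, np.nan)
        rows.append({"label": k, "name": meta["label"], "count": count,
                     **{f"{v:g}": m for v, m in zip(stack.axis.values, mean)}})
    return pd.DataFrame(rows)


def backproject(
    seg: SegmentMap,
    background: np.ndarray | None = None,
    alpha: float = 0.6,
) -> np.ndarray:
    """Composite segment colors over a grayscale background image.

    Returns an RGB float array in [0, 1]; unassigned pixels show the
    background (black if none given).
    """
    from matplotlib.colors import to_rgb

    shape = seg.labels.shape
    if background is None:
        base = np.zeros(shape + (3,))
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != shape:
            raise ValueError("background shape must match the segment map")
        lo, hi = np.nanmin(bg), np.nanmax(bg)
        norm = (bg - lo) / (hi - lo) if hi > lo else np.zeros(shape)
        base = np.repeat(norm[..., None], 3, axis=-1)
    out = base.copy()
    for k, meta in seg.legend.items():
        m = seg.labels == k
        color = np.array(to_rgb(meta["color"]))
        out[m] = (1 - alpha) * base[m] + alpha * color
    return np.clip(out, 0.0, 1.0)


def rois_to_json(rois, path) -> None:
    payload = [
        {"label": r.label, "color": r.color, "vertices": np.asarray(r.polygon).tolist()}
        for r in rois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def rois_from_json(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    rois = []
    for i, entry in enumerate(payload):
        rois.append(PhasorROI(
            polygon=np.asarray(entry["vertices"], dtype=float),
            label=entry.get("label", f"roi{i + 1}"),
            color=entry.get("color", _DEFAULT_COLORS[i % len(_DEFAULT_COLORS)]),
        ))
    return rois
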