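"""Selection of the deepest-depression slice from an axial series.

For each slice the outer body contour is traced, an assistant tangent line is
drawn across the two anterior crests of the chest (one per hemithorax), and
the depression depth is the maximal perpendicular distance from the anterior
boundary to that line, measured posteriorly.  The slice with the largest
depth is the target; the severity indices are then measured on the target
slice and a small neighborhood around it.

Because the depth is measured against the crest tangent line rather than the
image axes, it is invariant to moderate in-plane rotation of the patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .errors import GeometryError, PectusError
from .geometry import Contour, trace_boundary
from .phantom import AxialSlice

__all__ = ["SliceSelectionResult", "outer_body_contour", "depression_depth",
           "select_target"]


@dataclass
class SliceSelectionResult:
    target_index: int
    per_slice_depth_cm: list[float]
    crest_left: list[tuple[float, float] | None]
    crest_right: list[tuple[float, float] | None]
    deepest_point: list[tuple[float, float] | None]
    neighborhood: list[int]
    flags: set = field(default_factory=set)


def outer_body_contour(slice_: AxialSlice, threshold: float | None = None) -> Contour:
    """Boundary of the body on an axial slice.

    The body is the largest connected component above an Otsu threshold
    (override with ``threshold``), with interior holes filled so the contour
    follows the outer surface only.
    """
    img = np.asarray(slice_.image, dtype=float)
    if threshold is None:
        if np.ptp(img) == 0:
            raise GeometryError("blank slice: no body region distinguishable")
        threshold = float(filters.threshold_otsu(img))
    fg = img > threshold
    labels, n = measure.label(fg, connectivity=2, return_num=True)
    if n == 0:
        raise GeometryError("no above-threshold component on slice")
    largest = 1 + int(np.argmax(np.bincount(labels.ravel())[1:]))
    body = ndimage.binary_fill_holes(labels == largest)
    return Contour(vertices=trace_boundary(body), spacing_mm=slice_.spacing_mm)


def depression_depth(
    outer: Contour,
) -> tuple[float, tuple[float, float], tuple[float, float], tuple[float, float] | None]:
    """Tangent-line depression depth of an outer body contour.

    Returns ``(depth_cm, crest_left, crest_right, deepest_point)`` with the
    points in (row, col) pixel coordinates.  The crests are the most anterior
    outer points of each hemithorax (split at the transverse centroid); the
    depth is the maximal perpendicular drop of the anterior boundary posterior
    of the crest-to-crest line, or 0 when the boundary never dips below it.
    """
    p = outer.physical()
    s = outer.spacing_cm
    x, y = p[:, 0], p[:, 1]
    xc = float(x.mean())
    left = x > xc
    right = x < xc
    if not left.any() or not right.any():
        raise GeometryError("contour does not span its transverse centroid")
    i_l = int(np.argmax(np.where(left, y, -np.inf)))
    i_r = int(np.argmax(np.where(right, y, -np.inf)))
    to_px = lambda i: (-y[i] / s, x[i] / s)
    crest_l, crest_r = to_px(i_l), to_px(i_r)
    if i_l == i_r:
        return 0.0, crest_l, crest_r, None

    # Anterior arc between the crests: of the two cyclic arcs, the one whose
    # vertices are on average more anterior.
    n = len(p)
    lo, hi = sorted((i_l, i_r))
    arc_a = np.arange(lo + 1, hi)
    arc_b = np.concatenate([np.arange(hi + 1, n), np.arange(0, lo)])
    if arc_a.size == 0 and arc_b.size == 0:
        return 0.0, crest_l, crest_r, None
    mean_y = lambda arc: y[arc].mean() if arc.size else -np.inf
    arc = arc_a if mean_y(arc_a) >= mean_y(arc_b) else arc_b

    p1, p2 = p[lo], p[hi]
    d = p2 - p1
    norm = float(np.hypot(*d))
    if norm == 0:
        return 0.0, crest_l, crest_r, None
    # Positive when the arc point lies posterior of the crest line.
    drop = (d[0] * (p1[1] - y[arc]) - d[1] * (p1[0] - x[arc])) / norm
    i_best = int(np.argmax(drop))
    depth = float(drop[i_best])
    if depth <= 0:
        return 0.0, crest_l, crest_r, None
    deepest = to_px(arc[i_best])
    return depth, crest_l, crest_r, deepest


def select_target(
    slices: list[AxialSlice],
    k: int = 3,
    literal_six: bool = False,
    threshold: float | None = None,
) -> SliceSelectionResult:
    """Pick the deepest-depression slice and its measurement neighborhood.

    The neighborhood spans ``target - k .. target + k`` clipped to the stack
    (7 slices by default, target included); with ``literal_six`` the target
    itself is excluded, leaving the six surrounding slices.  Depth ties are
    broken toward the smallest index and flagged.
    """
    if len(slices) == 0:
        raise PectusError("empty stack")
    depths: list[float] = []
    crest_l: list = []
    crest_r: list = []
    deepest: list = []
    flags: set[str] = set()
    for sl in slices:
        contour = outer_body_contour(sl, threshold=threshold)
        depth, cl, cr, dp = depression_depth(contour)
        depths.append(depth)
        crest_l.append(cl)
        crest_r.append(cr)
        deepest.append(dp)
    arr = np.asarray(depths)
    if arr.max() <= 0:
        raise GeometryError("no-depression: all per-slice depths are zero")
    top = np.flatnonzero(arr == arr.max())
    if top.size > 1:
        flags.add("depth-tie")
    target = int(top[0])
    window = [i for i in range(target - k, target + k + 1) if 0 <= i < len(slices)]
    if literal_six:
        window = [i for i in window if i != target]
    return SliceSelectionResult(
        target_index=target,
        per_slice_depth_cm=depths,
        crest_left=crest_l,
        crest_right=crest_r,
        deepest_point=deepest,
        neighborhood=window,
        flags=flags,
    )
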