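"""A-P midline, extraction strip and expression profile extraction.

Working on an oriented embryo (A-P axis horizontal, anterior left), the
midline is approximated by the morphological skeleton of the mask: five
equidistant knots are placed along the skeleton's main branch, a natural
cubic spline is drawn through them, and the curve is extended to the mask
borders with quadratic Lagrange extrapolation so it covers the whole A-P
axis.  A band spanning 10% of the D-V (minor) axis, centred on the curve,
defines the extraction strip; per-column channel means inside the strip
give the expression profile, from which the colorimetric stain signals are
computed (NBT/BCIP: red channel; FastRed: green minus red).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, lagrange
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import FlyStripError, ParameterError

__all__ = [
    "skeletonize",
    "main_branch",
    "equidistant_knots",
    "AxisSpline",
    "fit_axis_spline",
    "ExtractionStrip",
    "build_strip",
    "ExpressionProfile",
    "extract_profile",
    "stain_signal",
    "extract_from_oriented",
]

_SQRT2 = float(np.sqrt(2.0))


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """1-pixel-wide medial skeleton of a binary mask (values {0, 255})."""
    mask = np.asarray(mask)
    if not np.any(mask > 0):
        raise FlyStripError("cannot skeletonize an empty mask")
    return np.where(_sk_skeletonize(mask > 0), 255, 0).astype(np.uint8)


def _neighbors(p, pixels):
    r, c = p
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            q = (r + dr, c + dc)
            if q in pixels:
                yield q, _SQRT2 if dr and dc else 1.0


def _dijkstra(source, pixels):
    dist = {source: 0.0}
    prev = {}
    heap = [(0.0, source)]
    while heap:
        d, p = heapq.heappop(heap)
        if d > dist.get(p, np.inf):
            continue
        for q, w in _neighbors(p, pixels):
            nd = d + w
            if nd < dist.get(q, np.inf):
                dist[q] = nd
                prev[q] = p
                heapq.heappush(heap, (nd, q))
    return dist, prev


def main_branch(skeleton: np.ndarray) -> np.ndarray:
    """Longest geodesic endpoint-to-endpoint path of the skeleton.

    The skeleton is treated as an 8-connected pixel graph with Euclidean
    step weights (1 for axial, sqrt(2) for diagonal moves).  Endpoints are
    pixels with a single neighbour; the pair of endpoints with the largest
    geodesic distance defines the main branch.  A skeleton without
    endpoints (a cycle) falls back to the leftmost and rightmost skeleton
    pixels as termini.  The path is returned ordered left to right
    (anterior to posterior) as an ``(N, 2)`` array of (row, col).
    """
    skeleton = np.asarray(skeleton)
    rows, cols = np.nonzero(skeleton)
    if rows.size == 0:
        raise FlyStripError("empty skeleton")
    pixels = set(zip(rows.tolist(), cols.tolist()))
    if len(pixels) == 1:
        return np.array([next(iter(pixels))])
    endpoints = [p for p in pixels if sum(1 for _ in _neighbors(p, pixels)) == 1]
    if not endpoints:
        # cyclic skeleton: use extreme-x pixels as termini
        endpoints = [min(pixels, key=lambda p: p[1]), max(pixels, key=lambda p: p[1])]
    best = (-1.0, None, None, None)
    for src in endpoints:
        dist, prev = _dijkstra(src, pixels)
        far = max(endpoints, key=lambda p: dist.get(p, -1.0))
        d = dist.get(far, -1.0)
        if d > best[0]:
            best = (d, src, far, prev)
    _, src, far, prev = best
    if src is None or best[0] < 0:
        raise FlyStripError("skeleton endpoints are not connected")
    path = [far]
    while path[-1] != src:
        path.append(prev[path[-1]])
    path.reverse()
    if path[0][1] > path[-1][1]:
        path.reverse()
    return np.asarray(path, dtype=int)


def equidistant_knots(path: np.ndarray, k: int = 5) -> np.ndarray:
    """``k`` points at equal arc-length fractions 0, 1/(k-1), ..., 1 of a path.

    Returns an ``(k, 2)`` array of (row, col) path points; the first and
    last knot coincide with the path termini.
    """
    path = np.asarray(path, dtype=float)
    if k < 2:
        raise ParameterError("need at least 2 knots")
    if len(path) < k:
        raise FlyStripError(f"path of {len(path)} pixels is shorter than {k} knots")
    steps = np.hypot(*np.diff(path, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    targets = np.linspace(0.0, arc[-1], k)
    idx = np.searchsorted(arc, targets)
    idx = np.clip(idx, 0, len(arc) - 1)
    # snap to the nearer of the two bracketing path points
    for i, t in enumerate(targets):
        j = idx[i]
        if j > 0 and abs(arc[j - 1] - t) < abs(arc[j] - t):
            idx[i] = j - 1
    return path[idx].astype(int)


@dataclass
class AxisSpline:
    """Embryo midline: natural cubic spline through 5 knots, extended
    beyond the outer knots by the quadratic Lagrange polynomial through the
    3 nearest knots on each side.

    ``knots`` is an ``(k, 2)`` array of (x, y) = (col, row) pixel
    coordinates with strictly increasing x.
    """

    knots: np.ndarray
    _interior: CubicSpline
    _left: np.poly1d
    _right: np.poly1d

    def __call__(self, x) -> np.ndarray:
        """Midline y (row) coordinate at column(s) ``x``."""
        x = np.asarray(x, dtype=float)
        x0, x1 = self.knots[0, 0], self.knots[-1, 0]
        y = self._interior(np.clip(x, x0, x1))
        y = np.where(x < x0, self._left(x), y)
        y = np.where(x > x1, self._right(x), y)
        return y if y.shape else float(y)


def fit_axis_spline(knots: np.ndarray, mask: np.ndarray | None = None) -> AxisSpline:
    """Fit the midline spline through (row, col) knots.

    Knot x coordinates (columns) must be strictly increasing; duplicate x
    values raise an error.  ``mask`` is accepted for interface symmetry;
    the spline itself is evaluated lazily over any column range.
    """
    knots = np.asarray(knots, dtype=float)
    xy = knots[:, ::-1]  # (x, y) = (col, row)
    order = np.argsort(xy[:, 0])
    xy = xy[order]
    if np.any(np.diff(xy[:, 0]) <= 0):
        raise FlyStripError("knots must have strictly increasing x (duplicate columns?)")
    interior = CubicSpline(xy[:, 0], xy[:, 1], bc_type="natural")
    left = np.poly1d(lagrange(xy[:3, 0], xy[:3, 1]).coef)
    right = np.poly1d(lagrange(xy[-3:, 0], xy[-3:, 1]).coef)
    return AxisSpline(knots=xy, _interior=interior, _left=left, _right=right)


@dataclass
class ExtractionStrip:
    """The 10% D-V band around the midline.

    ``half_width`` is 5% of the minor-axis length (the mask's maximal
    vertical extent), so the full band spans 10%; ``col_range`` is the
    inclusive horizontal extent of the mask.
    """

    centreline: AxisSpline
    half_width: float
    col_range: tuple[int, int]
    minor_axis: float


def build_strip(
    spline: AxisSpline, mask: np.ndarray, band_fraction: float = 0.10
) -> ExtractionStrip:
    """Construct the extraction band for an oriented mask.

    The minor (D-V) axis length is measured as the mask's maximal vertical
    extent, exact for an embryo whose A-P axis is horizontal.
    """
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise FlyStripError("empty mask")
    col_any = np.flatnonzero(mask.any(axis=0))
    minor = float(rows.max() - rows.min() + 1)
    return ExtractionStrip(
        centreline=spline,
        half_width=0.5 * band_fraction * minor,
        col_range=(int(col_any[0]), int(col_any[-1])),
        minor_axis=minor,
    )


@dataclass
class ExpressionProfile:
    """Per-channel mean intensity along the A-P axis.

    ``positions`` are in percent egg length (0 = anterior, 100 =
    posterior), one sample per pixel column of the strip.
    """

    positions: np.ndarray
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return {"red": self.red, "green": self.green, "blue": self.blue}[name]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position_percent": self.positions,
                "red": self.red,
                "green": self.green,
                "blue": self.blue,
            }
        )
        df["nbt_signal"] = stain_signal(self, "NBT_BCIP")
        df["fastred_signal"] = stain_signal(self, "FastRed")
        return df


def extract_profile(brightfield: np.ndarray, strip: ExtractionStrip) -> ExpressionProfile:
    """Column-wise RGB means inside the strip.

    For every pixel column in the strip's range, the mean of each channel
    is taken over the rows within ``centreline(x) +- half_width`` (clipped
    to the image).  Column indices map linearly to percent egg length.
    """
    bf = np.asarray(brightfield)
    if bf.ndim != 3 or bf.shape[2] != 3:
        raise FlyStripError(f"expected an (H, W, 3) bright-field image, got {bf.shape}")
    c0, c1 = strip.col_range
    if c0 < 0 or c1 >= bf.shape[1]:
        raise FlyStripError("strip column range lies outside the image")
    cols = np.arange(c0, c1 + 1)
    centre = np.atleast_1d(strip.centreline(cols))
    lo = np.maximum(np.rint(centre - strip.half_width).astype(int), 0)
    hi = np.minimum(np.rint(centre + strip.half_width).astype(int), bf.shape[0] - 1)
    if np.any(lo > hi):
        raise FlyStripError("strip lies outside the image vertically")
    means = np.empty((cols.size, 3))
    bff = bf.astype(float)
    for i, c in enumerate(cols):
        means[i] = bff[lo[i] : hi[i] + 1, c].mean(axis=0)
    span = max(c1 - c0, 1)
    positions = (cols - c0) * 100.0 / span
    return ExpressionProfile(
        positions=positions, red=means[:, 0], green=means[:, 1], blue=means[:, 2]
    )


def stain_signal(
    profile: ExpressionProfile, stain: str, invert_signal: bool = False
) -> np.ndarray:
    """Colorimetric stain signal from the RGB profile.

    NBT/BCIP (purple) is read from the red channel; FastRed (red stain) as
    green minus red, clipped at zero.  ``invert_signal`` flips the channel
    scale (255 - value) before the formula, for data where stain absorbs
    rather than adds intensity in the extracted channel.
    """
    red, green = profile.red, profile.green
    if invert_signal:
        red, green = 255.0 - red, 255.0 - green
    key = stain.lower().replace("/", "_").replace("-", "_")
    if key in ("nbt_bcip", "nbt", "purple"):
        return red.astype(float).copy()
    if key in ("fastred", "fast_red", "red"):
        return np.maximum(green - red, 0.0)
    raise ParameterError(f"unknown stain {stain!r}")


def extract_from_oriented(
    mask: np.ndarray,
    brightfield: np.ndarray,
    n_knots: int = 5,
    knot_override: np.ndarray | None = None,
) -> tuple[ExpressionProfile, ExtractionStrip, AxisSpline]:
    """Convenience: skeleton -> knots -> spline -> strip -> profile.

    ``knot_override`` replaces the automatically placed (row, col) knots,
    mirroring manual knot adjustment.
    """
    skel = skeletonize(mask)
    if knot_override is not None:
        knots = np.asarray(knot_override)
    else:
        knots = equidistant_knots(main_branch(skel), k=n_knots)
    spline = fit_axis_spline(knots, mask)
    strip = build_strip(spline, mask)
    profile = extract_profile(brightfield, strip)
    return profile, strip, spline
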