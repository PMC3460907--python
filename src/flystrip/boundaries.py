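"""Clamped cubic-spline representation of expression domain boundaries.

A domain boundary ("slope") is the graded transition between background and
plateau expression.  The user marks its outer edge x0 (signal first
distinguishable from background) and inner edge x2 (high expression
attained); a middle knot is placed automatically at the midpoint x1 with y1
read from the profile.  The boundary is then the cubic spline through the
three knots whose first derivative vanishes at both end knots (a "clamped"
spline), labelled with gene, an integer slope id, the side it bounds
(anterior/posterior) and the stain channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .errors import FlyStripError, ParameterError

__all__ = ["BoundarySpline", "fit_boundary", "eval_boundary", "suggest_window"]

POLARITIES = ("anterior", "posterior")
CHANNELS = ("purple", "red")


@dataclass
class BoundarySpline:
    """Clamped cubic spline through (x0,y0), (x1,y1), (x2,y2).

    x coordinates are in percent egg length, y in signal intensity.  The
    spline satisfies S(xi) = yi for all three knots and S'(x0) = S'(x2) = 0.
    """

    gene: str
    slope_id: int
    polarity: str
    channel: str
    knots: np.ndarray  # (3, 2) rows (x, y), ascending x
    _spline: CubicSpline = field(repr=False, default=None)

    def __post_init__(self):
        if self.polarity not in POLARITIES:
            raise ParameterError(f"polarity must be one of {POLARITIES}")
        if self.channel not in CHANNELS:
            raise ParameterError(f"channel must be one of {CHANNELS}")
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.shape != (3, 2):
            raise ParameterError("knots must be a (3, 2) array")
        if self._spline is None:
            x, y = self.knots[:, 0], self.knots[:, 1]
            if not (x[0] < x[1] < x[2]):
                raise ParameterError("knot x values must be strictly increasing")
            self._spline = CubicSpline(x, y, bc_type=((1, 0.0), (1, 0.0)))

    @property
    def x0(self) -> float:
        return float(self.knots[0, 0])

    @property
    def x1(self) -> float:
        return float(self.knots[1, 0])

    @property
    def x2(self) -> float:
        return float(self.knots[2, 0])

    def __call__(self, x) -> np.ndarray:
        return eval_boundary(self, x)

    def derivative(self, x) -> np.ndarray:
        return self._spline(np.asarray(x, dtype=float), 1)


def _nearest_sample(positions: np.ndarray, values: np.ndarray, x: float) -> float:
    return float(values[int(np.argmin(np.abs(positions - x)))])


def fit_boundary(
    positions: np.ndarray,
    signal: np.ndarray,
    x0: float,
    x2: float,
    gene: str = "",
    slope_id: int = 0,
    polarity: str = "anterior",
    channel: str = "purple",
) -> BoundarySpline:
    """Fit a clamped boundary spline between profile positions x0 and x2.

    The middle knot sits at the midpoint x1 = min(x0,x2) + |x2-x0|/2; all y
    values are read from the nearest profile sample.  ``x0`` and ``x2`` may
    be given in either order (anterior boundaries rise with x, posterior
    ones fall); the knots are stored with ascending x.
    """
    positions = np.asarray(positions, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if positions.shape != signal.shape or positions.ndim != 1:
        raise ParameterError("positions and signal must be 1-D arrays of equal length")
    if x0 == x2:
        raise ParameterError("x0 and x2 must differ")
    lo, hi = positions.min(), positions.max()
    for x in (x0, x2):
        if not lo <= x <= hi:
            raise FlyStripError(f"window edge {x} outside profile range [{lo}, {hi}]")
    x1 = min(x0, x2) + abs(x2 - x0) / 2.0
    knots = np.array(
        [
            [x0, _nearest_sample(positions, signal, x0)],
            [x1, _nearest_sample(positions, signal, x1)],
            [x2, _nearest_sample(positions, signal, x2)],
        ]
    )
    knots = knots[np.argsort(knots[:, 0])]
    return BoundarySpline(
        gene=gene, slope_id=int(slope_id), polarity=polarity, channel=channel, knots=knots
    )


def eval_boundary(spline: BoundarySpline, x) -> np.ndarray:
    """Evaluate the boundary spline inside its [x0, x2] span."""
    x = np.asarray(x, dtype=float)
    if np.any(x < spline.knots[0, 0] - 1e-12) or np.any(x > spline.knots[2, 0] + 1e-12):
        raise FlyStripError("evaluation point outside the boundary span")
    y = spline._spline(x)
    return y if y.shape else float(y)


def suggest_window(
    positions: np.ndarray,
    signal: np.ndarray,
    polarity: str = "anterior",
    smooth_sigma: float = 2.0,
) -> tuple[float, float] | None:
    """Advisory (x0, x2) window for a boundary; never auto-committed.

    Encodes the manual placement guidelines: the inner edge x2 where the
    smoothed signal levels off (reaches 90% of the plateau-above-background
    amplitude) and the outer edge x0 where it is no longer distinguishable
    from background (falls below the background mean + 2 SD, with a floor
    of 5% of the amplitude for noise-free data).  Returns None when no such
    crossings exist (e.g. a constant profile).
    """
    positions = np.asarray(positions, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if polarity not in POLARITIES:
        raise ParameterError(f"polarity must be one of {POLARITIES}")
    if signal.size < 5 or np.ptp(signal) == 0:
        return None
    s = gaussian_filter1d(signal, smooth_sigma, mode="nearest")
    # background statistics from the quartile of lowest smoothed samples
    n_bg = max(int(s.size * 0.25), 2)
    bg = np.sort(s)[:n_bg]
    peak = int(np.argmax(s))
    amplitude = s[peak] - bg.mean()
    if amplitude <= 0:
        return None
    bg_thresh = max(bg.mean() + 2.0 * bg.std(), bg.mean() + 0.05 * amplitude)
    inner_thresh = bg.mean() + 0.9 * amplitude
    if inner_thresh <= bg_thresh:
        return None
    if polarity == "anterior":
        # rising edge to the left of the plateau
        left = s[: peak + 1]
        above = np.flatnonzero(left >= inner_thresh)
        if above.size == 0:
            return None
        i2 = above[0]
        below = np.flatnonzero(left[:i2] <= bg_thresh)
        if below.size == 0:
            return None
        i0 = below[-1]
    else:
        right = s[peak:]
        above = np.flatnonzero(right >= inner_thresh)
        if above.size == 0:
            return None
        i2 = peak + above[-1]
        below = np.flatnonzero(s[i2 + 1 :] <= bg_thresh)
        if below.size == 0:
            return None
        i0 = i2 + 1 + below[0]
    if i0 == i2:
        return None
    return float(positions[i0]), float(positions[i2])
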