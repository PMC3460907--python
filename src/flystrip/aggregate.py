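"""Grouping and aggregation of expression boundaries over embryos and time.

Boundaries from individual embryos, grouped by gene, slope id, polarity and
time class, are summarised by a median boundary: the medians of the start
and end knots are taken independently and a clamped spline is refitted on
the median knots.  Variability datasets expose the individual (normalised)
splines next to their median; space-time tables list the midpoints x1 of
the median boundaries ordered by developmental time.

Time classes follow blastoderm staging: cleavage cycles C1-C13 plus C14A,
the latter subdivided into eight time points T1-T8 of 6-7 minutes.
Classification itself is a manual, expert task; here time classes are
validated metadata only.
"""

from __future__ import annotations

import functools
import warnings as _warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .boundaries import BoundarySpline
from .errors import FlyStripError, ParameterError

__all__ = [
    "TimeClass",
    "MedianBoundary",
    "median_boundary",
    "normalize_intensity",
    "variability_dataset",
    "spacetime_table",
]

CYCLES = tuple(f"C{i}" for i in range(1, 14)) + ("C14A",)
SUBDIVISIONS = tuple(f"T{i}" for i in range(1, 9))


@functools.total_ordering
@dataclass(frozen=True, order=False)
class TimeClass:
    """A cleavage-cycle time class, e.g. C13 or C14A_T3.

    ``subdivision`` (T1-T8) is only valid for cycle C14A.
    """

    cycle: str
    subdivision: str | None = None

    def __post_init__(self):
        if self.cycle not in CYCLES:
            raise ParameterError(f"unknown cleavage cycle {self.cycle!r}")
        if self.subdivision is not None:
            if self.cycle != "C14A":
                raise ParameterError("only C14A is subdivided into time points")
            if self.subdivision not in SUBDIVISIONS:
                raise ParameterError(f"unknown subdivision {self.subdivision!r}")

    @classmethod
    def parse(cls, text: str) -> "TimeClass":
        """Parse 'C12', 'C14A' or 'C14A_T5' (also accepts 'C14_T5')."""
        text = text.strip()
        if "_" in text:
            cycle, sub = text.split("_", 1)
            if cycle == "C14":  # common shorthand for C14A subdivisions
                cycle = "C14A"
            return cls(cycle, sub)
        return cls(text)

    def sort_key(self) -> tuple[int, int]:
        sub = 0 if self.subdivision is None else SUBDIVISIONS.index(self.subdivision) + 1
        return (CYCLES.index(self.cycle), sub)

    def __lt__(self, other: "TimeClass") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return self.cycle if self.subdivision is None else f"{self.cycle}_{self.subdivision}"


@dataclass
class MedianBoundary:
    """Median boundary of a (gene, slope, polarity, time class) group."""

    gene: str
    slope_id: int
    polarity: str
    time_class: TimeClass | None
    spline: BoundarySpline
    n: int

    @property
    def x1(self) -> float:
        return self.spline.x1


def median_boundary(
    boundaries: Sequence[BoundarySpline], time_class: TimeClass | None = None
) -> MedianBoundary:
    """Median of a group of homologous boundaries.

    Medians of the x0, x2 (and y) knot coordinates are taken independently
    across embryos; even-sized groups use the mean of the two central order
    statistics.  The middle knot is re-placed at the midpoint of the median
    end knots and a clamped spline is refitted on the median knots.

    All boundaries must share gene, slope id, polarity and channel.
    """
    boundaries = list(boundaries)
    if not boundaries:
        raise FlyStripError("cannot take the median of an empty group")
    labels = {(b.gene, b.slope_id, b.polarity, b.channel) for b in boundaries}
    if len(labels) > 1:
        raise FlyStripError(f"mixed boundary labels in one group: {sorted(labels)}")
    knots = np.stack([b.knots for b in boundaries])  # (n, 3, 2)
    med = np.median(knots, axis=0)
    x1 = (med[0, 0] + med[2, 0]) / 2.0
    med_knots = np.array([[med[0, 0], med[0, 1]], [x1, med[1, 1]], [med[2, 0], med[2, 1]]])
    b0 = boundaries[0]
    spline = BoundarySpline(
        gene=b0.gene,
        slope_id=b0.slope_id,
        polarity=b0.polarity,
        channel=b0.channel,
        knots=med_knots,
    )
    return MedianBoundary(
        gene=b0.gene,
        slope_id=b0.slope_id,
        polarity=b0.polarity,
        time_class=time_class,
        spline=spline,
        n=len(boundaries),
    )


def normalize_intensity(signal: np.ndarray) -> np.ndarray:
    """Min-max normalisation to [0, 1]; constant input gives zeros + warning."""
    signal = np.asarray(signal, dtype=float)
    lo, hi = signal.min(), signal.max()
    if hi == lo:
        _warnings.warn("constant signal: normalisation undefined, returning zeros")
        return np.zeros_like(signal)
    return (signal - lo) / (hi - lo)


def _group_key(gene, slope_id, polarity, time_class):
    return (gene, int(slope_id), polarity, str(time_class))


def variability_dataset(
    boundaries: Iterable[tuple[BoundarySpline, TimeClass]],
    genes: Sequence[str],
    slope_ids: Sequence[int] | None = None,
    time_classes: Sequence[TimeClass] | None = None,
    mode: str = "slopes_and_medians",
    samples: int = 50,
) -> dict:
    """Curves for a variability plot.

    Selects boundaries for the requested genes / slopes / time classes and
    returns, per group, the individual splines (y min-max normalised) and
    their median.  ``mode`` is 'slopes_and_medians', 'medians_only' or
    'slopes_only'; when more than one gene is selected only medians are
    returned (individual slopes of several genes are not overlaid).

    Returns a dict with 'groups' (list of per-group dicts with keys
    gene/slope_id/polarity/time_class/x/curves/median/n/color) and
    'notices' (text messages, e.g. empty selections).
    """
    if mode not in ("slopes_and_medians", "medians_only", "slopes_only"):
        raise ParameterError(f"unknown mode {mode!r}")
    genes = list(genes)
    notices: list[str] = []
    if len(genes) > 1 and mode != "medians_only":
        notices.append("multiple genes selected: restricting display to medians only")
        mode = "medians_only"
    selected: dict[tuple, list[BoundarySpline]] = {}
    for b, tc in boundaries:
        if b.gene not in genes:
            continue
        if slope_ids is not None and b.slope_id not in slope_ids:
            continue
        if time_classes is not None and all(tc != t for t in time_classes):
            continue
        selected.setdefault(_group_key(b.gene, b.slope_id, b.polarity, tc), []).append(b)
    if not selected:
        notices.append("selection matched no boundaries")
        return {"groups": [], "notices": notices}
    if time_classes is not None:
        wanted = {str(t) for t in time_classes}
        found = {key[3] for key in selected}
        for missing in sorted(wanted - found):
            notices.append(f"no data for time class {missing}: group omitted")
    palette = {g: f"C{i}" for i, g in enumerate(genes)}
    groups = []
    for key in sorted(selected):
        gene, slope_id, polarity, tc = key
        group = selected[key]
        median = median_boundary(group, TimeClass.parse(tc))
        entry = {
            "gene": gene,
            "slope_id": slope_id,
            "polarity": polarity,
            "time_class": tc,
            "n": len(group),
            "color": palette[gene],
        }

        def _curve(spl):
            x = np.linspace(spl.x0, spl.x2, samples)
            return x, normalize_intensity(spl(x))

        if mode in ("slopes_and_medians", "slopes_only"):
            entry["curves"] = [_curve(b) for b in group]
        else:
            entry["curves"] = []
        if mode in ("slopes_and_medians", "medians_only"):
            entry["median"] = _curve(median.spline)
        else:
            entry["median"] = None
        groups.append(entry)
    return {"groups": groups, "notices": notices}


def spacetime_table(
    boundaries: Iterable[tuple[BoundarySpline, TimeClass]],
    genes: Sequence[str] | None = None,
    time_range: tuple[TimeClass, TimeClass] | None = None,
) -> pd.DataFrame:
    """Midpoints x1 of the median boundaries, ordered by developmental time.

    One row per (gene, slope_id, polarity, time_class) with data; columns
    gene, slope_id, polarity, time_class, x1_percent, n.
    """
    selected: dict[tuple, list[BoundarySpline]] = {}
    for b, tc in boundaries:
        if genes is not None and b.gene not in genes:
            continue
        if time_range is not None and not (time_range[0] <= tc <= time_range[1]):
            continue
        selected.setdefault(_group_key(b.gene, b.slope_id, b.polarity, tc), []).append(b)
    rows = []
    for key, group in selected.items():
        gene, slope_id, polarity, tc = key
        med = median_boundary(group, TimeClass.parse(tc))
        rows.append(
            {
                "gene": gene,
                "slope_id": slope_id,
                "polarity": polarity,
                "time_class": tc,
                "x1_percent": med.x1,
                "n": med.n,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "slope_id", "polarity", "time_class", "x1_percent", "n"])
    if len(df):
        df["_t"] = [TimeClass.parse(t).sort_key() for t in df["time_class"]]
        df = df.sort_values(["gene", "slope_id", "polarity", "_t"]).drop(columns="_t")
        df = df.reset_index(drop=True)
    return df
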