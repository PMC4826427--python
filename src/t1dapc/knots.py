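"""Case-balanced spline knot placement.

Knots for the age, period and cohort splines are placed so that the number
of cancer cases between consecutive knots is (as nearly as possible) the
same: interior knots sit at the j/k-quantiles (j = 1..k-1) of the
event-weighted distribution of the timescale value, and boundary knots at
the observed extremes.  Exact ties are assigned to the lower interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateKnotsError(ValueError):
    """Raised when the event values cannot support the requested knots."""


@dataclass(frozen=True)
class KnotVector:
    """Knot positions on one timescale.

    Attributes
    ----------
    timescale : str
        One of ``"age"``, ``"period"``, ``"cohort"``.
    interior : tuple of float
        Strictly increasing interior knots.
    boundary : tuple of float
        (min, max) boundary knots.
    """

    timescale: str
    interior: tuple
    boundary: tuple

    def __post_init__(self):
        lo, hi = self.boundary
        allk = (lo, *self.interior, hi)
        if any(b <= a for a, b in zip(allk, allk[1:])):
            raise DegenerateKnotsError(
                f"knots not strictly increasing on {self.timescale}: {allk}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary[0], *self.interior, self.boundary[1]])


def balanced_knots(event_values, k, weights=None, timescale="age") -> KnotVector:
    """Place ``k-1`` interior knots splitting events into ``k`` equal groups.

    Parameters
    ----------
    event_values : array-like
        Timescale value (age, date of follow-up, date of birth) of each
        event, or of each cell when ``weights`` carries the cell's event
        count.
    k : int
        Number of inter-knot intervals; ``k - 1`` interior knots are placed.
    weights : array-like, optional
        Event multiplicities (default 1 per value).
    """
    v = np.asarray(event_values, dtype=float)
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != v.shape:
            raise ValueError("weights must match event_values")
        keep = w > 0
        v, w = v[keep], w[keep]
    if k < 1:
        raise ValueError("k must be >= 1")
    if v.size == 0:
        raise DegenerateKnotsError("no events")
    distinct = np.unique(v)
    if distinct.size < k + 1:
        raise DegenerateKnotsError(
            f"{distinct.size} distinct event values cannot support {k} intervals"
        )
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    total = cum[-1]
    interior = []
    for j in range(1, k):
        # smallest event value whose cumulative count reaches j/k of the total;
        # ties at the quantile fall in the lower interval (searchsorted 'left')
        q = total * j / k
        i = int(np.searchsorted(cum, q, side="left"))
        interior.append(v[min(i, v.size - 1)])
    interior = tuple(dict.fromkeys(interior))  # dedupe, keep order
    lo, hi = float(v[0]), float(v[-1])
    interior = tuple(x for x in interior if lo < x < hi)
    return KnotVector(timescale=timescale, interior=interior, boundary=(lo, hi))


def between_knot_counts(kv: KnotVector, event_values, weights=None) -> np.ndarray:
    """Event counts in the half-open inter-knot intervals (oracle helper).

    Events exactly at a knot are counted in the lower interval, matching
    the tie rule of :func:`balanced_knots`.
    """
    v = np.asarray(event_values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    edges = kv.all_knots
    idx = np.clip(np.searchsorted(edges, v, side="left") - 1, 0, len(edges) - 2)
    counts = np.zeros(len(edges) - 1)
    np.add.at(counts, idx, w)
    return counts
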