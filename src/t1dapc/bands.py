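"""Diabetes-duration bands.

Follow-up of a person with type 1 diabetes is classified by time since
diabetes diagnosis, cut at 0, 1, 2, 5, 10, 15 and 30 years, giving the
half-open bands [0,1), [1,2), [2,5), [5,10), [10,15), [15,30), [30,inf),
plus the reference level "pop" (general population) and the level
"unknown" for prevalent cases whose diagnosis date was not recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CUTS = (0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 30.0)

#: reference level for general-population person-time
POP_LEVEL = "pop"
#: duration level for T1D person-time with an unrecorded diagnosis date
UNKNOWN_LEVEL = "unknown"


@dataclass(frozen=True)
class DurationBands:
    """Cut points (years since diagnosis) defining half-open duration bands."""

    cuts: tuple = DEFAULT_CUTS

    def __post_init__(self):
        c = tuple(float(x) for x in self.cuts)
        if len(c) < 1 or c[0] != 0.0:
            raise ValueError("first duration cut must be 0")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("duration cuts must be strictly increasing")
        object.__setattr__(self, "cuts", c)

    @property
    def labels(self) -> list:
        """Band labels in band order, e.g. '0-1', '1-2', ..., '30+'."""
        out = []
        for a, b in zip(self.cuts, self.cuts[1:]):
            out.append(f"{a:g}-{b:g}")
        out.append(f"{self.cuts[-1]:g}+")
        return out

    @property
    def n_bands(self) -> int:
        return len(self.cuts)

    def band_index(self, duration) -> np.ndarray:
        """Index of the band containing each duration (array-safe)."""
        d = np.asarray(duration, dtype=float)
        idx = np.searchsorted(np.asarray(self.cuts), d, side="right") - 1
        if np.any(d < 0):
            raise ValueError("negative diabetes duration")
        return idx

    def band_label(self, duration) -> np.ndarray:
        labels = np.asarray(self.labels, dtype=object)
        return labels[self.band_index(duration)]


DEFAULT_BANDS = DurationBands()
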