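"""Frequency-band definitions shared across the pipeline.

Band edges follow the clinical EEG convention used throughout the package:
each band is half-open, ``[lo, hi)`` in Hz, so the shared 10.5 Hz edge between
alpha1 and alpha2 is unambiguous, and the 7-8 Hz and 13-14 Hz gaps in the
default table are intentional.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with inclusive lower / exclusive upper edge (Hz)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: need lo < hi, got [{self.lo}, {self.hi})")

    def mask(self, freqs) -> np.ndarray:
        """Boolean mask of frequency-grid bins falling inside [lo, hi)."""
        f = np.asarray(freqs, dtype=float)
        return (f >= self.lo) & (f < self.hi)


#: Default band table: delta1, delta2, theta1, theta2, alpha1, alpha2, beta.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta1", 0.5, 3.0),
    BandSpec("delta2", 3.0, 4.0),
    BandSpec("theta1", 4.0, 5.5),
    BandSpec("theta2", 5.5, 7.0),
    BandSpec("alpha1", 8.0, 10.5),
    BandSpec("alpha2", 10.5, 13.0),
    BandSpec("beta", 14.0, 30.0),
)


def get_band(name: str, bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")
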