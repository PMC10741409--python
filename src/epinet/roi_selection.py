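"""Suprathreshold ROI selection from a vertex-level condition-difference map.

A rectified, grand-averaged source-activation difference map (pre-interictal
minus resting state) is reduced to the set of vertices whose value reaches a
fraction of the map maximum (default 10%), and to the list of atlas regions
containing at least one suprathreshold vertex.  The fraction-of-maximum
reading makes the mask invariant to overall map scale; a percentile mode is
available behind a flag.
"""
from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np


def threshold_map(values: Sequence[float], frac: float = 0.1,
                  labels: Sequence[str] | None = None,
                  mode: str = "max-fraction") -> tuple[np.ndarray, list[str]]:
    """Mask vertices with value >= frac * max(values); list their regions.

    Parameters
    ----------
    values : per-vertex nonnegative difference values
    frac : threshold fraction, 0 < frac < 1
    labels : optional vertex -> region label mapping (same length as values)
    mode : ``"max-fraction"`` (threshold = frac * max) or ``"percentile"``
        (threshold = the (1 - frac) quantile of the values)

    Returns
    -------
    mask : boolean array over vertices
    regions : region labels (input order, deduplicated) with >= 1
        suprathreshold vertex; empty when no labels are given
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.any(v < 0):
        raise ValueError("values must be nonnegative (rectified upstream)")
    if not 0 < frac < 1:
        raise ValueError("frac must satisfy 0 < frac < 1")
    if labels is not None and len(labels) != len(v):
        raise ValueError("labels must have one entry per vertex")

    vmax = v.max() if v.size else 0.0
    if vmax == 0.0:
        warnings.warn("all-zero difference map: empty mask", stacklevel=2)
        mask = np.zeros(v.shape, dtype=bool)
    elif mode == "max-fraction":
        mask = v >= frac * vmax
    elif mode == "percentile":
        mask = v >= np.quantile(v, 1 - frac)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    regions: list[str] = []
    if labels is not None:
        regions = list(dict.fromkeys(lab for lab, m in zip(labels, mask) if m))
    return mask, regions
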