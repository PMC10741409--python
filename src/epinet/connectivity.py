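"""Band-resolved lagged coherence between all ROI pairs.

The coupling measure is the lagged (zero-lag-removed) coherence

.. math::

    \\rho_{GL}(\\omega) = \\frac{|\\mathrm{Im}\\, S_{yx}(\\omega)|}
        {\\sqrt{s_{yy}(\\omega)\\, s_{xx}(\\omega) - \\mathrm{Re}\\, S_{yx}(\\omega)^2}}

where :math:`S_{yx}` is the cross-spectrum and :math:`s_{xx}, s_{yy}` the
(real) auto-spectra.  Only the imaginary — i.e. lagged — part of the
coherency enters the numerator, and the instantaneous (real) part is removed
from the denominator, so the measure is exactly zero for instantaneous linear
mixtures of a signal with itself (volume conduction / crosstalk) and its
magnitude is unaffected by the amount of such mixing.  Values lie in [0, 1]
by the Cauchy-Schwarz inequality.

Cross-spectra are estimated Welch-style: Hann-tapered, demeaned segments
(default 2 s, 50% overlap — 0.5 Hz resolution, so every default band edge
lands on a bin) pooled across all epochs of a subject/condition before the
coherence is formed.  Band values are the mean of the bin-wise quantity over
bins in ``[lo, hi)``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, BandSpec
from .epochs import CONDITIONS, EpochSet

logger = logging.getLogger(__name__)

#: Relative tolerance below which the denominator is treated as degenerate
#: (perfect real coherence): that bin contributes 0.  Keeps instantaneously
#: mixed pairs at exactly zero instead of a 0/0 rounding artifact.
DEGENERATE_RTOL = 1e-10


@dataclass
class CrossSpectrum:
    """Welch-averaged cross-spectral matrices, Hermitian at every bin."""

    S: np.ndarray          # (n_rois, n_rois, n_freqs) complex
    freqs: np.ndarray      # (n_freqs,) Hz
    n_segments: int

    @property
    def n_rois(self) -> int:
        return self.S.shape[0]


def cross_spectrum(epochs: list[np.ndarray], fs: float, seg_len: int | None = None,
                   overlap: float = 0.5, window: str = "hann") -> CrossSpectrum:
    """Pooled Welch cross-spectrum over segments of all epochs.

    Parameters
    ----------
    epochs : list of (n_rois, n_samples) arrays
    fs : sampling rate in Hz
    seg_len : segment length in samples (default ``2 * fs``)
    overlap : fractional segment overlap in [0, 1)
    """
    from scipy.signal import get_window

    if not epochs:
        raise ValueError("need at least one epoch")
    n_rois = epochs[0].shape[0]
    if seg_len is None:
        seg_len = int(round(2 * fs))
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(seg_len * (1 - overlap))))

    segments = []
    for k, ep in enumerate(epochs):
        if ep.shape[0] != n_rois:
            raise ValueError(f"epoch {k}: inconsistent ROI count {ep.shape[0]} != {n_rois}")
        n_t = ep.shape[1]
        if n_t < seg_len:
            raise ValueError(f"epoch {k}: length {n_t} < segment length {seg_len}")
        for start in range(0, n_t - seg_len + 1, step):
            segments.append(ep[:, start:start + seg_len])
    if len(segments) < 2:
        raise ValueError(f"only {len(segments)} segment(s); need >= 2 for stable "
                         "variance terms")

    seg = np.asarray(segments, dtype=float)               # (n_seg, n_rois, seg_len)
    seg = seg - seg.mean(axis=-1, keepdims=True)
    win = get_window(window, seg_len)
    X = np.fft.rfft(seg * win, axis=-1)
    scale = 1.0 / (fs * np.sum(win ** 2) * len(segments))
    S = np.einsum("sif,sjf->ijf", X, np.conj(X)) * scale
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    return CrossSpectrum(S=S, freqs=freqs, n_segments=len(segments))


def lagged_coherence(cs: CrossSpectrum, band: BandSpec) -> np.ndarray:
    """Band-averaged lagged coherence matrix (symmetric, zero diagonal, [0,1]).

    Bins with a degenerate denominator (perfect real coherence) contribute 0
    and are reported through a logged warning.
    """
    m = band.mask(cs.freqs)
    if not m.any():
        raise ValueError(f"band {band.name!r} [{band.lo}, {band.hi}) does not overlap "
                         f"the frequency grid (df={cs.freqs[1] - cs.freqs[0]:g} Hz)")
    S = cs.S[:, :, m]
    power = np.real(np.einsum("iif->if", cs.S))[:, m]     # auto-spectra, (n_rois, n_bins)
    pp = power[:, None, :] * power[None, :, :]
    den = pp - np.real(S) ** 2
    num = np.abs(np.imag(S))
    degenerate = den <= DEGENERATE_RTOL * pp
    n_rois = cs.n_rois
    off = ~np.eye(n_rois, dtype=bool)
    n_bad = int(np.count_nonzero(degenerate[off]))
    if n_bad:
        logger.warning("lagged_coherence(%s): %d off-diagonal bin(s) with degenerate "
                       "denominator contribute 0", band.name, n_bad)
    val = np.zeros_like(den)
    ok = ~degenerate
    val[ok] = num[ok] / np.sqrt(den[ok])
    out = val.mean(axis=-1)
    out = np.clip(0.5 * (out + out.T), 0.0, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class ConnectivityTensor:
    """subject x condition x band x ROI x ROI lagged-coherence array."""

    values: np.ndarray                 # (n_subj, 2, n_bands, n_rois, n_rois)
    subjects: list[str]
    conditions: tuple[str, ...]
    bands: list[str]
    roi_labels: list[str]
    meta: dict | None = None

    def band_slice(self, band: str) -> np.ndarray:
        """(n_subj, 2, n_rois, n_rois) view for one band."""
        return self.values[:, :, self.bands.index(band)]

    def save(self, path: str | Path) -> Path:
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        for si, sub in enumerate(self.subjects):
            for ci, cond in enumerate(self.conditions):
                for bi, band in enumerate(self.bands):
                    df = pd.DataFrame(self.values[si, ci, bi],
                                      index=self.roi_labels, columns=self.roi_labels)
                    df.to_csv(root / f"{sub}_{cond}_{band}.tsv", sep="\t")
        manifest = {"subjects": self.subjects, "conditions": list(self.conditions),
                    "bands": self.bands, "roi_labels": self.roi_labels,
                    "meta": self.meta or {}}
        (root / "tensor.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return root

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityTensor":
        root = Path(path)
        manifest = json.loads((root / "tensor.json").read_text())
        subjects, conditions = manifest["subjects"], tuple(manifest["conditions"])
        bands, rois = manifest["bands"], manifest["roi_labels"]
        values = np.zeros((len(subjects), len(conditions), len(bands), len(rois), len(rois)))
        for si, sub in enumerate(subjects):
            for ci, cond in enumerate(conditions):
                for bi, band in enumerate(bands):
                    df = pd.read_csv(root / f"{sub}_{cond}_{band}.tsv", sep="\t", index_col=0)
                    values[si, ci, bi] = df.to_numpy(dtype=float)
        return cls(values=values, subjects=subjects, conditions=conditions,
                   bands=bands, roi_labels=rois, meta=manifest.get("meta") or None)


def build_tensor(es: EpochSet, bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                 seg_len: int | None = None, overlap: float = 0.5) -> ConnectivityTensor:
    """Lagged-coherence tensor for every subject, condition and band.

    Epochs are pooled at the cross-spectrum (segment) level before the
    coherence is formed — not by averaging per-epoch coherences — which keeps
    the estimator stable at 1-3 epochs per subject.
    """
    subjects = es.subjects
    n_rois = es.n_rois
    values = np.zeros((len(subjects), len(CONDITIONS), len(bands), n_rois, n_rois))
    for si, sub in enumerate(subjects):
        for ci, cond in enumerate(CONDITIONS):
            epochs = es.data.get(sub, {}).get(cond, [])
            if not epochs:
                raise ValueError(f"subject {sub!r} has no epochs for condition {cond!r}")
            cs = cross_spectrum(epochs, es.fs, seg_len=seg_len, overlap=overlap)
            for bi, band in enumerate(bands):
                values[si, ci, bi] = lagged_coherence(cs, band)
    return ConnectivityTensor(values=values, subjects=subjects, conditions=CONDITIONS,
                              bands=[b.name for b in bands], roi_labels=es.roi_labels,
                              meta={"source_meta": es.meta} if es.meta else None)
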