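"""Synthetic two-condition, multi-subject ROI time-series generator.

Emulates source-projected ("scout") EEG series for a paired design with a
pre-interictal condition (``"pre"``) and a resting-state condition
(``"rest"``): every ROI carries independent 1/f background noise, and a
planted set of ROI pairs additionally shares band-limited sources injected
with a pure delay, so that lagged coherence registers the coupling.  Coupling
amplitude is condition-dependent (``sync_gain`` > 1 raises it in "pre" on the
synchronization subnetwork; ``desync_gain`` < 1 lowers it on the
desynchronization subnetwork), which gives every downstream stage — spectral
connectivity, network-based statistics, graph metrics, node influence — a
known ground truth.

Design notes
------------
* Shared sources are white noise band-pass filtered with a zero-phase
  (forward-backward) 4th-order Butterworth filter, renormalized to unit
  standard deviation, and injected into each group node with a pure delay of
  ``k`` steps for the ``k``-th node.  The default step is one sixth of the
  band-center period (60 degrees of phase per step), so every within-group
  pair carries a strongly lagged component — a nonzero imaginary
  cross-spectrum is what lagged coherence requires, and zero-lag coupling
  would be invisible to it by construction.  ``coupling_lag`` overrides the
  step with a fixed delay in seconds.
* Subjects differ in coupling strength by a lognormal multiplier with
  coefficient of variation ``subject_cv`` (mean 1), emulating realistic
  between-patient heterogeneity of synchronization effects.
* Background noise has power spectral density proportional to
  ``1/f**noise_exponent`` and unit standard deviation per ROI.  ``snr`` is
  the in-band coupling-to-background amplitude ratio: the shared source is
  scaled so that, at ``snr = 1`` and gain 1, its standard deviation equals
  the standard deviation of the background noise restricted to the coupling
  band.  (A broadband-unit-std convention would saturate the in-band
  signal-to-noise ratio — a narrowband source of std 1 overwhelms the 1/f
  floor inside its band — and condition gains would no longer move the
  coherence monotonically.)
* With both gains equal to 1 the two conditions are draws from the same
  process (a null configuration for false-positive calibration).
* All randomness flows through one ``numpy`` generator consumed in a fixed
  order, so an identical seed yields bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy import signal

from .bands import DEFAULT_BANDS, BandSpec, get_band
from .epochs import CONDITIONS, EpochSet

Edge = tuple[int, int]


def _check_connected(edges: tuple[Edge, ...], what: str) -> None:
    """Planted edge sets must form one connected graph on their incident nodes."""
    if not edges:
        return
    nodes = sorted({v for e in edges for v in e})
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, j in edges:
        parent[find(i)] = find(j)
    roots = {find(v) for v in nodes}
    if len(roots) > 1:
        raise ValueError(f"{what}: planted edges must form a connected graph on their nodes")


@dataclass(frozen=True)
class GroundTruth:
    """Planted coupling structure and condition-dependent gains.

    Coupling is organized in *source groups*: each group is a small set of
    ROIs sharing one band-limited source, injected with a distinct pure delay
    per node, so every within-group pair is lagged-coherent.  The planted
    edge set is the union of within-group cliques; overlapping groups build
    hub-centered subnetworks.  (Independent per-edge sources would pile up
    in-band power at shared nodes and make the condition gain move per-edge
    coherence non-monotonically; shared group sources keep the per-edge
    coupling strength degree-independent.)
    """

    sync_groups: tuple[tuple[int, ...], ...]
    desync_groups: tuple[tuple[int, ...], ...] = ()
    sync_gain: float = 2.0
    desync_gain: float = 0.3
    sync_group_amps: tuple[float, ...] | None = None
    desync_group_amps: tuple[float, ...] | None = None
    sync_group_gains: tuple[float, ...] | None = None
    desync_group_gains: tuple[float, ...] | None = None
    hub_node: int = 0
    sync_band: BandSpec = get_band("delta2")
    desync_band: BandSpec = get_band("alpha1")

    def __post_init__(self) -> None:
        for name, groups in (("sync_groups", self.sync_groups),
                             ("desync_groups", self.desync_groups)):
            for g in groups:
                if len(g) < 2:
                    raise ValueError(f"{name}: groups need at least 2 nodes, got {g}")
                if len(set(g)) != len(g):
                    raise ValueError(f"{name}: duplicate node in group {g}")
        _check_connected(self.sync_edges, "sync")
        _check_connected(self.desync_edges, "desync")
        for name, amps, groups in (
                ("sync_group_amps", self.sync_group_amps, self.sync_groups),
                ("desync_group_amps", self.desync_group_amps, self.desync_groups)):
            if amps is not None:
                if len(amps) != len(groups):
                    raise ValueError(f"{name}: need one amplitude per group")
                if any(a <= 0 for a in amps):
                    raise ValueError(f"{name}: amplitudes must be positive")
        for name, gains, groups, lo, hi in (
                ("sync_group_gains", self.sync_group_gains, self.sync_groups, 1.0, None),
                ("desync_group_gains", self.desync_group_gains, self.desync_groups,
                 0.0, 1.0)):
            if gains is not None:
                if len(gains) != len(groups):
                    raise ValueError(f"{name}: need one gain per group")
                if any(g < lo or (hi is not None and g > hi) for g in gains):
                    raise ValueError(f"{name}: gains out of the allowed range")
        if not (0.0 <= self.desync_gain <= 1.0 <= self.sync_gain):
            # equality on both sides admits the null construction (gains = 1)
            raise ValueError("need 0 <= desync_gain <= 1 <= sync_gain")
        if self.sync_edges:
            deg: dict[int, int] = {}
            for i, j in self.sync_edges:
                deg[i] = deg.get(i, 0) + 1
                deg[j] = deg.get(j, 0) + 1
            if deg.get(self.hub_node, 0) != max(deg.values()):
                raise ValueError(f"hub_node {self.hub_node} does not attain the "
                                 "maximum planted degree")

    @staticmethod
    def _clique_union(groups: tuple[tuple[int, ...], ...]) -> tuple[Edge, ...]:
        edges = {tuple(sorted((i, j))) for g in groups
                 for a, i in enumerate(g) for j in g[a + 1:]}
        return tuple(sorted(edges))

    @property
    def sync_edges(self) -> tuple[Edge, ...]:
        """Planted synchronization edges (within-group cliques, union)."""
        return self._clique_union(self.sync_groups)

    @property
    def desync_edges(self) -> tuple[Edge, ...]:
        return self._clique_union(self.desync_groups)

    def max_node(self) -> int:
        nodes = [v for g in self.sync_groups + self.desync_groups for v in g]
        return max(nodes + [self.hub_node])


def default_ground_truth(n_rois: int = 48) -> GroundTruth:
    """Demo truth: a hub-centered delta2 sync subnetwork and an alpha1 desync one.

    The sync subnetwork is three triangles sharing node 0 (nine edges, hub
    degree 6) in the delta2 band; the desync subnetwork is three triangles
    sharing node 7 (nine edges) in alpha1.  The two subnetworks share nodes
    (bands are analyzed separately) but plant disjoint edge sets.  Group
    base amplitudes are staggered per band (sync 0.7 / 1.0 / 1.4, desync
    0.9 / 1.3 / 1.8): staggering keeps the edge-wise effect sizes
    heterogeneous, which stabilizes the permutation null of the
    network-based statistics, and the stronger desync amplitudes keep the
    decreased-connectivity network detectable after its gain collapse.
    """
    if n_rois < 10:
        raise ValueError("default ground truth needs n_rois >= 10")
    return GroundTruth(sync_groups=((0, 1, 2), (0, 3, 4), (0, 5, 6)),
                       desync_groups=((7, 1, 3), (7, 2, 5), (7, 8, 9)),
                       sync_group_amps=(0.7, 1.0, 1.4),
                       desync_group_amps=(0.9, 1.3, 1.8),
                       hub_node=0)


def near_clique_groups(nodes: tuple[int, int, int, int] = (0, 1, 2, 3),
                       ) -> tuple[tuple[int, ...], ...]:
    """Two overlapping triangles on four nodes: a five-edge near-clique
    (K4 minus one edge)."""
    a, b, c, d = nodes
    return ((a, b, c), (b, c, d))


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions; defaults mirror the study design at reduced rate.

    ``epochs_per_condition=None`` draws 1-3 epochs per subject from the seed
    (echoing unequal real epoch counts); the resting-state count always
    matches the pre-interictal count within a subject.
    """

    n_subjects: int = 21
    n_rois: int = 10
    epochs_per_condition: int | None = 2
    fs: float = 250.0
    epoch_len: float = 6.0
    band_table: tuple[BandSpec, ...] = DEFAULT_BANDS
    coupling_lag: float | None = None
    noise_exponent: float = 1.0
    snr: float = 1.0
    subject_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.fs * self.epoch_len
        if abs(n - round(n)) > 1e-9 or round(n) < 2 * self.fs:
            raise ValueError("epoch_len * fs must be an integer >= 2 * fs")
        if self.coupling_lag is not None:
            if self.coupling_lag <= 0:
                raise ValueError("coupling_lag must be > 0 (zero-lag coupling is "
                                 "invisible to lagged coherence)")
            if round(self.coupling_lag * self.fs) < 1:
                raise ValueError("coupling_lag shorter than one sample at this rate")
        if self.subject_cv < 0:
            raise ValueError("subject_cv must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("need n_subjects >= 2")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len))


def roi_label_table(n_rois: int) -> list[str]:
    """First ``n_rois`` Desikan-Killiany region labels (plus thalami), padded
    with generic names when more ROIs are requested than the atlas holds."""
    text = resources.files("epinet.data").joinpath("dk_regions.txt").read_text()
    labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if n_rois <= len(labels):
        return labels[:n_rois]
    return labels + [f"ROI{k:02d}" for k in range(len(labels), n_rois)]


@lru_cache(maxsize=32)
def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], beta: float) -> np.ndarray:
    """Gaussian noise with PSD ~ 1/f**beta, unit std along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


@lru_cache(maxsize=64)
def _band_noise_fraction(n: int, fs: float, beta: float, lo: float, hi: float) -> float:
    """Fraction of unit-std 1/f**beta noise variance falling in [lo, hi) Hz."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    s2 = np.zeros_like(f)
    s2[1:] = f[1:] / fs  # normalized frequency, matches _pink_noise scaling
    s2[1:] = s2[1:] ** (-beta)
    w = np.full_like(f, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    in_band = (f >= lo) & (f < hi)
    return float((w * s2)[in_band].sum() / (w * s2).sum())


def _group_sources(rng: np.random.Generator, groups, n: int, delay: int,
                   band: BandSpec, fs: float) -> list[np.ndarray]:
    """One unit-std band-limited source per group, long enough for the
    largest per-node delay within the group."""
    out = []
    sos = _bandpass_sos(band.lo, band.hi, fs)
    for g in groups:
        raw = rng.standard_normal(n + (len(g) - 1) * delay)
        src = signal.sosfiltfilt(sos, raw)
        sd = src.std()
        out.append(src / (sd if sd > 0 else 1.0))
    return out


def generate_epoch_set(cfg: SimConfig, truth: GroundTruth | None = None) -> EpochSet:
    """Generate the full two-condition epoch set with planted coupling.

    Returns an :class:`EpochSet` whose ``meta`` echoes the configuration and
    ground truth (planted edges, gains, hub node) for downstream evaluation.
    """
    if truth is None:
        truth = default_ground_truth(cfg.n_rois)
    if truth.max_node() >= cfg.n_rois:
        raise ValueError(
            f"planted edge references ROI index {truth.max_node()} >= n_rois={cfg.n_rois}")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    def step_samples(band: BandSpec) -> int:
        if cfg.coupling_lag is not None:
            return int(round(cfg.coupling_lag * cfg.fs))
        f_c = 0.5 * (band.lo + band.hi)
        return max(1, int(round(cfg.fs / (6.0 * f_c))))

    if cfg.epochs_per_condition is None:
        counts = rng.integers(1, 4, size=cfg.n_subjects)
    else:
        counts = np.full(cfg.n_subjects, cfg.epochs_per_condition, dtype=int)

    plant = [(truth.sync_band, truth.sync_groups, truth.sync_gain,
              truth.sync_group_amps, truth.sync_group_gains),
             (truth.desync_band, truth.desync_groups, truth.desync_gain,
              truth.desync_group_amps, truth.desync_group_gains)]

    subj_mult = np.exp(cfg.subject_cv * rng.standard_normal(cfg.n_subjects)
                       - 0.5 * cfg.subject_cv ** 2)

    data: dict[str, dict[str, list[np.ndarray]]] = {}
    for s in range(cfg.n_subjects):
        sub = f"sub-{s + 1:03d}"
        data[sub] = {}
        for cond in CONDITIONS:
            epochs = []
            for _ in range(int(counts[s])):
                x = _pink_noise(rng, (cfg.n_rois, n), cfg.noise_exponent)
                for band, groups, pre_gain, group_amps, group_gains in plant:
                    if not groups:
                        continue
                    delay = step_samples(band)
                    sources = _group_sources(rng, groups, n, delay, band, cfg.fs)
                    in_band_sd = np.sqrt(_band_noise_fraction(
                        n, cfg.fs, cfg.noise_exponent, band.lo, band.hi))
                    base = cfg.snr * in_band_sd * subj_mult[s]
                    if group_amps is None:
                        group_amps = (1.0,) * len(groups)
                    if group_gains is None:
                        group_gains = (pre_gain,) * len(groups)
                    for grp, src, g_amp, g_gain in zip(groups, sources,
                                                      group_amps, group_gains):
                        amp = base * g_amp * (g_gain if cond == "pre" else 1.0)
                        m = len(grp)
                        for k, node in enumerate(grp):
                            off = (m - 1 - k) * delay
                            x[node] += amp * src[off:off + n]
                epochs.append(x)
            data[sub][cond] = epochs

    meta = {
        "sim_config": {
            "n_subjects": cfg.n_subjects, "n_rois": cfg.n_rois,
            "epochs_per_condition": cfg.epochs_per_condition,
            "fs": cfg.fs, "epoch_len": cfg.epoch_len,
            "coupling_lag": cfg.coupling_lag, "noise_exponent": cfg.noise_exponent,
            "snr": cfg.snr, "seed": cfg.seed,
            "bandpass": "butterworth order 4, zero-phase forward-backward",
        },
        "ground_truth": {
            "sync_groups": [list(g) for g in truth.sync_groups],
            "desync_groups": [list(g) for g in truth.desync_groups],
            "sync_group_amps": (list(truth.sync_group_amps)
                                if truth.sync_group_amps else None),
            "sync_group_gains": (list(truth.sync_group_gains)
                                 if truth.sync_group_gains else None),
            "desync_group_gains": (list(truth.desync_group_gains)
                                   if truth.desync_group_gains else None),
            "desync_group_amps": (list(truth.desync_group_amps)
                                  if truth.desync_group_amps else None),
            "sync_edges": [list(e) for e in truth.sync_edges],
            "desync_edges": [list(e) for e in truth.desync_edges],
            "sync_gain": truth.sync_gain, "desync_gain": truth.desync_gain,
            "hub_node": truth.hub_node,
            "sync_band": truth.sync_band.name, "desync_band": truth.desync_band.name,
        },
    }
    return EpochSet(fs=cfg.fs, roi_labels=roi_label_table(cfg.n_rois), data=data, meta=meta)
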