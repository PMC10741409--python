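# Methods

`epinet` implements a complete analysis chain for paired two-condition EEG
source-space connectivity studies — pre-interictal versus resting-state
activity in generalized epilepsies being the motivating design — together
with a synthetic data generator that plants known, band-specific coupling so
that every stage of the chain can be validated against ground truth. This
note records the models, the estimators, the numerical conventions, and the
design choices that were genuinely open.

## 1. The synthetic generator

### Signal model

Each subject and condition contributes one or more 6-second epochs of ROI
("scout") time series at 250 Hz. Every ROI carries independent background
noise with power spectral density proportional to `1/f^beta` (default
`beta = 1`) and unit standard deviation — the canonical broadband EEG
spectrum shape.

Coupling is organized in *source groups*: a group is a small set of ROIs
(usually a triangle) sharing one band-limited source, obtained by zero-phase
(forward–backward, 4th-order Butterworth) band-pass filtering of white noise
and renormalizing to unit standard deviation. The k-th node of a group
receives the source delayed by `k` steps; the default step is one sixth of
the band-center period (60° of phase per step), so every within-group pair
carries a strongly *lagged* component. This matters because the connectivity
measure downstream deliberately discards all zero-lag (instantaneous)
coupling: a generator that mixed sources without delay would plant coupling
the estimator cannot see, and a short fixed delay (e.g. 20 ms, only ~25° at
3.5 Hz) leaves most of the coupling in the instantaneous part. A fixed delay
in seconds remains available through `coupling_lag`.

The planted edge set of a subnetwork is the union of within-group cliques;
overlapping groups build hub-centered structures (e.g. three triangles
sharing one node give a 9-edge subnetwork whose shared node has the maximum
degree). Shared group sources — rather than one independent source per edge
— keep per-edge coupling strength degree-independent: with independent
per-edge sources, the in-band power that a high-degree node accumulates
from its other edges acts as interference and can make per-edge coherence
*decrease* when the condition gain increases.

### Condition contrast and amplitude conventions

The two conditions differ only in coupling amplitude: the synchronization
subnetwork (default band delta2, 3–4 Hz) is scaled by `sync_gain` (default
2) in the "pre" condition, the desynchronization subnetwork (alpha1,
8–10.5 Hz) by `desync_gain` (default 0.3). With both gains at 1 the two
conditions are draws from the same process — the null configuration used
for false-positive calibration. Gains may also be given per group.

`snr` is defined as the **in-band** coupling-to-background amplitude ratio:
the source is scaled by the standard deviation of the background noise
restricted to the coupling band (computed analytically from the generation
spectrum). A broadband unit-std convention would be misleading for
narrowband sources: a unit-variance source concentrated in a 1 Hz band
overwhelms the 1/f floor inside that band by more than an order of
magnitude, saturating coherence at any gain. With the in-band convention,
`snr = 1, gain = 2` yields per-edge lagged coherence moving from roughly
0.3–0.5 (rest) to 0.6–0.85 (pre) on simple pairs — a strong but
non-degenerate paired effect.

Optional heterogeneity: per-group base amplitudes (the demo staggers them
0.7/1.0/1.4) and a lognormal between-subject coupling multiplier
(`subject_cv`, default 0 — pilots showed it mostly costs power at these
effect sizes).

### Default problem sizes

Defaults are 21 subjects (the study's cohort size), 2 matched epochs per
condition (the drawn-1–3 mode of the real data's unequal counts remains
available), and **10 ROIs**. The small parcellation is a deliberate choice
driven by the component-forming threshold T = 1.5 used downstream: with 21
subjects, a null edge exceeds t = 1.5 one-sided with probability ≈ 0.075,
so the null supra-threshold graph has mean degree ≈ 0.075·(R−1) and
percolates (grows a giant component) for R ≳ 14. Extent-based NBS then
cannot separate a small planted component from noise percolation no matter
how strong the planted effect is; at R ≤ 12 the null stays subcritical and
the method behaves as intended. This is a property of the fixed threshold,
not of the implementation.

### What the generator does and does not emulate

It emulates: matched-epoch paired designs, 1/f background, band-limited
lagged coupling with condition-dependent strength, hub-centered subnetwork
topology, unequal epoch counts, and (optionally) between-subject effect
heterogeneity. It does **not** emulate scalp-level volume conduction and its
inverse solution, spatially correlated noise, artifacts, nonstationarity
within epochs, or realistic anatomical geometry.  Band-pass sources have
Butterworth spectral skirts, so weaker condition effects also appear in
neighboring bands; in demo runs those components do not survive the
across-band correction. Passing tests therefore
demonstrate that the chain recovers planted effects under clean source-level
conditions; they do not certify performance on real sensor-derived data.

## 2. Lagged coherence

For ROI pair (x, y) at frequency ω, with Welch cross-spectrum S_yx and
auto-spectra s_xx, s_yy:

    rho_GL(ω) = |Im S_yx(ω)| / sqrt( s_yy(ω) s_xx(ω) − (Re S_yx(ω))² )

The band value is the mean of rho_GL over the bins in `[lo, hi)`. Values
are in [0, 1] by Cauchy–Schwarz; the measure is exactly zero for any
instantaneous linear mixture of one signal (volume conduction), and its
magnitude is unaffected by how much instantaneous crosstalk is added.
The implemented form takes the magnitude of the imaginary part (the printed
formula's canonical nonnegative reading, consistent with its use as a graph
weight).

Estimation: Hann-tapered, demeaned 2 s segments with 50% overlap, pooled
over all epochs of a subject/condition *before* the ratio is formed (not by
averaging per-epoch coherences), which stabilizes the estimator at 1–3
epochs per subject. The 2 s segment gives 0.5 Hz resolution so every default
band edge falls on a bin; band edges are half-open to disambiguate the
shared 10.5 Hz boundary.

Numerical conventions: bins where the denominator is non-positive or within
a relative tolerance of 1e-10 of zero (perfect real coherence — e.g. a pair
y = a·x, where rounding makes the denominator a tiny but nonzero number)
contribute 0 and are counted in a logged warning. The matrix is symmetrized,
clipped to [0, 1], and its diagonal forced to 0. Fewer than two total
segments is an error (the variance terms degenerate).

The estimator has a positive small-sample bias (|Im| of a noisy complex
mean): with ~10 segments the null level is ≈ 0.2, falling as the number of
segments grows. Planted effects in the simulations are calibrated to sit
well above this floor.

## 3. Network-based statistics (paired design)

Edge-wise statistics are one-sample t values on the per-subject condition
differences (pre − rest, or its negation for the opposite contrast). Edges
with zero-variance differences get t = 0 if the mean is also zero, and a
large sentinel (treated as supra-threshold, logged) otherwise. Edges with
t > T (default T = 1.5) form a graph whose connected components are the
candidate networks, scored by extent (edge count). The null distribution of
the maximum component extent is built from within-subject condition swaps —
independent sign flips of each subject's difference vector — and
`p_raw = (1 + #{perm max ≥ observed}) / (1 + n_perm)`. Both contrasts are
evaluated; components below the report ceiling (default 0.05 on p_raw) are
returned. Across-band correction is Bonferroni over the number of bands
tested (Benjamini–Hochberg available behind a flag).

Two statistical properties worth knowing:

* **Percolation**: at T = 1.5 with n = 21 the null supra-threshold graph
  percolates for more than ~14 nodes (see §1); keep parcellations small or
  thresholds higher.
* **Burst floor**: for a planted component whose edges all carry strong,
  homogeneous effects, an unbalanced sign-flip pattern (k of n subjects
  unswapped) reconstitutes the component in the null — the flipped t is
  ≈ (2k−n)/√n for estimation-dominated effects — which floors p_raw around
  P(k ≥ 15 | n = 21) ≈ 0.04. Heterogeneous edge strengths (hub-centered
  structures, staggered amplitudes) break the joint reconstitution and
  restore small p values. The planted benchmarks are designed in this
  regime.

## 4. Graph metrics

On the binary topology of a significant network with subject-specific
lagged-coherence weights w_ij:

* **Characteristic path length** L_w: edge lengths 1/w_ij, d_ij the
  weighted shortest path, L_w the mean over ordered pairs (sum divided by
  n(n−1)). Disconnected input is a contract violation (the caller passes one
  NBS component); a zero weight on a topology edge is floored at 1e-6 with a
  loud log message. The 1 − w length map is not used (1/w is the standard
  choice for coherence weights).
* **Clustering coefficient** C_w: weighted geometric-mean triangle form,
  t_i = ½ Σ (ŵ_ij ŵ_ih ŵ_jh)^{1/3}, C_i = 2 t_i / (k_i (k_i − 1)) with
  binary degree k_i (0 when k_i < 2), C_w the mean over all nodes. Two
  weight scalings are implemented: `max` (divide by the graph maximum — the
  generic convention for unbounded weights, making C_w scale-invariant) and
  `unit` (use the weights as-is, valid because lagged coherence is already
  in [0, 1]). The per-subject pipeline path uses `unit`: per-graph max
  normalization cancels exactly the between-condition coupling-level
  difference that the paired comparison is supposed to measure, and
  condition contrasts of a max-normalized C_w on amplitude-scaled planted
  subnetworks are statistically indistinguishable from noise. Reported C_w
  values on the demo data (≈ 0.1–0.3) are on the same scale as published
  coherence-weighted clustering values.

Both metrics are validated to 1e-12 against independent brute-force
references (full Floyd–Warshall relaxation; exhaustive triangle triple
loops) on hundreds of random graphs.

## 5. Node influence

Six per-node components on the **binary** topology of the significant
network (degree k, neighbors Γ(i)):

* NC_i — mean degree of i's neighbors;
* CR_i = 10^(−c_i) · Σ_{j∈Γ(i)} (k_j + 1), c_i the binary local clustering
  (the ClusterRank damping convention);
* BC_i — shortest-path betweenness;
* CI_i = (k_i − 1) Σ_{j: dist(i,j)=ℓ} (k_j − 1) over the exact-ℓ shell
  (ℓ = 2 default, configurable 1–3);
* DC_i = k_i;
* LH_i = h(i) + Σ_{j∈Γ(i)} h(j), h(j) the H-index of j's neighbor degrees.

Each component is min–max rescaled to [1, 100] (constant vectors map to all
100, logged); the composites are

    spreading = (NC' + CR') · (BC' + CI')      hubness = DC' + LH'

each itself rescaled to [1, 100], so the top hub scores exactly 100. Hubs
are nodes above mean + 1 SD when the hubness distribution passes
Shapiro–Wilk at α = 0.05, else above median + IQR.

Group-level scores use the binary formulas above. Subject-level score
tables — the input to the paired spreading permutation test — need
between-subject variation, which a shared binary topology cannot supply, so
they use weighted counterparts of the same six components: degree →
strength (sum of coherence weights), betweenness on 1/w edge lengths,
weighted geometric-mean clustering in the ClusterRank damping, collective
influence and the H-index over strengths (shells still binary). This is the
package's own construction; the group/subject distinction is reported
separately in all outputs.

The spreading test statistic is the median across subjects of the
per-subject (pre − rest) spreading score; the null is within-subject
condition swaps, p two-sided with the +1 correction, Benjamini–Hochberg
across nodes, spreaders at q < 0.05. Two caveats are inherent to this
design and documented rather than patched: the [1, 100] per-graph rescaling
saturates the top-ranked node in both conditions (so the strongest hub's
spreading difference is compressed toward zero), and a sign-flip test of a
*median* has little power against same-sign homogeneous shifts (the flipped
median stays near ±c). The test is well calibrated (verified against exact
2^n enumeration) and powered for mixed-sign heterogeneous shifts.

The desynchronization degree of a decreased-connectivity network is the
group-median drop in node strength (sum of network-edge weights) from rest
to pre, min–max rescaled to [1, 100]; nodes above mean + 1 SD of the
rescaled values are labeled desynchronized. This is an explicit
reconstruction — the quantity is defined here by strength loss, one of
several readings the source material admits.

## 6. Statistical layer

Paired graph-metric comparisons apply Shapiro–Wilk to the differences at
α = 0.05: normal → paired t (effect size Cohen's d_z), otherwise Wilcoxon
signed-rank (effect size r = Z/√n, signed by the direction of the mean
difference; |r| ≤ 1 by construction — published r values exceeding 1 in
magnitude are not reproducible under any standard convention and are not
emulated). Wilcoxon p values are exact up to 25 nonzero differences (zeros
dropped) and use the continuity-corrected normal approximation above.
Bonferroni uses family size = 2 metrics × number of reported networks by
default (configurable); Benjamini–Hochberg q values are monotone-enforced.

## 7. Pipeline and reproducibility

`run_pipeline` chains simulate → connectivity → per-band NBS (+ across-band
correction) → per-subject graph metrics (+ paired tests, Bonferroni) →
node influence (group scores, hub classification, spreading test, desync
degrees) → ground-truth evaluation (edge sensitivity/precision, hub
detection), and writes TSV stage outputs plus a JSON and Markdown report.
All randomness derives from the one configured seed (the simulator consumes
it directly; NBS and influence use child seeds spawned from it), reports
contain no timestamps, and two runs of the same configuration are
byte-identical. Stages are individually re-runnable from the serialized
intermediates through the CLI (`epinet simulate / connectivity / nbs /
graph / influence / run`).

## 8. Validation problem sizes

The shipped validation suite uses deliberately small configurations chosen
once: null calibration at 20 subjects × 20 ROIs × 500 permutations × 200
replicates; subnetwork recovery with a 6-edge butterfly (two triangles
sharing the hub — note that no graph has a 5-edge clique) on 8 ROIs over 20
replicates; hub recovery with the 9-edge three-triangle subnetwork on 10
ROIs over 50 replicates; the demo configuration (both subnetworks, 7 bands)
over a 3-seed panel. Oracle suites run 100–200 random graphs with up to 12
nodes.

## 9. Known limitations

* The estimator's |Im|-bias floor (§2) compresses condition differences for
  weak coupling; very weak planted effects are invisible at 1–3 epochs.
* The extent-based NBS behavior depends qualitatively on the
  threshold/parcellation regime (§3); the package does not warn when the
  null graph is supercritical.
* Subject-level influence scores are a weighted generalization, not a
  published formula.
* The generator's conditions differ only in planted coupling amplitude;
  real condition contrasts also involve topology, spectra, and noise
  changes that this mechanism cannot express (notably, amplitude scaling
  alone cannot move a *max-normalized* clustering coefficient — the reason
  the pipeline defaults to unit normalization for coherence weights).
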