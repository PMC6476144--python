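# Methods

## Problem and pipeline

Dynamic contrast-enhanced MRI of a lymph node produces, for every pixel of
the node, a signal-intensity time course SI(t). The pipeline summarizes each
node by two enhancement-pattern clusters and four semiquantitative
parameters per cluster, then compares clusters and contrast agents across
nodes. All processing is single-slice (2D+time); multi-slice data are a loop
over slices, not a 3D analysis.

Conventions: frames are numbered 1-based in every user-facing interface
(scan 1 is the first acquisition); internally arrays are 0-based and the
conversion happens at the boundary. The default temporal sampling is 70
frames over ~46 minutes (frame interval 46/70 ≈ 0.657 min), with 3
pre-contrast baselines and bolus arrival between frames 3 and 4.

## Motion correction

Model: per-frame 2D translation. Abdominal single-slice motion from
breathing and peristalsis is predominantly translational at this resolution;
rotations and nonrigid deformation are out of scope — series that a
translation cannot fix are meant to be *flagged*, not force-fit.

Estimation: each frame is aligned to a reference frame, by default the 2nd
post-injection frame (`n_baseline + 2`), chosen because contrast is already
present but kinetics are still slow. Both images are high-pass filtered
(subtraction of a sigma = 3 px Gaussian blur) before matching: the
contrast-enhancement difference between frames is spatially smooth, so
removing the smooth component prevents it from biasing the correlation
peak, while fine anatomical structure — which is constant over time —
remains. The shift is the argmax of the cross-correlation of the zero-mean
filtered images, refined to 0.01 px by upsampled-DFT local cross-correlation
(`skimage.registration.phase_cross_correlation`, `normalization=None`).
Plain quadratic interpolation of the correlation peak and spline resampling
were tried first and left 0.07–0.13 px biases on phantom data, violating the
package's own 0.05 px idempotence requirement; the DFT refinement and sinc
resampling (below) reduce all phantom shift errors to ≤ 0.03 px.

Correction: frames are translated by Fourier-domain (sinc) interpolation,
which is exact for band-limited content and wraps at the borders —
acceptable for the ≲ few-pixel shifts in scope.

Residual motion: after correction, shifts are re-estimated on the corrected
frames. If any residual exceeds the threshold (default 1.0 px,
configurable), the series is flagged and the pipeline excludes the node with
an explicit log line and a nonzero exit in the CLI. The threshold semantics
are this package's construction; there is no universal criterion for "not
fully recovered" motion. A zero-variance (constant) frame yields a warning
and an identity shift.

## Normalized differential enhancement

Per node pixel, `NDE(t) = (SI(t) − SI_pre) / DEmax_muscle`.

* `SI_pre` is the mean of the pixel's pre-injection frames (all baselines,
  not just one: averaging reduces noise and is the conventional choice).
* `DEmax_muscle` is computed from the ROI-*mean* muscle curve: with m(t) the
  mean muscle signal at frame t and m_pre its baseline mean, the normalizer
  is max over post-injection frames of m(t) − m_pre. A per-pixel maximum
  would be biased upward by noise. A non-positive value (muscle never
  enhances) is an error — such data cannot be normalized.

NDE is invariant to global multiplicative rescaling of the series and its
baseline frames average to zero to machine precision; both are enforced by
tests.

## PCA screen and k-means segmentation

The node's NDE curves form an n_pixels × n_frames matrix. The PCA screen
reports the percentage of variance per component of the centered matrix
(full SVD). A zero-variance curve set raises an error rather than reporting
100% on one component.

k-means runs on the raw NDE vectors — no additional standardization (NDE is
already muscle-normalized) and no spatial term, so anatomical structure in
the label map is a finding, not an assumption. Defaults: k = 2 (the minimum
able to expose heterogeneity, supported by the PCA screen), squared
Euclidean distance, best of `n_init = 20` k-means++ restarts, seed 0. For
k = 2 with ≤ 12 curves the globally optimal partition is found by exhaustive
enumeration instead, since restarted Lloyd iterations can stall in local
optima on tiny instances; this also makes the small-n behavior exactly
verifiable against a brute-force oracle.

Cluster roles are assigned operationally: the cluster whose averaged curve
has the larger post-injection AUC is "inner", the other "outer"; an exact
AUC tie falls back to the larger peak (recorded in the result). Role
assignment uses enhancement only — the inner/outer anatomical localization
is an empirical observation, and an automated pipeline needs a rule that
does not presuppose it.

## Semiquantitative parameters

All parameters are computed on cluster-averaged NDE curves, time in minutes.

* **AUC** — trapezoidal integral from the last baseline frame to the final
  frame. The integration window and rule are this package's conventions
  (the quantity is standard but its exact construction varies between
  studies); absolute AUC values are therefore comparable only within runs
  of this package. AUC is *not* normalized.
* **wash-in** — maximum of the consecutive-frame slopes between the last
  baseline frame and the frame of maximal enhancement, divided by the
  node's maximal enhancement. A curve that never rises yields 0 with a
  warning.
* **wash-out** — ordinary least-squares slope over the last 40 frames
  (scans 31–70 of the 70-scan protocol; for other lengths the last
  max(40, n_frames − 30) frames, overridable via `washout_frames`), divided
  by the same normalizer. Negative when contrast clears.
* **normalizer** — the maximum of the node-mean NDE curve, shared by both
  clusters of a node (per-node, not per-cluster, normalization; a per-pixel
  maximum would be noise-inflated).
* **volume (%)** — the cluster's share of node pixels on the analyzed slice.

## Statistics

The parameter table has one row per (node, cluster); each node was imaged
with one agent (Gd-DTPA or Gd-BOPTA). The design is a split-plot / mixed
two-way ANOVA: cluster is a within-node factor, agent a between-node factor,
node the blocking unit — the only error structure consistent with paired
inner/outer values per node. Omnibus main effects and the interaction come
from `pingouin.mixed_anova` (checked in tests against a hand-computed
sums-of-squares decomposition on balanced tables).

Within-agent inner-vs-outer contrasts use the pooled within-node error: with
d_i = inner_i − outer_i, the error variance is the variance of d pooled
across agents (df = N − 2) and each agent's contrast is
t = mean(d_agent) / sqrt(s²_pooled / n_agent), two-sided, Bonferroni-adjusted
by factor 2 (two agents per parameter). Reports annotate p < 0.05 (*) and
p < 0.01 (**). A table with identical inner and outer values yields p = 1,
F = 0 rather than an indeterminate ratio. The exact error term and family
used in the original analysis of these data are not published; with this
construction the Gd-DTPA wash-out contrast reaches adjusted p ≈ 0.038 where
the original reports p = 0.056 — same direction, different error term.

## Digital phantom

The phantom emulates the acquisition geometry the pipeline targets: a
64 × 64 grid with an elliptical node (axes 10 × 7 px, ~220 px) split into a
concentric inner compartment (`inner_fraction`, default 0.3 of the node
area, the axes scaled by √fraction) and an outer shell, plus a rectangular
muscle strip; 70 frames, 3 baselines, bolus between frames 3 and 4.

Enhancement kinetics use a product of mono-exponential uptake and washout,
E(t) = A·(1 − e^(−k_in·Δt))·e^(−k_out·Δt) with Δt the time since the first
post-injection frame. No pharmacokinetic meaning is claimed — it is a smooth
uptake-then-washout shape whose rate parameters make recovery checks
analytic. Defaults (chosen once to emulate the enhancement structure
reported for normal nodes: inner AUC roughly double the outer, steeper inner
washout, ~30% inner volume):

| compartment | A (a.u.) | k_in (1/min) | k_out (1/min) |
|---|---|---|---|
| inner  | 2.5 | 1.2 | 0.05 |
| outer  | 1.0 | 0.5 | 0.02 |
| muscle | 0.4 | 0.8 | 0.03 |

Pixel signal is `baseline_signal·(1 + E(t))` (baseline 100 a.u.) plus a
*static anatomical texture* (default 40 a.u., fine + coarse Gaussian-filtered
noise) and additive Gaussian noise (default sigma 5 a.u.; outer-compartment
peak SNR ≈ 17; an optional Rician mode reflects magnitude-MRI noise, the
Gaussian default keeps analytic expectations simple). The texture is
essential for testing registration — without it the pre-contrast frames are
featureless and frame alignment is undefined — and provably does not affect
NDE, clustering or parameters, because a static additive field is absorbed
into SI_pre. Motion, when scheduled, is applied per frame as a Fourier-domain
translation of the noise-free frame before noise is added, so applied shifts
are exactly recoverable and noise is uncorrelated with motion.

What the phantom does **not** emulate: real anatomical shapes, partial-volume
mixing at compartment borders, within-compartment kinetic gradients, bowel
peristalsis deformation (only rigid translation), fat signal, scanner drift.
Passing tests therefore demonstrate the correctness and robustness of the
computations under the stated conditions, not clinical performance.

## Numerical choices and degenerate inputs

* Registration resolution 0.01 px (upsampled DFT factor 100); residual
  threshold 1.0 px.
* k-means seed 0, `n_init` 20; exhaustive optimum for n ≤ 12, k = 2.
* PCA uses the full (exact) SVD solver.
* AUC tie in role assignment → peak-value tie-break, recorded.
* Flat muscle curve → normalizer error; all-identical curves → PCA error;
  constant frame → registration warning + identity; no-rise curve →
  wash-in 0 + warning; wash-out window smaller than 2 frames → error.
* The phantom is bit-reproducible for a given spec + seed; the pipeline
  writes a manifest (config hash, seed, stage timings) next to every output,
  and reruns with the same config are byte-identical.

## Problem sizes

Tests and the acceptance script use 64 × 64 × 70 phantoms (~220 node
pixels), 15–20 simulated nodes per claim, and the packaged 15-node table;
these sizes make every stage's behavior measurable while keeping the whole
suite fast to run routinely.
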