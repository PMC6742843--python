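# Methods

This note records the models, conventions and numerical choices behind
`roinet`, and what the validation suite does and does not establish.

## Synthetic cohort model

Each subject's ROI signal is a T × N multivariate time series built as
follows. A target correlation matrix is assembled from a block structure:
ROIs are partitioned into communities with correlation `r_within = 0.5`
inside a community and `r_between = 0.05` across (defaults; both
configurable). Group differences are *planted* as signed deltas added to
designated seed-target entries of the patient group's correlation matrix
(default: ten edges at +0.3), so the downstream inference has an exact
ground truth. The matrix is scaled by per-ROI standard deviations (default
1) into a covariance.

If the requested structure is not positive definite it is repaired by the
smallest eigenvalue shift (`C ← (C + sI)/(1 + s)`, restoring unit
diagonal); the shift is logged, and a repair that would move any
correlation by more than 0.05 is a hard error rather than a silent
distortion of the requested design.

Innovations are multivariate Gaussian with that covariance, temporally
coloured by a common AR(1) coefficient (default 0.3 — a realistic lag-one
autocorrelation for BOLD sampled at a long TR; a 100-sample burn-in is
discarded so the series starts near stationarity). On top of the signal
the generator adds, per subject:

- a linear drift (default 0.005 signal units/volume — scanner drift);
- a sinusoid at 0.12 Hz, amplitude 0.5 (an aliased-physiology stand-in,
  deliberately outside the analysis band so the filter must remove it);
- global-signal excursions at the scheduled motion-spike times;
- ten unit-variance smoothed nuisance component series injected with known
  Gaussian loadings (scale 0.3) — the ground truth for confound
  regression. The motion parameters are smoothed random walks
  (0.05 mm scale; rotations scaled by 1/50 so a 50 mm lever arm gives
  comparable displacement) plus scheduled spikes on trans-x.

Study-design defaults mirror the emulated cohort: 28 subjects per group,
220 volumes at TR 3.2 s. The default simulation runs at 40 ROIs with 8
seed ROIs (desk-scale stand-in for the full 132-parcel set, which ships in
`roinet.atlas.conn_style_labels()` with its 8 + 2 + 26 seed subsets); the
ROI count is configurable and the construction scales its seed and
planted-edge counts down for very small label sets. All randomness derives
from a single master seed through `numpy.random.SeedSequence` spawning,
with separate streams for each subject's signal and confounds; cohorts are
bit-reproducible.

What the generator does *not* emulate: hemodynamic convolution, voxel-level
spatial structure and spatially correlated noise, non-stationarity, subject
heterogeneity in covariance (within a group every subject shares one
covariance), and realistic outlier/physiology coupling. Passing tests
therefore demonstrate correctness of the *pipeline machinery* and its
statistical operating characteristics under a faithful stochastic model of
the study design — not robustness to every artefact of real BOLD data.

## Denoising

The stage order is detection → regression → detrend + filter, and tests
assert it. Outliers are volumes with framewise displacement above 0.9 mm
(FD uses the 50 mm small-angle lever-arm formula; FD(0) = 0) or an absolute
z-scored global-signal first difference above 5 — configurable thresholds
mirroring common "intermediate" artifact-detection settings. Scrubbing is
implemented as one indicator regressor per flagged volume rather than
deletion: the series keeps its length, which keeps the spectral step well
defined, and the fitted residual at a flagged volume is exactly zero.

The nuisance design is intercept + 6 motion parameters + their first
differences (first row zero) + 10 component series + scrub indicators.
Rank-deficient designs drop dependent columns (pivoted QR, warning names
them); a design as wide as the series is a hard error. Residuals are
orthogonal to every retained column to machine precision.

Filtering is an ideal (rectangular) frequency-domain band-pass after linear
detrending: an rFFT bin at frequency f is retained iff 0.008 ≤ f ≤ 0.09 Hz
(inclusive edges — the boundary-bin convention), everything else zeroed.
The sharp band edges match a stated frequency interval better than an IIR
approximation would; the filter is a projection, hence linear and
idempotent, and that is tested. The band-pass alone is idempotent; the
detrend+filter composition is not (two non-commuting projections), which is
why the API exposes both `bandpass_filter` and `bandpass_detrend`.
Regression and filtering are applied sequentially, not simultaneously.

## Connectivity conventions

FUN is the Pearson correlation matrix; EFF is `b(i→j) = cov(i,j)/var(i)`
with row i the seed/predictor. Series are *not* variance-normalised before
EFF — normalising would collapse the slope onto the correlation and erase
the asymmetry the regression model is there to expose. Both matrices pass
through `z = artanh(v)` after clipping v into ±(1 − 10⁻⁶); the clip exists
because regression slopes can exceed 1 where artanh is undefined, and every
clip is counted and logged. The diagonal is masked (NaN) and never enters
thresholding or inference. Constant ROIs yield undefined entries with a
warning and are excluded downstream rather than imputed.

## Graph topology

Binarisation is strict absolute thresholding, `|z| > 0.4` by default: the
boundary value makes no edge, and a strong anticorrelation is topologically
identical to a strong positive correlation. Asymmetric EFF matrices are
symmetrised before the undirected metrics — OR rule by default (an edge if
either direction passes), AND and mean available by configuration.

Distances and geodesic counts come from BFS from every node; betweenness
uses Brandes' dependency accumulation and is verified against a
Floyd–Warshall + explicit path-enumeration oracle (exhaustively on all 52
non-isomorphic graphs up to 5 nodes, and on 200 random 6–8-node graphs) as
well as against networkx. Conventions for degenerate cases: cost divides by
N−1 (proportion of *possible* neighbours, so a fully connected node has
cost 1, even though "proportion of nodes" is the looser folk definition);
betweenness is pair-normalised by (N−1)(N−2)/2 (raw Freeman sums available)
and defined as 0 for N < 3; average path length averages only over
*reachable* nodes and is undefined (NaN, excluded from group statistics,
never imputed) for isolated nodes, whereas global efficiency counts
unreachable pairs as 0 — the standard way the two integration measures
split the disconnection question; clustering and local efficiency are 0
for nodes with fewer than two neighbours.

## Group inference

Edge-wise comparisons use the pooled-variance two-sample t (the GLM [1 −1]
contrast; Welch is deliberately not used), sign convention patients minus
controls. Degenerate rows follow fixed conventions: zero pooled variance
with equal means gives t = 0, p = 1; with unequal means the row is flagged
infinite-t with p → 0 and logged. FDR is Benjamini–Hochberg (not BY; via
statsmodels), by default jointly across all tested connections; a per-seed
scope is available since either reading of "corrected across connections"
is defensible. Tested connections are every pair with at least one seed
endpoint: unordered pairs once for FUN (seed-seed pairs not double
counted), both directions for EFF. Node-wise comparisons run the same t +
BH machinery per topology metric across nodes, dropping undefined values
(isolated-node path lengths) with logged counts and excluding nodes left
with fewer than two defined values in a group.

## Validation and its limits

Because the emulated study design reports region lists rather than effect
sizes, inference is validated on operating characteristics, all recomputed
at run time:

- **FDR behaviour**: over 200 replicate cohorts at the study conditions
  (n = 28/group, T = 220, 40 ROIs, ten +0.3 planted edges, 284 tested
  connections), the mean false-discovery proportion among retained edges
  is compared to the 0.05 retention level with its Monte-Carlo standard
  error. Measured values land at ≈ 0.05 (seed-dependent, roughly
  0.051–0.058): null-edge p-values are exactly calibrated (checked
  empirically at tail quantiles), and the small excess over the
  independence value q·m₀/m ≈ 0.048 reflects BH step-up under the positive
  dependence of edges sharing seed ROIs and target communities — a
  property of the procedure at these conditions, not of the
  implementation.
- **Power**: all ten planted edges are recovered with the correct sign in
  well over 80% of replicates (in practice essentially always at delta
  0.3).
- **Global null**: with no planted effects the mean significant-edge count
  over 20 replicate cohorts stays within the BH bound.

Problem sizes (40 ROIs, 200 replicates, 20 null replicates) are the
package's desk-scale defaults; they complete in a few minutes on one CPU.
The deterministic contracts — graph-metric oracle equivalence, filter
retention/suppression ratios, nuisance-removal ground truth, byte-identical
reruns and stage-chaining equality — are asserted exactly or at the stated
numerical tolerances (1e−10 for graph metrics, 3/√T sampling bounds for
simulation fidelity).

## Known limitations

- The pipeline starts at extracted ROI series; no spatial preprocessing,
  image I/O or true voxelwise aCompCor (component series are supplied or
  simulated, with known loadings standing in for WM/CSF principal
  components).
- Single fixed threshold (0.4) binary graphs; no weighted metrics,
  modularity, or small-world indices.
- No covariate adjustment, permutation inference or network-based-statistic
  clustering.
- EFF "effective-like" slopes are bivariate and contemporaneous — they
  encode variance asymmetry, not causal direction or lagged influence.
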