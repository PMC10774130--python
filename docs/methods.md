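# Methods

This note documents the models implemented in `facekit`, their assumptions,
the main tunable parameters, what the synthetic fixtures do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Data model and train/test segmentation

Keypoints are per-frame `(x, y, likelihood)` records under a named schema.
The default schema has 13 bodyparts — eye (4), mouth (2), nose (4),
whisker (3); an extended 15-point variant adds a paw and a nose-bridge
point, both excluded from analyses by default. Neural prediction uses the
eye + nose + whisker subset (11 bodyparts, 22 coordinates), because mouth
keypoints are not visible from the side view used during neural recordings.
Coordinates are 0-based pixel centers, `x` = column, `y` = row, origin
top-left. Keypoint files are long CSV (`frame,bodypart,x,y,likelihood`) or
HDF5 mirroring the arrays; neural recordings are NPZ/HDF5 with `activity`
(neurons x timepoints), `positions` (micrometres, 2-D) and `rate` (Hz,
nominally 3).

All fitting modules share one split: the recording is cut into 10
equal-length contiguous segments (remainder frames go to the last); the
first 75% of each segment trains, the next `ceil(gap * rate)` frames are
discarded (gap 3 s for neural prediction, 2.6 s for the autoregressive
model) and the rest tests. The gap breaks temporal autocorrelation leakage
between train and test. Segment arithmetic uses floor for the train count;
a segment whose test block would be empty raises rather than silently
shrinking.

## Keypoint tracker

A U-Net-style convolutional network maps a normalized grayscale frame
(1st percentile -> 0.0, 99th -> 1.0, linear, unclipped) to per-keypoint
heatmaps and x/y location-refinement maps at 1/4 resolution (256 -> 64).
Heatmap cells use per-cell sigmoids so the peak value is a confidence in
[0, 1]; refinement maps carry the full-resolution offset from each cell's
pixel (cell (r, c) <-> pixel (c*4, r*4)) to the keypoint, restoring
sub-cell accuracy. Decoding takes the argmax cell (row-major first on
ties) plus its refinement offset; an all-zero heatmap decodes to the image
center with likelihood 0 and a degeneracy flag.

Training targets are unit-peak Gaussian bumps (sd 2 cells) plus refinement
offsets; the loss is binary cross-entropy on heatmap logits plus smooth-L1
on refinement maps within 4 cells of the target, weighted 1 : 0.05, with
NaN-labeled (invisible) keypoints masked from both terms. The optimizer is
Adam, batch 8, base LR 4e-4 held for the first 30/36 of the epochs, then
LR/10, then LR/25; weight decay 0. Fine-tuning reruns the same loop from a
trained network at LR 1e-4 with weight decay 1e-3 for 36 epochs.
Augmentations: random crop (scale U(0.8, 1.0)) + resize, contrast gain
U(0.7, 1.3), and horizontal flip (p = 0.5) only when a left/right
bodypart-pair map is supplied. Exact encoder widths are configurable;
the default profile is (16, 32, 64, 128) and the desk-scale profile used
by the synthetic experiments is (8, 16, 32, 48) at 128 px input, which
keeps CPU training of a 50-frame toy problem in the minutes range. The
network and all gradient math run in float32 on a small in-repo
reverse-mode autodiff engine (`facekit.nn`), whose every op is
finite-difference checked in the test suite.

## Trace quality control

Three passes. (1) Likelihood outliers: each bodypart's likelihood trace is
baselined with a 4 s Gaussian filter (reflective edges); frames whose
residual falls below -8 times the residual's standard deviation are
flagged. (2) Trace outliers: a frame is flagged when its Euclidean step
from the previous frame exceeds 25 px *and* it has not simply returned to
its position two frames earlier — the second condition stops the recovery
frame after a single-frame glitch from being flagged while a persistent
step still flags its transition frame — or when either coordinate deviates
from its 1 s running median by more than 25 px. (3) Imputation: flagged
samples are bridged by linear interpolation between neighbouring good
samples, the bridged trace is median-filtered with a 300 ms window
(windows rounded to odd frame counts), and flagged frames take the
filtered values; unflagged samples are never modified.

The imputation presumes the trace is smooth at the 300 ms scale. For
dynamics faster than that (10 Hz whisking sampled at 50 Hz), the median
filter cannot reconstruct mid-oscillation values and imputation errors of
order the oscillation amplitude are expected; the recovery fixtures
therefore use OU traces with tau >= 2 s, and this is a documented
limitation for fast keypoints in real data.

## Autoregressive timescale estimation

Each keypoint coordinate is convolved causally with unit-sum exponential
kernels, decay constants log-spaced over [0.04, 5] s (10 kernels), plus
the tau -> 0 limit of the same family — a delta kernel, i.e. the raw
trace. The delta element matters: the finite-tau kernels alone cannot
reconstruct the instantaneous sample, which caps short-lag prediction well
below the AR(1) optimum (on an OU fixture, test VE 0.27 against an
achievable 0.34). A joint multi-output ridge regression (lambda 1e-4
per-sample on standardized features) maps the features at time t to all
coordinates at t + lag, refit separately per lag over a grid of 0.02-10 s
in 20 ms steps and 10-40 s in 500 ms steps. VE on test segments gives a
curve per keypoint; the timescale summary is the first lag (linearly
interpolated) where VE drops to half its value at the 20 ms reference,
`inf` if never reached, undefined when the reference VE is not positive.

Two finite-sample effects bias half-decay estimates slightly downward on
slow processes: the empirical autocorrelation of a tau = 5 s process over
tens of minutes fluctuates below its expectation, and the many temporally
correlated basis features carry far fewer effective samples than frames,
so the fit generalizes slightly below the in-sample optimum at long lags.
At 30-45 min of 50 Hz data the estimates sit within ~20% of the analytic
`0.02 + tau ln2 / 2`, well inside the 25% band the synthetic experiments
check, and group ordering (nose before eye) is robust.

## Behavior-to-neural encoding

Activity is z-scored per neuron (zero-variance neurons flagged and
excluded from VE denominators) and reduced to its top 128 PCs; predictions
target `Y = V S` and are projected back through `U` for per-neuron VE
(populations under 200 neurons are predicted directly). VE follows the
R-squared convention, `1 - SSE/SST` with SST the squared deviation of the
test trace from its own mean, so a mean predictor scores exactly 0.

**Reduced-rank regression.** Closed form: ridge solution (lambda added to
the raw input covariance; 1e-6 for behavior, 1e-1 for peer prediction)
followed by projection of the fitted values onto their top-r output-space
singular directions. Full rank reproduces ridge exactly; rank 21 is the
default for keypoint inputs, 128 for movie PCs. Whole-frame SVD of a video
(`movie_pcs`) is provided as a simple stand-in for blockwise video-SVD
pipelines.

**Deep encoder.** Core: linear (n_in -> n_in, no bias), temporal
convolution (10 filters, 51 frames ~ 1 s at 50 Hz, centered, zero-padded,
full cross-channel), ReLU, dense 50 + ReLU, dense 256 + ReLU; the 256-dim
output is the "deep behavioral features", computed at the behavior rate
and subsampled at the nearest behavior frame at or before each neural
frame time for the linear readout (256 -> 128 PCs). Trained with AdamW,
LR 0.1, weight decay 1e-4, 300 epochs, annealed x0.1 at epochs 200 and
250; one batch per training segment. Small-data adjustments: under 2,000
neurons LR and decay are divided by 10; under 1 h of training data they
are halved and 100 epochs are dropped. Weights are He-initialized then
scaled by 0.4 (toward the uniform fan-in convention); the smaller initial
function norm measurably improves held-out VE at these data sizes. Note
the temporal receptive field is ~±0.5 s: behavioral structure smoothed
over much longer windows cannot be represented by the core and is learned
poorly.

**Peer prediction.** The field of view is split into 200 um vertical
strips by x-position (depth ignored); even strips form one population,
odd the other. Each side's top-128 PCs are predicted from the other's by
RRR (rank 127, lambda 1e-1) fit on training segments; projecting through
the target side's loadings gives per-neuron test VE — the explainable
variance (EV). Normalized VE is per-neuron VE/EV where EV > 1e-3, or
population-level mean VE / mean EV. On planted populations with known
shared-variance fraction `1 - f`, mean EV lands within ~0.03 of `1 - f`
at 1 h of 3 Hz data; residual downward bias is regression shrinkage at
finite T. Cumulative VE across PCs and EV-normalized scaling curves over
neuron/time fractions follow the same conventions.

## Clustering and locality

Scaled k-means models each z-scored neuron as a signed scalar gain times
its cluster's temporal pattern. Updates alternate: optimal gain per
(neuron, cluster) is `(x.mu)/(mu.mu)`; assignment minimizes the gain-optimal
residual; means are gain-weighted averages. Gains are unconstrained in
sign; each mean's sign is fixed so the majority of member gains are
positive. Initialization is kmeans++ seeding on row-normalized activity;
emptied clusters are re-seeded from worst-fit neurons; iteration stops at
an assignment fixpoint once the objective has also converged (with stable
assignments the updates are a power iteration — at k = 1 this converges to
the rank-1 SVD). The objective never increases and is recorded.

The locality index of a cluster is KL(P || Q) between the cluster's
spatial histogram P and the all-neuron histogram Q over 200 um bins
anchored at the data bounding box; Q takes a 0.5 pseudocount in occupied
bins before normalization. Low KL = spatially diffuse. Correlating each
cluster's locality with its behavior-prediction r (Pearson r between mean
member prediction and mean member activity on test indices) links spatial
compactness to unpredictability.

## Behavioral-state HMM

Discrete K-state model (default 50; fixtures use 10-20) with categorical
initial distribution, row-stochastic transitions and spherical Gaussian
emissions. The transition matrix is reparametrized as a row-softmax of an
unconstrained log-transition matrix Q (initialized Q_ii = 3, Q_ij = 0);
initial-state logits start at 0; emission means start at random data
samples. The emission scale is frozen, never learned: after per-feature
standardization, sigma^2 = n/256 — 1.0 for 256-dim deep features, 22/256
for the 22 keypoint coordinates — so feature sets of different
dimensionality weight the emission term comparably. Deep features are
downsampled 10x (50 -> 5 Hz) by striding before fitting.

Fitting ascends the exact marginal log-likelihood (scaled forward
recursion, stable to T = 1e5) by Adam (LR 0.05, 400 iterations, full
sequence). Gradients are the analytic forward-backward quantities —
posterior transition counts for Q, posterior-weighted residuals for the
means — exactly what reverse-mode differentiation of the forward recursion
yields; the implementation is finite-difference checked and the
log-likelihood is verified against brute-force path enumeration. On
5-state fixtures the gradient fit matches or exceeds an
expectation-maximization baseline (hmmlearn, same initialization) in
held-out likelihood, with transition rows recovered to total-variation
< 0.01.

State statistics: Viterbi paths (log-space max-product, ties to the lowest
state index, initial distribution b at t = 1); lifetimes `-log(1 - A_ii)`
(absorbing rows flagged); the off-diagonal-normalized matrix B (self
transitions zeroed, rows renormalized); state sorting by maximizing
`sum B_sorted[j, i] * F[j, i]` with `F_ji = -log((i - j)^2)` for j < i and
0 otherwise — exhaustive for K <= 8, else seeded greedy insertion + swap
hill climbing. That objective scores 0 for any mass on the first
superdiagonal *or* anywhere below the diagonal, so ties break toward the
permutation with the larger above-diagonal mass, matching the
forward-running intent of the band target. n-nearest cumulative transition
curves, reverse and two-step transition probabilities (two-step =
max over intermediate states of the product), a baseline equal to the mean
off-diagonal entry of B, forward-sequence length histograms (consecutive
duplicates collapsed, maximal strictly increasing runs in the sorted
order), and state-conditioned neural trial averages (trials =
uninterrupted same-state runs, alternating train/test trial split, top-n
neurons selected on train trials, reported on test trials) complete the
battery. The temporal control is a seeded whole-timepoint permutation.

## Synthetic fixtures: what they emulate, and what they do not

The generators define the study conditions for every experiment:

* **Face scenes** render each keypoint as a Gaussian blob with its own
  amplitude and width on a ring inside the frame, moved by group-specific
  OU dynamics (eye tau 5 s, nose 0.5 s) and ~10 Hz pseudo-random whisking
  (sinusoid with OU phase noise and envelope), reflected at a 2-blob-width
  margin, plus pixel noise. A "shifted domain" variant changes blob
  contrast, size, background and noise to emulate another lab's video.
* **Keypoint traces** use the same dynamics without rendering; whisking
  amplitude is 0.6x the drift amplitude (default 6 px) so natural motion
  stays below the 25 px artifact threshold, as in real recordings where
  that threshold is diagnostic of tracking failures.
* **Planted-encoder populations** drive latents through a fixed random
  ReLU-family network of the 22 neural-prediction coordinates: 4
  rectifier-pair units `relu(u) + relu(-u)` (= |u|; zero linear component
  under symmetric inputs, yet representable by one ReLU hidden layer) and
  2 purely linear units, causally smoothed with tau 0.6 s — inside the
  encoder's ±0.5 s receptive field and slower than nose/whisker motion, as
  behavioral-state-level latents are. Each neuron mixes behavior-driven
  latents, shared non-behavioral low-rank signals and independent noise
  with chosen variance fractions, so explainable variance and
  behavior-explainable variance are known exactly. Positions are uniform
  (diffuse) or clustered per dominant latent.
* **HMM sequences** sample a transition matrix with controlled
  self-transition probability and forward-cycle bias, plus Gaussian
  emissions from random means.

None of the fixtures emulate calcium-indicator dynamics, deconvolution
artifacts, photobleaching, non-stationary behavior, occlusions beyond
planted teleports, or realistic mouse-face appearance. Passing experiments
therefore certify the algorithms against their own generative assumptions
— recovery, calibration and ordering properties — not field performance on
real videos or recordings.

## Experiment sizes

The synthetic experiments use CPU-scale problem sizes chosen to make their
statistics stable: 30 min of 50 Hz behavior (45 min for the timescale
estimates) with 400-800 neurons at 3 Hz for encoding analyses; 50 training
frames at 128 px with reduced channel widths for the tracker; T = 20,000
samples for 5-state HMM recovery; and K = 20 states at 5 Hz for the
deep-feature vs keypoint state-dynamics comparison.

A caveat on the state-dynamics comparison: on this fixture the
transition-sparsity ordering (deep features transition to fewer near states
than keypoints) is robust across random seeds, while the median-lifetime
ordering is marginal — the slow eye coordinates (tau 5 s) already give the
keypoint model long dwells, and the learned deep features are only
moderately slower. On real recordings the published effect is driven by
high-level behavioral states that this keypoint-driven fixture can only
partially emulate.
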