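# Methods

## Sliding-window connectivity

A subject is an m × T matrix of regional BOLD signals (the time axis is the
0-based volume index; the repetition time is carried as metadata only,
because every downstream quantity is defined per volume). Windows of length
t advance by step s; only fully contained windows count, so the number of
observed networks is n = ⌊(T − t)/s⌋ + 1. Exact division would be
non-integer for the default setting (T = 140, t = 6, s = 5), and a partial
window has no physical meaning, so floor division is the only consistent
reading. Within each window the pairwise Pearson correlation forms one
*observed snapshot*, timestamped at the window centre start + (t − 1)/2 so
that interpolation targets and the reference-window protocol (below) live on
the same axis. Pearson correlation is scale-invariant, so no per-region
normalization is applied before windowing. A zero-variance segment makes the
coefficient undefined; it is substituted with 0 and logged, which keeps
matrices finite without inventing structure. Defaults t = 6, s = 5 follow
the window-size sensitivity sweep (`window_size_sweep`), which shows the
interpolation loss minimized near length 6 on synthetic data of this scale.

## Continuous-time snapshot dynamics

The state is the full m × m correlation matrix X(t); each node's feature
vector is its correlation profile (d = m). The model is

- encoder: X_h = tanh(X W_e + b_e), with hidden width d_h
  (default min(m, 32); full rank relative to m whenever affordable, so the
  affine decoder can represent the observed matrices exactly),
- hidden dynamics: dX_h/dt = tanh(Â X_h W_h + b_h), with
  Â = D^{-1/2}(A + I)D^{-1/2} the self-loop-normalized operator (spectral
  norm ≤ 1, so the linearized dynamics cannot be operator-amplified),
- decoder: X̂ = X_h W_d + b_d, linear.

The static coupling graph A is the element-wise mean of the observed
|correlation| matrices, proportionally thresholded to the strongest 15% of
off-diagonal weights (density configurable). No dynamic coupling is
attempted: the operator is a fixed summary of which regions interact, while
all temporal structure lives in the hidden state.

An optional terminal label loss exists in the configuration as a disabled
hook; node-level semantic labels are never used — subject-level
classification happens downstream on snapshot features.

### Training and differentiation

The running loss is the mean over observed snapshots of the per-element ℓ1
(optionally ℓ2) discrepancy between the decoded trajectory and the observed
matrices. The trajectory starts from the first observed snapshot at its
window-centre time and is integrated with a fixed-step solver — Euler or
classical RK4 (default, step 0.2 volumes) — on a grid anchored at that
time. Gradients are computed discretize-then-optimize: hand-written
reverse-mode sweeps through the unrolled solver steps (stage values are
recomputed on the backward pass; checked against finite differences to
~1e-9 relative error in the test suite). Optimization is Adam
(learning rate 0.02, 300 epochs by default); the best-loss parameters over
the run are kept, and one seed controls the weight initialization, making
fits bit-reproducible. Observation times must fall on the integration grid
(the default step divides the default window spacing); requested prediction
times between grid points are read off by linear interpolation between
bracketing states, an O(dt²) error well below solver accuracy.

An adaptive solver (scipy RK45) is available for integration and
prediction; training requires a fixed-step solver because the gradient
path is the unrolled discretization. Fitting with `adaptive` raises a clear
error rather than silently switching.

### Interpolation and extrapolation

The trained span is declared to be the full volume axis [0, T − 1], not
just the window-centre range [(t−1)/2, …]: the per-volume in-snapshot
convention requires all T volumes, and the few volumes before the first
window centre are reached by a short backward integration leg (half a
window at default settings). In-snapshots are decoded at each requested
time and symmetrized (M + Mᵀ)/2; out-snapshots continue the trajectory for
`horizon` unit steps past T − 1 and are additionally clamped to [−1, 1],
since extrapolated decodings may drift outside the correlation range.
Clamping never enters the training loss.

## Evaluation against reference windows

A predicted snapshot at volume i is scored against the Pearson network of
the signal segment of the training window length starting at i − 3 (the
reference window re-centred near i for length-6 windows; the published
protocol's bracket order is read as a typographical inversion). Losses are
unnormalized upper-triangle sums — ℓ1 the sum of absolute differences, ℓ2
the Euclidean norm — consistent with loss magnitudes that grow with network
size; a per-edge mean is available behind a flag. Edge indices whose
reference window would leave the series are skipped, not padded.
Out-snapshots can only be scored when the series extends past the trained
span, i.e. on synthetic data where the future signal is simulable.

## Small-world validation

Snapshots are binarized by proportional thresholding (default density 0.15,
a standard operating point for brain networks; ties at the cutoff break
lexicographically so the edge set is deterministic). C is the transitivity
3·G_Δ / (3·G_Δ + 2·G_Λ) = 3·triangles / Σᵢ C(kᵢ, 2); L is the mean
shortest-path length over connected pairs, computed on the largest
component when the graph is disconnected (flagged in the record — the
common brain-network convention). The null ensemble is 20 degree-preserving
double-edge-swap rewirings (10 swaps per edge); published notation hints at
several reference classes but defines none, and the γ, λ formulas require a
single rewired ensemble, so one is used. Graphs admitting no valid swap
(stars, complete graphs) are their own reference, which correctly fixes
σ = 1 for a complete graph. Per-snapshot null seeds derive from a master
seed plus the snapshot index.

## Features and classification

Each snapshot contributes one global clustering coefficient; a subject's
feature vector concatenates in-snapshots then out-snapshots (210 entries at
default scale). Classification is stratified 5-fold cross-validation with a
fixed seed (no validation scheme is published for this task; the protocol
is always echoed in reports). Features are standardized inside training
folds only. Default classifiers: RBF-kernel SVM (C = 1), KNN (k = 5),
Gaussian naive Bayes. Sensitivity is recall on the disease group,
specificity recall on the control group; aggregate metrics come from
confusion counts pooled over folds, AUC from pooled decision scores. Only
binary disease-vs-control contrasts are supported.

## Synthetic data

`generate_subject` draws each volume from a modular equicorrelation
covariance: within-module correlation w(t), between-module correlation b,
unit variances, plus additive white noise of sd σ_n (which dilutes observed
correlations by 1/(1 + σ_n²)). Positive semi-definiteness of every implied
covariance is checked at generation. Drift models: static, linear ramp, or
sinusoid of amplitude 0.1 and period 70 volumes (the default — a slow
oscillation comparable to the acquisition length, giving the dynamics model
genuine temporal structure to learn). Defaults m = 30, T = 140, 3 modules,
w = 0.5, b = 0.1, σ_n = 0.3: desk-scale but shaped like a real acquisition;
the 264-region scale is available but not required by any test. Group
effects shift w, which moves the clustering coefficient of thresholded
graphs — the downstream feature — rather than signal means, which would not.

What the generator does *not* emulate: hemodynamic response convolution,
scanner drift and motion artifacts, spatial autocorrelation of real
atlases, and temporal autocorrelation of BOLD noise (volumes are
conditionally independent draws). Passing tests therefore demonstrate the
pipeline's correctness and sensitivity under controlled covariance
structure, not performance on real cohorts.

`generate_dynamics_truth` provides the interpolation oracle: the trajectory
is the correlation normalization of M(t) Σ₀ M(t) with M(t) = e^{−rate·L·t}
for the Laplacian of a random connected graph — computable exactly at any
time through the Laplacian eigendecomposition, and a valid correlation
matrix at every t. Recovery tests fit the model to 4/7/10 snapshots evenly
spaced on [0, 9] (solver step 0.25 so all observation times are on-grid)
and score held-out times against the closed form.

## Numerical choices and degenerate inputs

- Eq-style floor division for window counts; windows are half-open
  [start, start + t).
- Correlations clipped to [−1, 1] after symmetrization to absorb rounding.
- Proportional thresholds keep round(density × #pairs) edges and refuse
  densities that keep none.
- Training diverging to non-finite loss raises with advice (smaller
  learning rate / step size) rather than returning garbage.
- σ is marked undefined (NaN) when the null clustering mean is 0, instead
  of dividing by zero.
- Manifest paths are stored relative to the manifest so cohorts relocate.

## Problem sizes

Test and acceptance runs use m = 30, T = 140 for full-length pipeline
checks, m = 5–15 for oracle comparisons, and 10 subjects per group for
classification, with Euler/step-1.0 solver settings for cohort-scale fits —
sizes chosen so the whole suite exercises every stage at realistic shape on
a single CPU.

## Known limitations

- The coupling graph is static; slow reorganization of the interaction
  structure itself is only captured through the hidden state.
- Extrapolation quality decays with horizon: the ODE relaxes toward a
  fixed point, so distant out-snapshots lose the variance (and eventually
  the small-world structure) of observed networks.
- ℓ1 training treats all edges equally; no distinction between within- and
  between-module edges.
- Multi-class staging (e.g. ordered disease severity) is out of scope; run
  multiple binary contrasts instead.
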