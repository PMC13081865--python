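# Methods

This note records the models the package implements, the defaults it ships,
the numerical choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Low-alpha reconstruction

Generalized eigendecomposition contrasts a narrowband covariance S (8–10 Hz,
4th-order Butterworth, zero-phase forward–backward) against the broadband
covariance R of the same mean-centred recording.  Both are regularized with
Ledoit–Wolf shrinkage toward a scaled identity (scikit-learn's closed-form
estimator, applied independently to S and R), which keeps S positive
definite so `scipy.linalg.eigh(R, S)` is well posed.  Eigenvalues are the
broadband-to-alpha variance ratio, so components are sorted ascending and
the *smallest* eigenvalues carry the strongest alpha enrichment.

Retention uses a relative-stability rule on the ascending eigenvalues: scan
consecutive gaps and retain components 1..i where i is the first index whose
following gap is less than 5% of the preceding eigenvalue, clamped to
[3, 12].  The left endpoint of the violating gap is included — the most
literal reading of the rule, fixed so tests are well defined.  If no gap
violates, the cap (12) applies.

Component time series are `wᵀ` × (mean-centred alpha data).  Spatial maps
use the standard pattern-from-filter construction: (alpha covariance) × w.
Each map is sign-flipped (together with its filter) if its largest-|loading|
channel is negative, then min–max rescaled to [0, 1].  Back-projection sums
`(1/λ_k) · map_k · ts_k`, so better-separated components contribute more.
Reconstruction is linear in the data for fixed filters.

The post-reconstruction "posterior-dominant topography" quality check of the
original workflow is visual; no automated criterion is imposed here — the
GED model object exposes its maps so a user can inspect concentration.

## Connectivity

Instantaneous phase comes from the analytic signal (Hilbert transform) of
the *continuous* reconstructed record, computed once before segmentation;
this avoids per-epoch transform edge artifacts.  (Whether phase should be
extracted per window instead is not determined by the source procedure; the
continuous default is the package's choice, and a `phase_mode="per_epoch"`
switch provides the alternative for sensitivity analysis.)

The complex PLV of a channel pair over T samples is `(1/T) Σ exp(i Δφ)`;
ciPLV = Im(PLV)/√(1 − Re(PLV)²), with the guard ciPLV := 0 when Re² = 1
(the numerator is then necessarily zero; 0 is the limit value).  Edge
weights are |ciPLV|, giving symmetric zero-diagonal graphs in [0, 1].
Epoch-level graphs (60 per subject; 3 s epochs, 300 samples at 100 Hz)
average complex PLV over ten non-overlapping 30-sample windows before
conversion; the global graph computes whole-epoch complex PLV per epoch,
averages across epochs, then converts.  For simulated per-cell membrane
voltages — where volume conduction is absent and zero-lag coupling is real —
the graph is |Pearson correlation| instead.

## Topology and nodal signals

Each graph decomposes into its maximum spanning tree (Kruskal on descending
weights; ties broken by lexicographic edge order, so the split is
deterministic) and the complementary cyclic edge set.  On a connected
N-node graph the tree has exactly N−1 edges and the two sets partition all
positive-weight edges; disconnected graphs are rejected by name.  The MST
depends only on weight ranks, so any strictly increasing reweighting leaves
it unchanged.  Degenerate ties could in principle be ordered differently by
other birth–death constructions; the tie rule here is documented rather than
inferred.

Nodal signals: 0D and 1D participation are node strengths within each
subgraph, z-scored across electrodes (population SD); alpha power is the
per-electrode periodogram integral over 8–10 Hz, computed per 3 s epoch for
the epoch regime and over the whole 180 s window as a single block for the
global regime.  The alpha-power signal is left unstandardized — the
z-scoring convention attaches to the topology strengths — and a flag exposes
the alternative.

## Graph-spectral features

The normalized Laplacian L = I − D^(−1/2) W D^(−1/2) has eigenvalues
(graph frequencies) in [0, 2] with λ₁ = 0 and eigenvector ∝ √degree on a
connected graph.  For a signal x with graph Fourier coefficients x̂ = Uᵀx:
smoothness is the Dirichlet energy xᵀLx (= Σλᵢx̂ᵢ²); spectral entropy is the
Shannon entropy (nats) of pᵢ = x̂ᵢ²/Σx̂ⱼ², bounded by [0, ln N]; frequency
spread is the p-weighted standard deviation of the frequencies.

Dynamic summaries treat each epochwise feature as a 60-point series: SD
(sample, n−1), MAFD (mean |first difference| over the 59 steps), and sample
entropy with m = 2 and tolerance r = 0.2 × the median across-subject SD of
the matching series — nine r values (3 families × 3 descriptors) computed at
the cohort level *before* any per-subject normalisation.  In single-subject
use, r falls back to 0.2 × the subject's own series SD.  SampEn follows the
standard template-matching definition with self-matches excluded and both
template sets of size n−m; if either count is zero the ratio is regularised
by the smallest positive float and a large finite value is returned.
Dynamic summaries are computed on raw (unstandardized) series.

The 45 features are named `{part0d,part1d,alphapow}_{smoothness,entropy,
spread}_{global,epoch_mean,sd,mafd,sampen}` in fixed family-major order.

## Prediction

Per leave-one-out fold: predictors are standardized on the training
subjects; an elastic net (mixing 0.5) is solved along 25 geometrically
spaced penalties spanning three decades below the smallest all-zeroing
penalty, with a deterministic contiguous 5-fold internal CV choosing the
minimum-MSE penalty; features with nonzero coefficients feed a single-
hidden-layer network (10 tanh units, linear output, MSE loss) trained by
L-BFGS to tolerance 1e-6 or 500 iterations from a seeded initialization.
An empty selection falls back to the training-mean score, bit-exactly.
The network consumes the training-standardized features directly (the open
question of whether standardization is reapplied is resolved as: it is not).
The path solver drives scikit-learn's compiled coordinate-descent kernel
with warm starts; it agrees with `sklearn.linear_model.enet_path` to 1e-10
(tested) and exists because the permutation null re-runs the full LOOCV
hundreds to thousands of times.

Network capacity control deserves a note.  At these sample sizes
(≈ 45 subjects, up to ≈ 45 selected inputs) a 10-unit network can
interpolate its training fold.  Validation-split early stopping — the
classic default of the toolchain that inspired this design — was evaluated
and rejected: a 7–9-subject validation split is too noisy to stop on and
reliably underfits.  Instead the network starts from small-norm weights
(Gaussian, SD 0.3/√fan-in, the magnitude regime of Nguyen–Widrow
initialization); gradient training from a small start converges to a
low-norm, smooth interpolant, which on planted-signal benchmarks tracks the
linear post-selection predictor closely.  The contract is architecture +
seed; the optimizer is any deterministic full-batch gradient method.

Group-mean imputation runs before LOOCV, exactly mirroring the reference
procedure.  This leaks the held-out subject's group mean into training — a
known caveat replicated deliberately for fidelity and confined to columns
with missing entries.

Permutation inference shuffles ability scores only, within the analysed
group, re-running the full pipeline per draw.  With h_N of N null
correlations ≥ the observed one, p_N = (h_N + 1)/(N + 1),
SE_N = √(p_N(1−p_N)/N), Wald 95% CI p_N ± 1.96·SE_N, and convergence is a
final margin below 0.005.  Two properties of the null are worth knowing:
under LOOCV the null r distribution centres slightly *below* zero (the
training-mean fallback anticorrelates with the held-out score — an
all-fallback draw gives exactly r = −1), and constant prediction vectors
have r defined as 0.  Neither affects exchangeability, so permutation p
remains uniform under the null (tested by KS over 50 null cohorts).

## Thermodynamic modelling

The state variable is sample-wise alpha-power smoothness: x(t) is the
vector of squared analytic-signal amplitudes, L the normalized Laplacian of
the epoch containing t, S(t) = x(t)ᵀLx(t), concatenated across the 60
epochs and globally z-scored.  Increments spanning an epoch boundary are
retained (the series is a single concatenated record); a flag drops them
for sensitivity analysis.  Subjects with fewer than 1000 finite samples are
excluded with a diagnostic.

Drift and diffusion are conditional Kramers–Moyal averages over 20 linear
bins spanning the central 95% (2.5th–97.5th percentiles) of the state
distribution, conditioning on the increment's *starting* point (the
restriction is not applied to endpoints; the source procedure does not say,
and the start-point convention is standard).  Bins need more than 10
samples to count; diffusion uses the conditional sample variance (n−1).
A cubic `D¹(z) = az³ + bz² + cz + d` is least-squares fitted (unweighted,
bin midpoints as abscissae) through the ≥ 4 valid bins and integrates to
`U(z) = −a/4 z⁴ − b/3 z³ − c/2 z² − dz`, with U(0) = 0.  Rigidity is
κ = −c/2, the quadratic coefficient of U at the standardized operating
point; central noise is the unweighted mean of D² over valid bins with
centres in [−1, 1] (count-weighted averaging available by flag).

Finite-sampling behaviour: with Euler–Maruyama data the binwise drift
estimator is unbiased for the generator's own map, and the leading biases
(within-bin regression dilution ~h²/12, finite-Δt diffusion bias ~θΔt) are
below 2% at the default Δt = 0.01 s.  On Ornstein–Uhlenbeck paths
(θ ∈ {0.5, 1, 2, 4}, D = 0.5, 10⁵ samples) the median recovered κ and noise
over 20 seeds land within a few percent of θ/2 and D; single-seed scatter
is ±15%, dominated by the cubic fit's sensitivity to sparse edge bins.

## Group-level inference

Metric–ability associations use IRLS with Tukey bisquare weights (tuning
constant 4.685, MAD scale); the slope p-value is the large-sample normal
approximation of the IRLS coefficient covariance, matching common
robust-fit reporting.  Exact fits (zero residual scale, where bisquare
weights are undefined) fall back to the OLS line with unit weights.  Group
comparisons use a two-sample pooled-variance t statistic per feature — the
base statistic is the package's choice — with max-statistic permutation
FWE control and the +1 tail correction; with one feature this reduces to an
ordinary permutation test.

## Synthetic data: what it emulates, and what it does not

*EEG*: narrowband sources are bandpass-filtered Gaussian noise (naturally
drifting amplitude/phase) mixed through nonnegative posterior-peaked
topographies over spectrally shaped 1/f noise; generated directly at
100 Hz, 32 channels, 195 s.  SNR (default 4) and source count (default 2)
are free parameters — the source recordings' true values are unknown — and
no head-model forward physics, artifacts, or acquisition chain are
simulated.  Passing tests therefore show the pipeline recovers planted
structure under its own generative assumptions, not that it is robust to
real-world artifact regimes.

*Langevin*: Euler–Maruyama with dz = (az³+bz²+cz+d)dt + √(2D)dW, default
dt = 0.01 s, ≥ 1000 samples; ground truth κ = −c/2, noise = D.

*Cohorts*: 45 subjects per group, features from a chosen covariance
(identity, equicorrelation, or full matrix), ability = 100 + Σwⱼfⱼ + ε with
5 coupled features of weight 5 and ε of SD 2.5 by default — an IQ-like
scale with high signal-to-noise, as the recovery benchmarks require.
Optional missingness exercises imputation.

Test problem sizes (null-calibration cohorts of 10 subjects, 50 repetitions
at 200 permutations; 20 seeds per OU condition) are the package's chosen
benchmark scale; generator defaults remain at the study conditions above.

## Known limitations

- ciPLV discards zero-lag coupling by construction; genuinely instantaneous
  physiological coupling is invisible to the graphs.
- The epoch-level Laplacian treats each 3 s graph as static; within-epoch
  nonstationarity is only partially absorbed by the 10-window averaging.
- Min-MSE elastic-net selection retains many weakly weighted features by
  design; selection *frequency* across folds, not the selected-set size, is
  the interpretable importance measure.
- The Langevin inversion assumes a stationary one-dimensional diffusion
  with state-independent noise over the central range; κ < 0 (anti-
  confining centre, as in bistable dynamics) is meaningful but the quartic
  potential is only as good as the cubic drift fit within the central 95%.
- Group-mean imputation before cross-validation mildly leaks information,
  replicated knowingly for procedural fidelity.
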