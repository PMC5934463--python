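# Methods

## Scope and data model

`vforg` quantifies spatio-temporal organization in a multichannel
recording: a channels × samples real matrix with a sampling rate, unique
integer channel ids and an ordered, non-overlapping epoch schedule. The
reference use case is epicardial VF mapping (≈200–256 electrodes at 1 kHz,
3.5 min records split into seven 30 s epochs: control perfusion, five
ischaemia stages, reflow; `DEFAULT_VF_EPOCHS`), but nothing in the code
assumes those numbers.

## Preprocessing

**Piecewise linear detrending.** An independent least-squares line is
removed from each non-overlapping segment of every channel
(`scipy.signal.detrend` with breakpoints). The default segment length is
1000 samples, matching the analysis-window length; this is a package
choice, as is dropping a trailing one-sample segment (a line through one
point is ill-posed). Detrending is idempotent and leaves each segment with
≈ zero mean, which the correlation normalization relies on.

**Channel screening.** The dominant frequency (DF) of a channel is the
argmax of its Welch power spectral density (Hann taper, 3000-sample
segments, 1500 overlap, mean averaging) searched over [0.5 Hz, fs/2); the
0.5 Hz floor keeps the near-DC drift residue from masquerading as a DF
while still letting out-of-band DFs be detected and reported. A channel is
kept iff its DF lies in the 2–20 Hz fibrillation band (inclusive) and its
RMS is at least 5 % of the median channel RMS. The RMS floor automates
what is otherwise a visual near-zero-amplitude screen; 5 % was fixed once
as a conservative surrogate and excluded channels carry exactly one
reason (`low_amplitude` takes precedence, since a near-zero channel has no
trustworthy spectrum).

## Lagged correlation and the organization measure

`r_ij(τ)` for τ ≥ 0 is the inner product over the overlapping `N−τ`
samples divided by the product of **full-length** norms — implemented
literally, accepting that |r| slightly understates alignment at large
lags — and `r_ij(−τ) = r_ji(τ)`, which makes the correlation matrix
exactly symmetric. `R_ij` keeps the signed value at the lag of maximum
|r|; ties break toward the smallest |τ| and, among ±τ, toward the negative
lag. The tie rule is applied on the i<j orientation and mirrored: applying
it independently to both orientations could disagree in sign on exact
|r| ties, and exact symmetry is the stronger guarantee. Zero-variance
channels get r ≡ 0 (flagged), never NaN. The implementation evaluates one
matrix product per non-negative lag and is tested against a literal
double-loop evaluation at 1e−12.

The lag half-width is `d = ceil(round(max_cycle_ms·fs/1000)/2)`: the cycle
length in samples, halved, rounding up so an odd count never shortens the
window (232 ms at 1 kHz → d = 116). The maximum average cycle length is an
*input*: estimating it (e.g. as the inverse mean DF, `lag.from_df` in the
pipeline) involves choices — which epochs, whether to pad by a confidence
margin — that belong to the study, not the library.

`c = ‖R‖_F / n` is bounded by 1/√n (unit diagonal only) and 1.

## Functional networks

Thresholding zeroes entries of |R| below θ; adjacency is the nonzero
pattern of the thresholded weights. Two consequences are deliberate:
θ = 0 gives the complete graph on channels with any nonzero correlation,
and exactly-zero correlations never form edges (so the identity matrix has
no edges at any θ and `W_ij > 0 ⇔ A_ij = 1` holds). Weights are |R|:
geometric-mean triangle intensities need non-negative weights, and the
threshold is defined on magnitude; the signed matrix stays available
upstream.

The weighted clustering coefficient uses the triangle-intensity form with
weights normalized by the largest weight of the thresholded network
(per window, per threshold; an all-zero network has C = 0). The intensity
sum runs over **unordered** neighbour pairs so that the factor 2 in
`C_i = 2l_i/(k_i(k_i−1))` reproduces the Brain Connectivity Toolbox /
Onnela coefficient; for binary weights it reduces to the classic
unweighted coefficient. Computed in matrix form
(`2l = diag((Ŵ^{∘1/3})³)`), cross-checked in tests against triple-loop
enumeration and networkx.

AUC summaries integrate measure(θ) by the trapezoidal rule on the printed
0:0.05:1 grid with no interpolation at drop points; a step falling between
grid nodes therefore contributes half a grid cell. Density and edge count
are non-increasing in θ by construction. The average clustering
coefficient is **not**: pruning a weak spoke at a node divides the
k(k−1) normalizer quadratically while strong triangles survive, so C can
jump upward at the threshold where weak inter-cluster edges vanish. This
is a property of the coefficient itself, not an implementation artifact;
the test suite documents it.

Hubs are nodes with strength strictly above the mean — a uniform network
has none.

## Hierarchical clustering

`D = 1 − |R|` (clipped to [0,1], zero diagonal) feeds average-linkage
(UPGMA) agglomeration, delegated to `scipy.cluster.hierarchy.linkage` and
verified against a quadratic-time agglomerator that recomputes every
inter-cluster distance from raw member pairs. Cuts apply all merges of
height ≤ h (merges at exactly h included); labels are renumbered by first
channel occurrence for determinism. The normalized cluster count at a cut
counts **singletons as clusters** — a channel correlated with nothing is a
(degenerate) region, and counting it keeps the index's range and its
anti-correlation with the clustering-coefficient AUC clean; the
`cluster_map` export flags singletons separately so displays can mark
channels that "do not form a cluster". The cut-off grid for the AUC
mirrors the threshold grid.

## Sliding windows and trends

Windows start at multiples of the hop; a truncated final window is kept
iff it is at least one hop long. This convention reproduces 420 segments
for a 210 s record at 1 kHz with 1000/500 windowing (the textbook
`floor((N−L)/H)+1` gives 419) and is property-tested against direct
enumeration. Windows shorter than `2d+2` samples cannot host the lag
search and are skipped with a warning, not zero-padded.

The epoch trend is a continuous linear spline
`y = β₀ + β₁t + Σ_k γ_k (t−t_k)₊` with knots at epoch onsets, fit by
ordinary least squares; rank-deficient designs (segments with too few
windows) raise rather than silently regularize. Slope changes are
reported in measure-units per second; no percentage rescaling is applied,
since the natural units are unambiguous. Group summaries are arithmetic
means and sample SDs (ddof = 1) across recordings; a single recording
reports SD 0 with an explicit flag.

## Comparison with external complexity series

Phase-singularity counts (or any per-time complexity series) are an
*input* CSV — computing them requires phase-map estimation that is out of
scope. R² is from a simple linear regression (equal to squared Pearson r);
alignment granularity is configurable, defaulting to per-second averaging
of the window series because external count series are typically
per-second. The per-epoch PCA treats recordings as observations and time
points as variables (an epoch matrix of 30 time points × 10 recordings
projects to 2 × 10 component scores), column-centred, with each
component's sign fixed by making its largest-magnitude loading positive.

## Synthetic generator

The generator emulates the salient statistics of epicardial VF records:
per-cluster oscillations with DFs in the 2–20 Hz band, spatially
contiguous clusters (k-means on a quasi-uniform unit-disc layout —
sunflower spiral plus seeded jitter), slow drift (0.2 Hz sinusoid plus
linear ramp, emulating respiration), log-normal per-channel amplitudes
(SD 0.1) and additive Gaussian noise. Phase jitter is a mean-reverting
(damped) random walk with a 0.5 s time constant and unit stationary
variance, scaled by √(1−coupling) at the cluster level (between-coupling)
and the channel level (within-coupling). The damping matters: a pure
random walk's phase dispersion grows without bound, so the same coupling
value would yield different correlations at different record lengths;
with damping, coupling maps to a stationary correlation
(≈ exp(−(1−w)·J²) within clusters, J = 1 rad). `within = 1` with zero
noise/drift makes within-cluster channels exact scalar multiples
(correlation 1). All randomness flows from the single `seed` argument; no
global RNG state is touched.

Default study conditions used by the tests and the acceptance script:
two clusters at 5 and 9 Hz, within-coupling 0.95, between-coupling 0,
noise SD 0.1, 30 s at 1 kHz, 40 channels for recovery runs (10 seeds);
ordering comparisons use 20 channels × 10 s, and invariant sweeps use
10–16 channels × 5 s to keep the suite fast. These sizes are scaled-down
analogues of a 256-electrode, 3.5 min recording; the arithmetic being
checked (window counts, lag windows, closed forms, oracle equivalence) is
size-independent.

What the generator does **not** emulate: action-potential morphology,
conduction and restitution dynamics, wavebreak, electrode contact
artifacts, non-stationary DF drift within an epoch, or 3-D geometry.
Passing recovery tests therefore show that the pipeline correctly inverts
its own generative family — coupled noisy oscillators — not that it
resolves arbitrary clinical VF structure.

## Numerical choices and degenerate inputs

- Correlation entries are clipped to [−1, 1] after assembly to absorb
  floating rounding; matrices are validated symmetric with unit diagonal.
- Oracle-equivalence tests run at 1e−12 absolute tolerance; trend
  recovery on noiseless splines at 1e−8.
- Empty networks: density 0, strengths 0, C = 0, no hubs. Empty keep-sets
  from channel screening are legal and logged; the pipeline aborts if
  fewer than two channels survive.
- Dendrogram merge tie-breaks follow scipy's ordering; on
  continuous-valued dissimilarities ties have measure zero, and the
  partition-level results are tie-invariant.

## Known limitations

- The correlation measure is linear; phase-coherent but
  amplitude-uncorrelated coupling is underestimated.
- Peak-|r| lag selection discards the delay structure by design (delays
  are noise-sensitive); no directed or frequency-domain coupling measures
  are provided.
- The AUC trapezoid on a 0.05 grid quantizes step positions to half a
  cell; finer grids are configurable where that matters.
- Windowed measures at 1000 samples resolve ≥ 2 Hz rhythms; slower
  content aliases into the trend rather than the window series.
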