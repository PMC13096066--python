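# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## NDTE: model and estimator

The directed flow from source X to target Y treats the next sample of Y as
the prediction target and asks how much of the predictable part of that
sample is contributed by X's past beyond Y's own past:

- numerator: I(Y_t ; X_past | Y_past)
- denominator: I(Y_t ; X_past, Y_past)
- F = numerator / denominator, clipped to [0, 1]; defined as 0 when the
  denominator falls below 1e-12 (a white-noise target carries no
  predictable information, so no flow is attributable).

Both pasts are embedded over T lags; the future horizon is a single sample.
All informations are differences of Gaussian differential entropies
H = n/2·ln 2πe + ½·ln det Σ, with Σ the biased (1/n) within-epoch sample
covariance of the stacked vector [Y_t, Y_past, X_past]. A relative jitter of
1e-10 × trace is added to each submatrix diagonal before the `slogdet`
factorization; this keeps 400-sample windows numerically safe and bounds the
flow of a noiseless pure-delay pair just below 1. Because the estimator uses
covariances only, it is exact for linear-Gaussian dynamics and is an
approximation (of the Gaussian-copula kind) otherwise. F is invariant to
separate affine rescaling of the two series up to the jitter floor (verified
numerically to ~1e-5).

Two closed-form oracles pin the estimator down: for a bivariate Gaussian
with ρ = 0.8 the mutual information estimate matches −½ln(1−ρ²) ≈ 0.5108
nats within 2% at n = 50 000, and for the VAR(1) system
y_t = 0.5 x_{t−1} + 0.5 y_{t−1} + ε the flow matches
ln(5/4)/ln(5/3) ≈ 0.4368 within 0.05 at n = 20 000 (stationary variance of y
is 5/3; residual variance 5/4 given y's past, 1 given both pasts).

### Model order

T is the first local minimum of the per-trace sample autocorrelation
function, operationalized as the first lag τ (after an initial descent)
with ACF(τ) < ACF(τ+1); if the ACF decays monotonically to `max_lag`, the
1/e crossing is used instead. The returned order is the rounded mean over
regions and trials (and, when epochs are pooled before the call, over
conditions and participants). Note that the biased sample ACF of a finite
pure cosine is tapered by (1 − k/n), which shifts the minimum slightly below
the half period for short records; this is a property of the estimator, not
a bug.

## Surrogate inference

The null for each ordered pair rotates the **source** series by a uniform
offset in [L/4, 3L/4] (the target's future is preserved exactly; offsets
near 0 or L would produce near-identity surrogates). Rotation preserves the
amplitude spectrum, so only the cross-dependence is destroyed. Per-trial
p-values use the add-one rule p = (1 + #{surrogate ≥ observed})/(S + 1) and
can therefore never be 0; aggregation is one-sided Stouffer
(z_i = Φ⁻¹(1−p_i), combined p = 1 − Φ(Σz/√n)), first across trials within a
participant, then across participants. p-values of exactly 0 or 1 are
clipped to [1e-15, 1−1e-15] with a warning before the probit transform. The
Benjamini–Hochberg mask is computed once on the group p matrix over all
R(R−1) ordered pairs and shared by all participants. Standardization
(Z = (F − surrogate mean)/surrogate SD) is applied per trial and then
averaged — standardize-then-average rather than average-then-standardize;
pairs with zero surrogate SD in a trial are dropped from that trial's
average with a warning. Under independent white-noise pairs the per-trial
p-values are uniform (KS distance < 0.1 over 500 pair-trials) and the
masked-pair fraction under a full null stays below the FDR level; both are
recomputed by the acceptance script.

## FRIC hub detection

Total inflow of region i is the row sum of the group flow matrix (orientation
M[i, j] = flow j → i) and total outflow the column sum; the inflow/outflow
reading of rows versus columns is isolated in `total_inflow`/`total_outflow`
so the convention can be flipped in one place if a different matrix
orientation is ever adopted. The FRIC value of a club simplifies to
Σ inflow(club) − Σ outflow(club) + Σ within-club flow. Clubs are grown along
the inflow ranking (ties broken by label order) starting at size 2 — a
singleton has no surrogate comparison under the fixed-(k−1) scheme — and
growth stops at the first size whose Monte-Carlo p (add-one, seeded) reaches
the alpha level; if size 2 already fails, the top-inflow singleton is
returned flagged non-significant.

**Known limitation (small parcellations).** With the matrix fixed, the
Monte-Carlo only resamples the identity of the random replacement member, so
at size k the test effectively asks whether the k-th ranked region beats
every one of the n−k candidate replacements. With few regions this is
granular and selection-biased in both directions: a planted club whose
members are exchangeable can fail at intermediate sizes (the next planted
member is an equally good replacement), and the top-ranked non-member can
spuriously win at the size just past the true club because inflow rank
correlates strongly (≈0.8) with the club score. Consequently, exact recovery
of a 3-member exchangeable planted club in a 10-region matrix succeeds in
only ≈25–30% of seeds, and on i.i.d. null matrices the first tested size is
declared significant in ≈40% of cases. The procedure is reliable when club
scores are well separated from the candidate pool (the regime of real
group-level flow matrices with ~60 regions); the graded-club fixtures in the
test suite demonstrate deterministic recovery in that regime. We deliberately
kept the published algorithm rather than substituting a differently
calibrated test.

## Epoch processing

Amplitude rejection removes an epoch iff any single region's within-epoch
peak-to-peak (max − min) reaches the threshold (default 100 signal units);
the per-region reading is configurable in principle by pre-combining
channels. Epoch-count equalization removes a seeded uniform subset of the
larger condition, preserving order. Difference waveforms pair the two
conditions by a seeded random bijection per participant, with the sign
convention 50% − 80% recorded in metadata. Analysis windows are half-open
[start, end) on the sample grid, so a 400 ms window at 1 kHz is exactly 400
samples. Filters are zero-phase FIR (firwin + filtfilt); the default length
is 3 periods of the lowest band edge, clamped (with a warning) so
forward–backward filtering remains valid for short epochs — for a 2.5 Hz
high-pass this implies epochs of at least ~3.6 s at 1 kHz for the full-length
filter, which is why filtering is applied to whole epochs before window
extraction.

## ERP cluster permutation

Elementwise paired t-maps over channels × time; suprathreshold samples of
one sign are clustered through spatial adjacency (same time, neighbouring
channels) and temporal contiguity (same channel, consecutive samples);
channels with fewer than `min_neighbors` (default 3) neighbours in the
layout are excluded from cluster formation. The cluster-forming threshold is
the two-sided paired-t quantile at 0.05 (configurable); the null statistic
is the maximum absolute cluster mass under random per-participant sign
flips, which controls the family-wise error — measured 4–5% over 500 null
datasets at reduced size. Spatial adjacency is built from channel coordinates
with a distance threshold chosen so the median neighbour count reaches 4.

## Entrainment measures

Welch band power uses Hann windows with 50% overlap and a zero-padded FFT so
the bin spacing equals the configured 0.12 Hz; a 1.2 s epoch cannot natively
resolve 0.12 Hz, so the fine spacing is spectral interpolation, not added
resolution — segment length equals the available window. Band power is
averaged over in-band bins and trials and normalized by the same measure on
a baseline interval. ITPC convolves complex Morlet wavelets (7 cycles,
configurable) at 20 log-spaced frequencies; the first and last 3 wavelet
standard deviations are set to NaN as edge artifacts. PLV uses FFT-based
Hilbert phases after mean removal; the per-epoch whole-head value is the
mean over all unordered channel pairs, with a 0.85 Hz high-pass recommended
for 1.2 s epochs. The scalar condition contrast is a two-sided paired
sign-flip permutation test on the mean difference; when the requested
permutation count covers the full sign-flip group (n ≤ 20,
n_perm ≥ 2ⁿ − 1) the test enumerates all 2ⁿ patterns exactly, otherwise it
uses random flips with the add-one convention.

## Synthetic generator: what it emulates and what it does not

The generator reproduces the design's statistics — cue conditions with 80%
vs 50% early-target contingencies, 1200/2400 ms cue–target intervals
measured cue offset to target onset (the window arithmetic
100 ms cue + 1200 ms interval + 100 ms = 1400 ms post-cue start of the
post-target window is only consistent with that reading), 200–1000 ms ITIs,
3 blocks × 50 trials per condition — and region dynamics as stationary VAR
processes with Gaussian i.i.d. innovations, condition effects implemented as
coupling-coefficient changes confined to a time window, a 100-sample burn-in
before each epoch, and seeds making every output byte-identical under
identical parameters. Non-stationary coefficient sets are rejected with the
companion-matrix spectral radius named in the error.

It does **not** emulate: 1/f background spectra, electrode-space volume
conduction or mixing, evoked (phase-locked additive) components, artifacts,
or non-Gaussian innovations. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the linear-Gaussian
model class that the Gaussian-entropy NDTE assumes — not robustness to the
full complexity of recorded EEG.

Reaction times are participant offset + condition mean + trial noise,
truncated at 50 ms (truncation mass is negligible at the default
330/360 ± 40 ms). Because the participant offset cancels in the paired
condition difference, the paired effect size grows as √(n/2) with trials per
condition; the model has no participant × condition random slope, so
matching a particular published effect size requires choosing the trial
count accordingly. Default means put the non-predictive condition 30 ms
slower, a realistic cueing effect.

Planted rich-club matrices set club rows (within- and into-club flow) to
`in_weight`, club-to-outside entries to `out_weight`, everything else to
`background`, plus seeded uniform tie-breaking jitter on
(0, 0.01·background) and a zero diagonal.

## Behaviour link

ΔRT = mean RT(50%) − mean RT(80%) per participant after excluding responses
slower than 1000 ms. Connection strength per participant is the
trial-averaged standardized Z on the group mask — the only per-subject
summary the pipeline defines. The strongest k masked connections (default
20; ≈0.5% of 62×61 ordered pairs) are selected by group Z with a
deterministic (target, source) tie-break, correlated with ΔRT by Pearson's
r, and BH-corrected across the k connections within each analysis window.

## Problem sizes

Default desk-scale runs use 4–8 regions, 3–10 participants, 8–20 trials per
condition, 20–50 surrogates, 200–1000 Monte-Carlo draws and 100–200
permutations; study-scale values (62 regions, 100 surrogates, 1000
permutations, 100 000 Monte-Carlo draws) are plain configuration fields of
`RunConfig`. The calibration experiments in the acceptance script use 500
null datasets for the cluster test, 500 pair-trials for surrogate
uniformity and 20 datasets for the FDR mask.
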