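# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests show.

## Assembly detection

The detector assumes stationary firing over the analysis interval and
models co-activation at a single timescale: spike counts in 25-ms bins
(`bin_width`, configurable), z-scored per neuron so high-rate cells do not
dominate. Significance is a bulk-spectrum argument: for independent
unit-variance rows, correlation-matrix eigenvalues stay below the
Marcenko–Pastur edge `(1 + sqrt(N/B))²`; every eigenvalue above it is
counted as one co-activation pattern. The bound requires more bins than
neurons and is asymptotic — at `N/B` near 1 it is meaningless, so the
precondition is enforced, not warned. Patterns are extracted by fastICA
(deflation, `tol 1e-6`, up to 1000 iterations) on the data projected into
the top-`n` principal subspace; on non-convergence the fit restarts with
fresh derived seeds up to 3 times before raising. Components are
back-projected to neuron space, unit-normalized, and sign-fixed so the
largest-magnitude weight is positive (ICA is sign-blind). Membership uses
the mean + 2 SD weight rule; note this is a *relative* rule — with very
few recorded neurons the threshold can exceed every member weight, so
member sets are meaningful for ensembles of a few dozen cells and up.

Activation strength is tracked on a 1-ms grid (`step`, configurable; the
20-kHz acquisition grid would be ~20× slower for no analytical gain) after
convolving each train with a Gaussian kernel of SD `bin_width/sqrt(12)` ≈
7.2 ms — the SD that matches the variance of the 25-ms boxcar — and
z-scoring over the interval. `A(t) = z(t)ᵀPz(t)` with zeroed diagonal is
evaluated as `(w·z)² − Σᵢwᵢ²zᵢ²`, algebraically identical to the full
quadratic form (the unit suite checks equality to 1e-9 against the brute
force double sum). Neurons whose smoothed trace has zero variance are
removed from the pattern and the weights renormalized (logged). Peaks
above `R_THRES = 5` at local maxima, minimum separation one bin width, are
activations. One behavior to be aware of: a chance near-coincidence of
just two members is itself a strong co-activation (two isolated spikes
reach z ≈ 6–8 each), so detected activation rates sit above the embedded
event rate by roughly `pairs × rate² × 25 ms`; this is a property of the
statistic, not an artifact of this implementation.

Cross-session comparison intersects neuron ids (zero weight for neurons
missing from a session), renormalizes, takes `|w_a·w_b|`, and matches
one-to-one by Hungarian assignment on the similarity matrix. No display
threshold is applied to similarity matrices.

## Cell-type classification

Waveform features assume a biphasic extracellular spike: a dominant trough
flanked by positive peaks. "Second zero intercept" is read as the second
crossing moving away from the trough — the first crossing bounds the
trough lobe, the second closes the adjacent peak; crossings are located by
linear interpolation and a unit lacking two crossings on either side is
flagged unclassifiable rather than guessed. Features are
amplitude-scale-free by construction (property-tested).

k-means runs with 20 seeded restarts on z-scaled features. The
cluster→name rule (the source of the labels, since clustering is
unsupervised): FSI = briefest summed peak durations; of the remaining two,
MSN = lower mean firing rate, TAN the other. Rates enter only through this
rule. Confirmation clusterings: DBSCAN with `(min_samples, eps)` scanned
over a density-smoothing range × k-distance quantiles and the partition
chosen by silhouette (an internal criterion — no reference labels are
consulted), noise points assigned to their nearest clustered neighbor so
partitions are comparable; and Ward-linkage hierarchical clustering (we
found average linkage produces unbalanced cuts on touching Gaussian-like
clusters, dropping cross-algorithm agreement to ~0.55, whereas Ward is the
standard choice for compact z-scaled clusters). Pairwise adjusted Rand
between the three algorithms is reported as the confirmation statistic.

Opto-tagging bins peri-pulse spikes at 0.2 ms over [−50, +8] ms. The
stated rule — some post-pulse bin exceeding the baseline mean by k = 3
baseline SDs — is kept, but because per-bin counts are small its Gaussian
reading has a heavy-tailed false-positive rate (~25–40% across a 40-bin
window); a tagged bin must therefore also clear the exact Poisson upper
tail of the baseline mean at the matching one-sided level `Φ(−k)`. The two
criteria coincide as counts grow; with the guard, the measured 100-seed
type-I rate on pulse-independent units is 0. With a silent baseline the SD
is floored at the binomial SD of half a spike over all pulses.

## Spike timing

Theta cycles come either from an analytic phase channel (boundaries at
phase-zero crossings — exact for generated sessions) or from an LFP: 3rd
order Butterworth band-pass 4–12 Hz applied forward-backward, analytic
phase via the Hilbert transform, boundaries where unwrapped phase crosses
multiples of 2π (linear interpolation). The series is odd-reflection
padded by two slow-band cycles so filter/Hilbert edge transients stay out
of the analyzed span; residual boundary error on a pure tone is ~10 µs,
well below the sample interval. Cycles outside 83–250 ms are flagged
invalid and skipped by the surrogate and cycle-binning machinery.

Correlograms pool target-spike lags over reference spikes (1-ms bins,
±200 ms default) and normalize by the reference count. Shift surrogates
draw, independently per spike and per surrogate, a uniformly random valid
cycle and place the spike at the time whose phase equals its original
phase (phase→time by the cycle's linear map); spike count and phase
multiset are preserved exactly. Per-bin 0.5%/99.5% quantile bands over
1000 surrogates are attached for display. For the *claim* that a
correlogram exceeds the null somewhere within a lag window, the per-bin
band is not the right test — its family-wise error grows with the window
(~4–6% over the five 3.2–8 ms bins). `exceeds_band` therefore compares the
maximum over the window bins against the same quantile of the
per-surrogate maxima, which has exact family-wise level by construction;
measured false-positive rate on theta-comodulated uncoupled pairs is 1.5%
(200 pairs), with 100% detection of 4-ms couplings at efficacy 0.2.

Rate scores are `(r_ON − r_OFF)/(r_ON + r_OFF)` (NaN when both rates are
zero; antisymmetric under exchange); score densities use a Gaussian KDE
with Silverman bandwidth clipped to [0.02, 0.2] on the score scale. Theta
modulation is the Rayleigh vector length of spike phases. PSP kinetics
take events as deflections exceeding baseline mean + 2 baseline SDs that
*stay* above threshold for ≥ 1 ms (single noise samples cross 2 SDs by
chance), amplitude relative to baseline mean, rise time between the 20%
and 80% amplitude crossings by linear interpolation, and paired-pulse
ratio as second/first amplitude.

## Ensemble prediction

The prediction equation is linear in parameters with additive error, so
the default family is Gaussian with identity link solved by least squares;
a log-link Poisson family is available. Predictors are the raw per-PYR
cycle counts. (The model equation could also be read as using principal
components of PYR activity; compressing predictors by PCA before the fit
is possible by passing the projected matrix, but raw counts are the
default because the coefficients then stay interpretable per cell.)
Rank-deficient designs fall back to ridge with penalty 1e-6 (logged); no
regularization otherwise. Accuracy is the Pearson correlation between
observed and predicted counts — invariant to affine rescaling of the
predictions, undefined (NaN, flagged) when either side has zero variance.
Cycles overlapping condition boundaries can be restricted by masking on
the cycle start times, as the pipeline does for its train/test split.

## Behavior

Preference scores exclude bridge and out-of-apparatus samples from the
denominator — the two-enclosure formula read literally. Occupancy maps
weight each frame by its interval, so the map total equals the tracked
duration to within one frame. Missing tracking frames are linearly
interpolated up to 0.5-s gaps and dropped beyond that.

## The synthetic generator

The generator emulates the statistical structure the analyses assume:
place- and theta-modulated inhomogeneous-Poisson PYRs (thinning sampler);
assembly events at configured rates, each member emitting an extra spike
uniformly jittered within one 25-ms window with the configured
participation probability (the least-informative placement, since
assemblies are defined only by bin-scale co-activation); PYR→FSI coupling
as an extra FSI spike per presynaptic spike with the configured efficacy
at the configured latency (0.3-ms jitter SD); FSI→MSN feedforward
inhibition as a multiplicative rate dip `exp(−strength·Σ e^{−Δt/τ})`,
τ = 10 ms default; light epochs as per-neuron thinning by the suppression
factor (factor 0 silences exactly). Theta phase is an analytic
constant-frequency ramp (default 8 Hz, optional per-cycle jitter) exported
as ground truth, so cycle detection can be bypassed or tested against
truth. Position is a reflected Ornstein–Uhlenbeck walk over two 46-cm
enclosures at the 25-Hz camera rate, with exponential visit durations
tuned to the requested dwell preference. Waveforms are biphasic
half-cosine templates whose (first-peak, second-peak, symmetry) centroids
are class-specific — FSI narrowest — with between-neuron jitter scaled so
the closest centroids sit `separation` feature-SDs apart.

Defaults, chosen once as exploration-typical values: PYR 1.2 Hz with theta
depth 0.4 (spike-phase Rayleigh length ≈ 0.2) and place fields of depth
0.5, σ = 10 cm; MSN 1.5 Hz (lowest of the striatal classes), FSI 12 Hz,
TAN 5 Hz; MSNs in theta phase opposition to PYRs/FSIs. Reproducibility is
by counter-based substreams: one per neuron, assembly, and the trajectory,
derived from the session seed, so adding neurons never perturbs existing
trains.

What the generator does *not* emulate: spike-sorting artifacts
(contamination, drift, refractory violations), bursting and spike-height
adaptation, realistic LFPs (only the phase channel), behavioral state
changes, and nonstationarity across a session. Passing tests therefore
show the analysis chain recovers known structure from data matching its
assumptions — they do not certify performance on sorted real recordings,
where rate nonstationarity in particular can inflate the pattern count.

## Problem sizes in the tests

The validation suite uses desk-scale benchmarks chosen to give tight
statistical checks in minutes on one CPU: null calibration at 30 neurons ×
20,000 bins × 100 seeds; recovery at 50 PYRs, five 6-member assemblies
(participation 0.8, 1 event/s) over 20 minutes × 20 seeds; 100
surrogate-test pairs at 1000 surrogates; 300-waveform banks; GLM recovery
at 10,000 cycles and wiring specificity over 50 seeds. The same quantities
are recomputed end-to-end by `scripts/acceptance.py`.

## Known limitations

- The Marcenko–Pastur census assumes independence under the null;
  slow shared modulations (strong common theta at high rates, overlapping
  place fields with slow trajectories, population nonstationarity) shift
  bulk eigenvalues toward the bound and can add spurious patterns.
- Activation-peak counts include genuine chance co-activations of member
  pairs (see above); at 1 Hz embedded events and ~1 Hz member baselines
  these add ~20–30% extra peaks.
- The membership rule (mean + 2 SD) is relative to the recorded
  population and degenerates for very small ensembles.
- Opto-tagging assumes pulse-locked, short-latency responses; slow or
  adapting responses dilute across bins and are missed.
- The GLM is linear in counts with no spike-history or coupling filters;
  it measures transferable linear structure, not causality.
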