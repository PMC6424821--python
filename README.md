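# ca1nac

Ensemble-electrophysiology analysis of the hippocampus→nucleus-accumbens
circuit: detection and cross-session tracking of neuronal co-activation
assemblies, waveform-based striatal cell-type classification,
theta-oscillation-controlled spike-timing analysis, ensemble-to-ensemble
GLM prediction, and behavioral place-preference scoring — together with a
ground-truthed synthetic-session generator that exercises every stage.

The package is for systems neuroscientists working with sorted spike
trains from dual-site recordings (dorsal CA1 pyramidal cells, PYRs, and
nucleus-accumbens medium spiny neurons, MSNs, fast-spiking interneurons,
FSIs, and tonically active neurons, TANs), and for anyone who needs a
tested, reusable implementation of these analyses with a simulator that
knows the right answer.

## Methods at the core

**Assembly detection.** Spikes are counted in 25-ms bins and z-scored per
neuron, giving a matrix `Z` (neurons × bins). The number of significant
co-activation patterns is the number of eigenvalues of the neuron
correlation matrix above the Marcenko–Pastur bound

    lambda_max = (1 + sqrt(N/B))**2,       N neurons, B bins,

the analytic upper edge for independent unit-variance data. Fast ICA on
the data projected into the significant principal subspace yields one
unit-norm weight vector `w` per assembly; members are neurons whose weight
exceeds the vector mean by two SDs. The activation strength at time *t* is
the quadratic form

    A(t) = z(t)^T P z(t),       P = w w^T with diag(P) = 0,

of the Gaussian-smoothed, z-scored population rate — the zeroed diagonal
means single neurons cannot contribute, only co-activations. Activations
are peaks of `A(t)` above `R_THRES = 5`; patterns are compared across
sessions by the similarity index `|w_a · w_b|` with Hungarian matching.

**Cell-type classification.** Each unit's mean waveform `w(t)` (trough at
t = 0) is reduced to the duration of its first and second positive peaks
(time to the second zero intercept on each side of the trough) and the
spike symmetry `amp1 / (amp1 + amp2)`; k-means (k = 3) on the scaled
features, with firing rates naming the clusters (FSI narrow and fast, MSN
slowest), cross-checked by DBSCAN and Ward hierarchical clustering.

**Spike timing under theta.** Cross-correlograms give target discharge
probability around reference (PYR) spikes. Theta-phase-preserving shift
surrogates relocate every reference spike to a random theta cycle at its
original phase — preserving the phase histogram exactly while destroying
fine timing — so a short-latency (3.2–8 ms) correlogram peak that exceeds
the band over 1000 surrogates indicates a monosynaptic interaction rather
than theta comodulation. Light-driven rate changes are scored as
`(r_ON − r_OFF)/(r_ON + r_OFF)`; theta locking as the Rayleigh vector
length; slice PSPs by 2-SD event bounds, 20–80% rise time and paired-pulse
ratio.

**Ensemble prediction.** Spike counts are binned by theta cycles and each
MSN is modeled from the simultaneously recorded PYR population,

    MSN_j(theta) = beta_0 + sum_i beta_i PYR_i(theta) + error,

fitted by least squares (Poisson/log optional). Accuracy is the Pearson
correlation between observed and predicted counts, applied across
sessions to test whether the trained wiring transfers.

**Behavior.** The conditioned/novel place-preference score is
`(t_target − t_other)/(t_target + t_other)` over the two enclosures
(bridge excluded), plus occupancy and assembly-activation maps.

## Worked example

`examples/01_assembly_detection.py` embeds three 6-neuron assemblies in a
10-minute, 40-PYR synthetic session and recovers them:

```
significant patterns (MP bound): 3  (embedded: 3)
pattern 0: members [12, 13, 14, 15, 16, 17] (truth [12, 13, 14, 15, 16, 17], similarity 0.999)
pattern 1: members [0, 1, 2, 3, 4, 5] (truth [0, 1, 2, 3, 4, 5], similarity 0.998)
pattern 2: members [6, 7, 8, 9, 10, 11] (truth [6, 7, 8, 9, 10, 11], similarity 0.999)
first pattern: 1.27 activation peaks/s in the first minute (embedded event rate 0.99/s)
```

The eigenvalue census finds exactly the three embedded patterns, the ICA
weight vectors match the planted memberships almost perfectly (similarity
is the absolute inner product, 1 = identical), and the activation-peak
rate tracks the embedded 1 event/s (the small excess is chance co-firing
of member pairs, which is a genuine co-activation). The other examples
cover classification (`02`), surrogate-controlled spike timing (`03`),
cross-session GLM prediction (`04`), behavior scoring (`05`) and the full
pipeline driver (`06`); each prints its numbers with a line on what they
mean.

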