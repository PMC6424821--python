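"""Detect embedded co-activation assemblies and track their strength.

Generates a 10-min session of 40 pyramidal cells with three embedded
assemblies, counts significant patterns against the Marcenko-Pastur bound,
extracts the weight vectors with ICA, and tracks one pattern's activation
strength through time.
"""
import numpy as np

from ca1nac import assemblies, synthetic

members = [tuple(range(6 * k, 6 * k + 6)) for k in range(3)]
cfg = synthetic.SessionConfig(
    duration=600.0,
    n_pyr=40,
    assembly_spec=[(m, 1.0, 0.8) for m in members],
    seed=42,
)
spikes, cycles, position, waveforms, truth = synthetic.generate_session(cfg)

binned = assemblies.bin_and_zscore(spikes, (0.0, cfg.duration))
n_pat = assemblies.count_significant_patterns(binned)
print(f"significant patterns (MP bound): {n_pat}  (embedded: {len(members)})")

patterns = assemblies.extract_patterns(binned, n_pat, seed=0)
truth_pats = [
    assemblies.AssemblyPattern(
        np.isin(binned.neuron_ids, sorted(m)).astype(float), binned.neuron_ids
    )
    for m in truth.assembly_memberships
]
S, matching = assemblies.match_across_sessions(patterns, truth_pats)
for i, j in matching:
    print(
        f"pattern {i}: members {sorted(patterns[i].members)} "
        f"(truth {sorted(truth.assembly_memberships[j])}, "
        f"similarity {S[i, j]:.3f})"
    )

trace = assemblies.activation_strength(patterns[0], spikes, (0.0, 60.0))
peaks = assemblies.detect_activations(trace, r_thres=5.0)
print(
    f"first pattern: {peaks.size / 60.0:.2f} activation peaks/s in the first "
    f"minute (embedded event rate "
    f"{truth.event_times[matching[0][1]].size / cfg.duration:.2f}/s)"
)
# Each peak is a moment when member neurons co-spiked within ~25 ms beyond
# what their individual rates explain; chance co-activations of member
# pairs also cross the threshold, so the detected rate slightly exceeds
# the embedded event rate.
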