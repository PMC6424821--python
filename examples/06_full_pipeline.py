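"""Run the full synthetic-session -> analysis -> report chain.

The default pipeline simulates a session with embedded assemblies,
PYR->FSI coupling, feedforward inhibition and a light-suppression epoch,
then runs every analysis stage and prints the report bundle.
"""
import json

from ca1nac.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
print(json.dumps(report, indent=1, default=str))
# report["assemblies"]: patterns detected on the first half and tracked on
#   the second; report["classification"]: striatal labels vs ground truth;
# report["spike_timing"]: short-latency excess of the coupled pairs;
# report["rate_scores"]: light-driven suppression scores;
# report["glm"]: held-out PYR->MSN prediction accuracy;
# report["behavior"]: place-preference score and occupancy total.
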