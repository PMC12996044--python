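"""Generate the synthetic anti-TNFa colon-like cohort used by all later steps.

22 responders vs 16 non-responders, 300 ASVs, 4 + 4 planted signal ASVs
(Mediterraneibacter gnavus-like enriched in non-responders, Blautia-like in
responders) at fold change 4, ~9.3% non-bacterial contaminant reads.
Writes counts/taxonomy/tree/metadata/truth under results/cohort/.
"""
import sys

from mucopred import simulate

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
cfg = simulate.SimulationConfig(seed=seed)
cohort = simulate.generate_cohort(cfg)
paths = cohort.write("results/cohort")
depths = cohort.counts.sum(axis=1)
print(f"cohort: {cohort.counts.shape[0]} samples x {cohort.counts.shape[1]} ASVs, "
      f"depth {depths.min()}-{depths.max()}")
print(f"planted signal: {', '.join(cohort.truth.asv_id)}")
for k, p in paths.items():
    print(f"  wrote {k}: {p}")
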