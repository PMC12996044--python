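"""Alpha diversity per sample and its responder vs non-responder comparison.

Observed richness, Shannon, Simpson (1 - sum p^2) and Fisher's alpha on the
filtered bacterial counts, compared between groups with the two-sided
rank-sum test.
"""
import json

from mucopred import diversity, simulate

counts = simulate.read_counts("results/counts_filtered.tsv")
metadata = simulate.read_metadata("results/cohort/metadata.tsv")
y = metadata.loc[counts.index, "response"]

alpha = diversity.alpha_diversity(counts)
alpha.to_csv("results/alpha_diversity.tsv", sep="\t", index_label="sample_id")

out = {}
for metric in alpha.columns:
    a = alpha.loc[(y == "responder").values, metric].dropna()
    b = alpha.loc[(y == "non_responder").values, metric].dropna()
    u, p = diversity.compare_alpha(a, b)
    out[metric] = {"U": u, "p": round(p, 4),
                   "median_responder": round(float(a.median()), 3),
                   "median_nonresponder": round(float(b.median()), 3)}
    print(f"{metric}: responder median {out[metric]['median_responder']} vs "
          f"non-responder {out[metric]['median_nonresponder']} (p={p:.3f})")
with open("results/alpha_comparison.json", "w") as fh:
    json.dump(out, fh, indent=2)
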