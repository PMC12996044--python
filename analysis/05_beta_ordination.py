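"""Beta diversity: distances, PCoA, PERMANOVA, envfit, centroid distances.

Bray-Curtis on relative abundances plus unweighted/weighted UniFrac on the
phylogeny; PCoA of each; PERMANOVA of response on each distance; prior-
biologic exposure flags projected onto the Bray-Curtis ordination; Euclidean
distance between group centroids on the first two axes.
"""
import json

import pandas as pd
from skbio import TreeNode

from mucopred import beta, simulate

counts = simulate.read_counts("results/counts_filtered.tsv")
relabund = pd.read_csv("results/relative_abundance.tsv", sep="\t", index_col=0)
metadata = simulate.read_metadata("results/cohort/metadata.tsv")
tree = TreeNode.read("results/cohort/tree.nwk", convert_underscores=False)
y = metadata.loc[counts.index, "response"]

report = {}
for name, dm in (("bray_curtis", beta.bray_curtis(relabund)),
                 ("unweighted_unifrac", beta.unweighted_unifrac(counts, tree)),
                 ("weighted_unifrac", beta.weighted_unifrac(counts, tree))):
    ordn = beta.pcoa(dm, n_axes=2)
    ordn.coordinates.to_csv(f"results/pcoa_{name}.tsv", sep="\t",
                            index_label="sample_id")
    perm = beta.permanova(dm, y, n_permutations=999, seed=11)
    report[name] = {"R2": round(perm.r2, 4), "pseudo_F": round(perm.pseudo_f, 3),
                    "p": perm.p,
                    "axis_pct": [round(float(100 * v), 1)
                                 for v in ordn.proportion_explained[:2]]}
    print(f"{name}: PERMANOVA R2={perm.r2:.3f} F={perm.pseudo_f:.2f} "
          f"p={perm.p:.3f}; axes explain {report[name]['axis_pct']}%")
    if name == "bray_curtis":
        cd = beta.centroid_distances(ordn, y)
        cd.to_csv("results/centroid_distances.tsv", sep="\t")
        print(f"  centroid distance responder vs non-responder: "
              f"{cd.iloc[0, 1]:.4f}")
        flags = [c for c in ("prior_anti_tnfa", "prior_vdz", "prior_uste")
                 if metadata[c].nunique() > 1]
        env = beta.envfit_vectors(ordn, metadata.loc[counts.index, flags],
                                  n_permutations=999, seed=12)
        report["envfit"] = {k: {"R2": round(env.r2[k], 4), "p": env.p[k]}
                            for k in flags}
        for k in flags:
            print(f"  envfit {k}: R2={env.r2[k]:.3f} p={env.p[k]:.3f}")
with open("results/ordination_report.json", "w") as fh:
    json.dump(report, fh, indent=2)
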