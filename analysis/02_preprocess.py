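"""Filter the cohort's count table and compute relative abundances.

Applies the minimum-4-reads presence filter, excludes non-bacterial
(Eukaryota / unassigned-Domain) ASVs with an accounting of the read share
they carried, and writes the renormalised bacterial relative abundances.
"""
from mucopred import preprocess, simulate

counts = simulate.read_counts("results/cohort/counts.tsv")
taxonomy = simulate.read_taxonomy("results/cohort/taxonomy.tsv")

filtered = preprocess.filter_min_reads(counts, min_reads=4)
bacterial, report = preprocess.exclude_nonbacterial(filtered, taxonomy)
relabund = preprocess.relative_abundance(bacterial)

bacterial.to_csv("results/counts_filtered.tsv", sep="\t", index_label="sample_id")
relabund.to_csv("results/relative_abundance.tsv", sep="\t", index_label="sample_id")
report.to_json("results/filter_report.json")

print(f"{report.n_asvs_before} ASVs after min-read filter "
      f"({counts.shape[1] - filtered.shape[1]} dropped by <4 reads); "
      f"{report.n_asvs_removed_taxonomy} non-bacterial ASVs excluded "
      f"carrying {100 * report.mean_excluded_fraction:.1f}% "
      f"+/- {100 * report.sd_excluded_fraction:.1f}% of reads per sample")
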