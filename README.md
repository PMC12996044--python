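# mucopred

Analysis toolkit for asking whether the **baseline mucosa-adherent gut
microbiome predicts response to biologic therapy in Crohn's disease**. The
input is a 16S rRNA amplicon-sequence-variant (ASV) count table from
intestinal biopsies taken *before* treatment start, plus taxonomy, a
phylogeny and per-patient clinical metadata; the question is whether
responders and non-responders (a composite endoscopic + clinical/biochemical
endpoint at 26–52 weeks) can be told apart from the microbial profile alone,
and which taxa carry the signal.

The package implements the full workflow as a library with a CLI, plus a
seeded synthetic-cohort generator with *planted* signal so every stage is
testable end-to-end without patient data:

1. **Preprocessing** — minimum-read filter (≥ 4 reads in ≥ 1 sample),
   exclusion of non-bacterial (Eukaryota / unassigned-Domain) ASVs with a
   read-share report, relative abundance, top-250 by mean abundance.
2. **Cohort statistics** — uncorrected Pearson chi-square and Mann-Whitney
   comparisons of baseline covariates; the composite responder rule.
3. **Diversity** — observed richness, Shannon, Simpson, Fisher's α;
   rank-sum group comparison.
4. **Ordination** — Bray-Curtis and (un)weighted UniFrac, PCoA, PERMANOVA
   (pseudo-F, R², permutation p), envfit-style vector projection of prior-
   biologic exposure, centroid distances.
5. **Response model** — LASSO stability selection (50 stratified shuffle
   splits, penalty 0.1, top 50 by stability score), extremely-randomized-
   trees classification under repeated nested cross-validation (10 outer
   stratified 75/25 splits, inner 5-fold grid search, mean AUC),
   whole-pipeline label-permutation testing (p = fraction of null AUCs ≥
   observed), and biomarker ranking by normalized feature importance with
   enrichment direction.

The statistical core in one line: stability score = #splits with nonzero
LASSO coefficient; AUC = P(score⁺ > score⁻) + ½P(tie); permutation
p = #{AUC_null ≥ AUC_obs}/n; PERMANOVA R² = SS_among/SS_total with
SS_total = Σ_{i<j} d²_ij / n. Details, defaults and conventions:
[docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole study shape on one
synthetic colon-like cohort (22 responders vs 16 non-responders, 300 ASVs,
4 + 4 planted signal ASVs at fold change 4, ~9% contaminant reads):

```bash
python analysis/01_simulate_cohort.py 1   # seed 1
python analysis/02_preprocess.py
python analysis/03_cohort_table.py
python analysis/04_alpha_diversity.py
python analysis/05_beta_ordination.py
python analysis/06_response_model.py 1 50  # seed 1, 50 permutations (~8 min)
```

Output excerpts from that exact run:

```
cohort: 38 samples x 300 ASVs, depth 20633-59475
planted signal: ASV_71, ..., ASV_78

295 ASVs after min-read filter (5 dropped by <4 reads); 17 non-bacterial
ASVs excluded carrying 8.8% +/- 1.9% of reads per sample

shannon: responder median 3.947 vs non-responder 4.003 (p=0.636)

bray_curtis: PERMANOVA R2=0.061 F=2.33 p=0.001; axes explain [8.1, 7.2]%
  centroid distance responder vs non-responder: 0.1327
  envfit prior_vdz: R2=0.165 p=0.051
```

Reading the numbers: the exclusion step removed close to the configured 9.3%
contaminant read share; α-diversity does not separate the groups (the
generator plants no diversity shift at these settings, so p ≈ uniform);
PERMANOVA attributes ~6% of compositional variance to response status —
the planted 8-ASV fold-change-4 signal — with a small permutation p; the
envfit arrows quantify how prior-biologic exposure flags align with the
first two PCoA axes (here: chance alignment, since the generator draws
covariates independently). `06_response_model.py` then recovers the planted
ASVs — for this seed:

```
mean AUC over 10 outer splits: 1.000
permutation test (50 label shuffles): p = 0.000 (null mean 0.899)
planted signal recovered in top 15: 8/8
 asv_id                   taxonomy   normalized_importance  direction
 ASV_74  Mediterraneibacter gnavus                   1.000  non_response
 ASV_71  Mediterraneibacter gnavus                   0.478  non_response
 ...
 ASV_77    Lachnospiraceae Blautia                   0.384  response
```

All four *M. gnavus*-like planted ASVs rank highest with direction
"non_response" and the four *Blautia*-like ASVs follow with "response" —
exactly the generator's truth. Note the AUC of 1.0 is the optimistic
pre-selection estimate (stability selection sees all samples); the
permutation p, whose null shares that optimism, is the calibrated quantity.

The same run is available as a single command via the CLI
(`mucopred all --seed 1 --outdir results/run`), driven by an optional YAML
config (see `mucopred --help`).

## Acceptance script

`scripts/acceptance.py` re-runs the complete end-to-end analysis from
scratch — cohort generation, preprocessing, cohort table, diversity,
ordination + PERMANOVA + envfit, stability selection, nested CV and the
50-permutation test — from a single seed, prints a summary, and writes the
acceptance JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Stage outputs land under `scratch/acceptance/`. Runtime is ~10 minutes on
one CPU.
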