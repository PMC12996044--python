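# Methods

`mucopred` implements the computational workflow for asking whether the
baseline mucosa-adherent microbiome — 16S rRNA amplicon sequence variant
(ASV) profiles from intestinal biopsies — can predict a Crohn's disease
patient's response to biologic therapy, together with a synthetic-cohort
generator that makes every stage testable without access to patient data.
This note records the models, the defaults and why, and what the green test
suite does and does not establish.

## Response label

A patient is a *responder* at 26–52-week follow-up iff

```
[SES-CD reduction >= 50%]  AND  (
    [clinical:     (HBI drop >= 3  OR  follow-up HBI <= 4)  AND  no systemic steroids]
 OR [biochemical:  (CRP  drop >= 50%  OR  follow-up CRP  <= 5 mg/L)
               AND (fcal drop >= 50%  OR  follow-up fcal <= 250 µg/g)] )
```

SES-CD is the simple endoscopic score for Crohn's disease, HBI the
Harvey-Bradshaw index, CRP C-reactive protein, fcal faecal calprotectin.
The endoscopic criterion is a hard gate; clinical and biochemical
improvement are alternative second conditions. The rule is monotone: improving
any single follow-up value can never turn a responder into a non-responder
(property-tested). A zero baseline counts as "reduced by half" only when the
follow-up is also zero, so the absolute thresholds do the work for patients
who start in remission on that measure.

## Preprocessing

1. **Minimum-read filter** (default 4): an ASV is retained iff it reaches
   ≥ 4 reads in at least one sample. The alternative reading — zeroing
   sub-threshold cells sample-by-sample — is available as `per_sample=True`.
   Retained counts are never altered; the two filters below commute.
2. **Non-bacterial exclusion**: ASVs whose Domain is Eukaryota *or*
   unassigned are removed together; the per-sample read fraction they carried
   is reported (mean ± sd) but the ASVs take no further part.
3. **Relative abundance** is computed *after* exclusion, i.e. renormalised
   over bacterial reads, because downstream features should describe the
   bacterial community; pre-exclusion fractions live only in the filter
   report.
4. **Top-N by mean relative abundance** (default 250) with ties broken by
   ascending ASV id and a deterministic output column order, so feature
   indices are stable across runs.

## Diversity and ordination

α-diversity: observed richness, Shannon entropy in nats (a base option
exists), Simpson as 1 − Σp² (variants Σp² and 1/Σp² available), and
Fisher's α as the positive root of S = α·ln(1 + N/α), solved by bracketing
plus Brent to 1e-10 and undefined when every read is its own taxon (S = N).
Group comparisons use the two-sided unpaired rank-sum (Mann-Whitney) test —
the source protocol names the signed-rank test but compares independent
groups of unequal size, for which the unpaired test is the only applicable
variant.

The Mann-Whitney implementation uses the exact null distribution when both
groups have n ≤ 8 and the pooled sample is tie-free, otherwise the normal
approximation with tie-corrected variance and *no* continuity correction;
identical samples therefore give p = 1 exactly, which keeps the symmetric
case (z = 0) honest. The chi-square test for categorical covariates is the
uncorrected Pearson test: on 2×2 tables it is algebraically the square of
the two-proportion score z-test (checked numerically), and it is the variant
that reproduces the reference cohort's printed baseline p-values; Yates'
correction does not.

β-diversity: Bray-Curtis on relative abundances; unweighted UniFrac
(presence/absence branch fractions) and weighted UniFrac (branch lengths
weighted by the absolute difference of subtree read fractions). Weighted
UniFrac defaults to the normalized variant — raw distance divided by the
pair's maximum attainable value, Σ over tips of depth·(pₓ+p_y) with depth
measured tip-to-root — so values are comparable across pairs; the raw
variant is a flag. Distances are validated in the tests against naive
branch-enumeration oracles on small random trees.

PCoA Gower-centers −d²/2 and eigendecomposes. Negative eigenvalues (common
for non-Euclidean dissimilarities) are reported but receive no axis and no
share of `proportion_explained`, which is normalised over positive
eigenvalues only; no Cailliez/Lingoes correction is applied. Axis signs are
fixed deterministically (largest-magnitude coordinate positive).

PERMANOVA uses the definitional sums of squares (SS_total = Σ_{i<j} d²/n and
the per-group analogue) and the (1 + r)/(1 + n_permutations) p-value
convention with a seeded generator; the ML permutation test below instead
uses the plain fraction r/n, because that protocol defines its p explicitly
as a fraction — the add-one variant is a flag on both sides. envfit-style
vector fitting regresses each (numeric or 0/1) covariate on the first two
PCoA axes; the arrow is the coefficient direction scaled to length √R², and
p permutes the covariate values. Group centroid distances are plain
Euclidean means on axes 1–2.

## The response model

Step 1 — *stability selection*: over 50 stratified 75/25 shuffle splits, a
squared-error LASSO (penalty 0.1, features standardized per training split,
intercept unpenalised; an L1-logistic variant is a flag) is fitted to the
0/1 response; each feature scores the number of splits in which its
coefficient is nonzero (|β| > 1e-10), and the top 50 by score (ties by
ascending id) are retained.

Step 2 — *nested cross-validation*: 10 outer stratified 75/25 shuffle
splits; within each outer training set, an inner stratified 5-fold grid
search (default grid: trees {100, 300} × max-features {sqrt, log2} ×
min-leaf {1, 3}; ties go to the first grid entry) picks the configuration of
an extremely-randomized-trees classifier by mean AUC; the winner is refitted
on the whole outer-training portion and scored on the held-out quarter. AUC
is the Mann-Whitney probability that a random positive outscores a random
negative with ties counted ½. Reported performance is the mean over the 10
outer AUCs; feature importances are the impurity importances averaged over
the 10 refitted models.

Step 3 — *permutation test*: the observed mean AUC is compared with mean
AUCs from re-running the **whole** pipeline — stability selection included,
so selection optimism is part of the null — on label permutations
(200 by default; desk-scale runs use 50). p = #{null ≥ observed} / n.
Because selection precedes the outer CV, the observed mean AUC is an
optimistic quantity; the permutation p, not the AUC itself, is the
calibrated statistic, and the null-calibration test verifies it is uniform
under a zero-effect generator.

Step 4 — *biomarker ranking*: top-15 features by mean importance, normalized
to the maximum (so the best feature scores exactly 1); the direction label
("response"/"non_response") comes from comparing group mean relative
abundances, with exact ties marked indeterminate.

Cross-validation is at sample level without patient-level grouping,
mirroring the acknowledged limitation of the design it reimplements.
Seeding: one master integer seed per entry point is split into per-component
sub-streams via `numpy.random.SeedSequence`; the whole pipeline is
bit-reproducible for a fixed seed.

## Synthetic cohorts

The generator states a world resembling the anti-TNFα colon sub-cohort:

- 22 responders vs 16 non-responders, 300 ASVs.
- Baseline composition: log-normal relative abundances (σ = 1.5), sorted, so
  the abundance rank curve is steep and a top-250 filter is genuinely
  selective.
- Counts: Dirichlet-multinomial with concentration 200 × composition —
  moderate overdispersion typical of mucosal 16S profiles (per-taxon CV of
  order 1 at sub-percent abundances); depth uniform on [20 000, 60 000]
  (the source reports no per-sample depths; these are ordinary V3-V4
  amplicon depths).
- Signal: 4 "non-response" ASVs (labelled *Mediterraneibacter gnavus*-like)
  and 4 "response" ASVs (*Blautia*-like) whose expected relative abundance
  is multiplied by fold change 4 in their enriched group, then renormalised
  — multiplicative on composition, matching the compositional nature of 16S
  data. They are planted at mid-abundance ranks (around rank n/4) so they
  survive the top-N filter without dominating.
- Contaminants: 5.6% of ASVs (mirroring 343 of 6 174) carry Domain
  Eukaryota or no Domain and an expected 9.3% of each sample's reads, giving
  the exclusion step something real to remove.
- Clinical covariates are drawn from documented Bernoulli/log-normal
  marginals resembling a baseline biologics cohort and are **independent of
  the response label** — so any covariate "difference" in a synthetic run is
  chance, and the cohort-table stage can be null-calibrated.

What the generator does *not* emulate: read-level error, chimeras,
ecological covariance between taxa, batch effects, paired ileum/colon
structure, or covariate–response confounding. A green planted-signal test
therefore establishes that the pipeline recovers a compositional enrichment
of the stated size against Dirichlet-multinomial noise — not that it would
achieve any particular AUC on real mucosal cohorts.

## Numerical choices and degenerate inputs

- LASSO: scikit-learn coordinate descent, tolerance 1e-6; constant columns
  dropped with a warning (coefficient 0).
- Fisher's α: bracket doubling + Brent, |S − α ln(1+N/α)| < 1e-10.
- Tie-breaks everywhere are "descending score, then ascending feature id".
- Zero-total samples raise named `DegenerateSampleError`s rather than
  propagating NaNs; missing taxonomy raises an error naming the ASV; a
  counted ASV absent from the tree raises a missing-leaf error.
- Permutation p-values: PERMANOVA/envfit (1+r)/(1+n); ML permutation test
  r/n (see above).
- Desk-scale test settings: the null-calibration suite reduces stability
  splits to 10, outer repetitions to 3 and the grid to one 30-tree
  configuration, and the recovery suite uses a two-configuration 100-tree
  grid; statistical thresholds are not loosened in exchange.

## Known limitations

- The squared-error LASSO treats the binary label as a regression target
  (as in the reimplemented protocol); the logistic flag exists but is not
  the default.
- `fisher_alpha` is reported as NaN in per-sample tables where undefined.
- The six-model treatment × location sweep is expressed through
  configuration (cohort selectors) rather than hard-coded; the synthetic
  generator emulates one cohort at a time.
- PERMANOVA supports one grouping factor, no strata.
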