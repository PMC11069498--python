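# Methods

## Rank-mean differential abundance with discrete FDR

Per ASV, relative abundances are ranked across samples with average ties;
the test statistic is the difference of group mean ranks. Count tables are
converted to per-sample relative abundances before ranking so sequencing
depth cannot masquerade as abundance difference; relative or log tables are
ranked as given. Being rank-based, the statistic is invariant to any
strictly monotone per-feature transform.

The null is built by permuting group labels. When the number of distinct
label assignments C(n, n_A) does not exceed the permutation budget, all
assignments are enumerated (the identity included), and p-values are exact
fractions; otherwise assignments are resampled and p-values use the add-one
convention (1 + hits)/(1 + B) so a sampled p is never zero. `allow_exhaustive
= False` forces resampling, which exists so sampled p-values can be checked
against enumeration on small designs.

dsFDR control scans candidate thresholds t over the distinct observed
|effect| values in ascending order and picks the smallest t whose
plug-in estimate

    FDR(t) = mean over permutations of #{ |null statistic| >= t }
             / max(1, #{ |observed effect| >= t })

is at or below the target level (default 0.1, matching the level typically
used to derive signed ASV sets); features with |effect| >= t are called.
If no threshold qualifies the significant set is empty. Because the
exhaustive null contains the observed labeling, FDR(t) is strictly positive
and the selection is empty in the alpha -> 0 limit. The estimator is
unit-tested against a brute-force scan over all candidate thresholds.

Defaults: 1000 permutations, two-sided, alpha = 0.1. The test requires at
least 2 samples per group. Group A is the first label encountered unless an
explicit (A, B) order is passed; reversing the order negates every effect
and (for equal group sizes) leaves p-values and the significant set
unchanged.

## Log-rank-ratio index scoring

An index is two disjoint ASV sequence sets. Scoring ranks each feature's
relative abundance across the scored samples (average ties) and takes, per
sample, the natural log of the ratio of the mean rank over the positive set
to the mean rank over the negative set. Mean (not sum) aggregation keeps
unequal set sizes from biasing the ratio; average ranks are always >= 1 so
scores are finite. Index features absent from a sample contribute their low
across-sample rank rather than being skipped — zeros are informative and
keep the score defined.

Two readings of "rank transforming the samples" exist: ranking each feature
across samples versus ranking features within a sample. The default is
per-feature across-sample ranking (the convention of published log-ratio
health indices); `rank_within_sample=True` selects the alternative. Ranks
are computed over the scored (target) samples only; pooling reference and
target samples before ranking is possible by concatenating tables but is
not the default. The natural log base only shifts the scale.

Cross-cohort matching truncates both sequences to the shorter of the two
lengths and requires exact equality, with a 150 nt minimum (ASV pipelines
discard shorter reads, so any real ASV id clears it); matching is
prefix-indexed so it stays fast at thousands of ASVs. Coverage per set is
reported, and an index whose positive or negative set matches nothing is an
error rather than a silently degenerate score.

## Preprocessing filters

* Prevalence: features nonzero in strictly less than the cutoff fraction of
  samples (default 1%) are removed; a feature exactly at the boundary is
  kept (the rule is read strictly).
* Contaminants: an ASV is removed when the mean of its water, soil and
  mouse f-scores strictly exceeds its human f-score; ties are kept;
  unscored ASVs are kept and reported.
* Rarefaction: multivariate hypergeometric subsampling (without
  replacement) to exactly the requested depth; samples below depth are
  dropped and reported, not an error. Seed-deterministic.
* Metabolites: sum-normalization divides each value by the sample total.
  Correlation prep runs per metabolite: zeros -> (smallest nonzero)/5
  (exact division, no rounding), natural log, then clipping at the log-scale
  mean +/- 4 SD. The trim is applied on the log scale because downstream
  correlations are computed on log values; the step order is a documented
  choice. The pipeline applies prevalence filtering before contaminant
  filtering by default; both orders are available since the operations
  commute on the feature sets they remove.

## Cohort statistics

Age matching bins ages into fixed-width bins anchored at zero ([0,10),
[10,20), ... by default) and retains min(count_A, count_B) samples per bin
in each group, dropping the surplus uniformly at random with a seed.

Concordance between two contrasts' per-feature coefficients reports the
fraction sharing a strict sign (zero coefficients count as disagreement and
are listed) and the Spearman correlation with its two-sided p.

The consistency test asks whether correlations computed on all samples keep
their sign in a subset more often than chance. The chance level is
p_all·p_cd + (1 − p_all)(1 − p_cd) — the probability that two independent
sign draws with positive-rates p_all and p_cd agree — which accounts for an
unbalanced positive:negative ratio. The p-value is an exact binomial upper
tail P[X >= n_consistent]; one-sided because the hypothesis is excess
consistency (a two-sided variant is available).

## Paired-omics coupling

The first latent components of two blocks are the leading singular pair of
the column-standardized cross-covariance X'Y, computed by alternating power
steps with optional soft-threshold sparsity that keeps a configured
fraction of loadings nonzero (keep-fraction 1 reduces exactly to plain
two-block PLS, verified against a direct SVD). Sign convention: the
largest-magnitude X loading is made positive and the Y weight's sign is
then chosen so the cross-block covariance of the components is
non-negative — the optimum of the PLS objective is a non-negative singular
value, and fixing both signs independently could flip the component
correlation's sign arbitrarily, which would break the one-sided permutation
rule below. Blocks are centered and unit-scaled by default.

Significance: one block's sample order is permuted (the Y block by default;
either is supported and the null law is empirically the same), components
are refit per permutation, and p = #(null rho > observed rho)/B with B = 100
by default — the literal counting rule with strict inequality, so p = 0 is a
reportable outcome meaning no permutation beat the observed correlation. An
add-one variant is available for users who prefer never-zero p-values.

## Synthetic cohort generator

Counts are Dirichlet-multinomial: per-feature base concentrations are
lognormal weights (sigma 1.5) normalized to a total mass of 100 — low
enough for the strong overdispersion and sparsity typical of 16S data —
and per-sample depths are negative-binomial with mean 50,000 reads and size
30 (IQR roughly 40–60k, the scale of modern MiSeq/NovaSeq runs). Planted
effects multiply concentrations by 2^(±log2fc) in the affected group,
preserving compositionality. Defaults plant 30 positive and 20 negative
ASVs of 300 at log2fc = 2 with 50 samples per group; no published effect
size exists for rural/urban taxon shifts, so this is a calibration choice
sized to make recovery non-trivial but attainable. Feature ids are random
150-nt sequences, since real ASVs are sequence-identified and cross-cohort
matching operates on sequences. Rural groups draw ages from (40, 65) and
urban/CD groups from (~20, 40), mirroring the age confounding such cohorts
show and giving the age-matching stage something real to do.

The target cohort reuses the reference feature universe and planted sets,
scaling the planted log2 fold-change per group (e.g. rural 1.0,
rural-urban 0.5, urban 0.4, CD 0.0) to plant a monotone index gradient.
Contaminant ASVs get f-score rows whose environmental mean exceeds the
human score by construction. Coupled omics blocks are
sqrt(f)·latent⊗loading + sqrt(1−f)·noise with a shared standard-normal
latent.

What the generator does not emulate: phylogenetic correlation between ASVs,
taxonomic structure, batch effects, longitudinal sampling, and real
zero-inflation beyond what the Dirichlet-multinomial produces. Passing
recovery tests therefore shows the statistics behave as designed under the
assumed generative model, not that effect sizes in real cohorts are as
clean.

One consequence of compositional planting: concentrating extra mass in
planted features displaces every other feature's *relative* abundance in
the affected group. At dense planting (50 of 300 features) the rank test
legitimately detects some of that spillover, so the realized
false-discovery rate measured against the planted list overstates the
test's error on truly null features; calibration checks therefore use
sparse planting (10% of features), where spillover is negligible.

## Numerical choices and degenerate inputs

Ties always receive average ranks. Comparisons against permutation
statistics use a 1e-12 tolerance so ties between observed and null values
count as hits (conservative). Empty tables, all-zero samples/metabolites,
groups below 2 samples, indices with empty or overlapping sets, constant
blocks and out-of-range probabilities raise named errors rather than
propagating NaNs. All generators and permutation tests are deterministic
given their seed; the pipeline derives per-stage seeds from a single global
seed by CRC-hashing stage names, so adding a stage leaves earlier stages'
randomness untouched.

## Problem sizes

The shipped tests and the acceptance script run on simulated cohorts of
20–50 samples per group with 100–300 features, 1000-permutation tests, and
100–200 replicate calibration studies — sizes chosen so the complete
validation executes in minutes on a single core while keeping Monte-Carlo
error well below the margins being checked.

## Known limitations

* The dsFDR plug-in estimator is one published variant; alternatives
  (e.g. normalizing statistics per feature) can differ at the margin.
* Realized FDR measured against planted truth runs slightly above the
  nominal level on dense compositional plantings (see above).
* The coupling test extracts one component per block; multi-component or
  multi-block integration is out of scope.
* Covariate adjustment (age, gender) inside the differential abundance test
  is out of scope; age-bin matching is the supported confounder control.
* The published metabolite-coefficient concordance worked example requires
  the original study's supplementary coefficient table, which is not
  redistributed here; the acceptance test for it reports that requirement.
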