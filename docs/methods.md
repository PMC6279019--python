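# Methods

This note documents the models, defaults and numerical choices behind
`microsig`, and what the synthetic-data tests do and do not establish
about real cohorts.

## Study design the package targets

The target design is two independent 16S stool cohorts, each a
sample-by-OTU count table with 7-rank taxonomy and per-sample metadata
(a four-level group label with severe imbalance, plus sex, age, BMI and
free categorical factors). The scientific question is whether the group
label carries a community-level signal and, more importantly, whether
specific taxa shift reproducibly across *both* cohorts — replication,
not single-cohort significance, is the unit of evidence.

## Quality control

Samples are filtered in a fixed order — BMI ∈ (10, 60), age present and
in [18, 55], presence in the count table, known group label, fecal body
site, known sex, accepted country (default {USA}) — then OTUs with fewer
than 10 total reads are dropped and finally samples with fewer than 1,000
reads. Each sample is attributed to the *first* step at which it fails,
so the per-step attrition in `QCReport` sums to the total and is directly
comparable across runs. QC is idempotent. The accepted-ethnicity set is
configurable (`known_ethnicities=None` accepts any non-missing label) so
the same code path serves arbitrary group labels.

## Rarefaction and diversity

Rarefaction draws multivariate-hypergeometric subsamples (without
replacement) to exact depth; samples below depth are dropped, never
padded. Alpha metrics follow the QIIME-1 conventions: Shannon in bits
(log base 2 — documented prominently because ln is the other common
choice), Equitability = Shannon/log2(S_obs), Simpson = 1 − Σp², Chao1
bias-corrected S + F1(F1−1)/(2(F2+1)) by default with the classical
S + F1²/(2F2) behind a flag. Alpha values are averaged over 10
rarefactions by default (a runtime choice; the estimate stabilises
quickly), beta-diversity consensus matrices over 100. Supported beta
metrics are Bray–Curtis, binary Jaccard, Canberra and Euclidean;
phylogenetic metrics are out of scope (no tree input). Default depths of
1,000 and 10,000 bracket the regimes where shallow sampling does and does
not dominate.

## Distinguishability

* **ANOSIM** ranks the condensed distances once (average ranks on ties)
  and permutes labels. Permutation p-values use (1 + hits)/(1 + perms),
  so p is never 0. When the number of distinct label assignments is at
  most the requested permutation count (`method="auto"`), the test
  switches to exhaustive enumeration and p becomes an exact proportion
  (observed assignment included). The subsampling variant repeatedly
  down-samples groups above a cutoff and averages R and p; the ablation
  ledger runs every leave-one-group-out and every group pair.
* **PERMANOVA** uses sequential (Type-I) sums of squares in the listed
  term order on the Gower-centred matrix, matching the default of the
  standard formula interface for `dm ~ ethnicity + age + sex + bmi`.
  Hat matrices come from rank-revealing QR; a constant or collinear term
  receives zero df and an NA p rather than an error. Significance is by
  permutation of sample rows; passing several rarefied matrices averages
  the per-term statistics. Implemented in-package because the established
  Python implementation is single-factor; it is used as the independent
  cross-check for the single-factor case in the tests.
* **Adapted BioEnv** encodes continuous variables as centred/scaled
  columns and categoricals as full-rank dummies (reference level
  dropped), takes Euclidean distances over the whole encoded block, and
  correlates them (Spearman) with the community distances. A variable's
  p-value is the fraction of runs in which shuffling *that variable
  alone* (its underlying labels, never its encoded columns
  independently) reaches the observed all-variable correlation.

## Per-taxon screens and replication

Tables are collapsed phylum→genus; an OTU unclassified at the collapse
rank stays distinct inside its deepest classified parent
(`...; f__X; g__Unclassified`), which makes genus-level collapse sum
consistently to family-level collapse. The Kruskal–Wallis screen is
tie-corrected and vectorised: ranks per taxon are computed once and label
permutations only recompute group sums, which is what makes the
1,000-permutation replication null cheap. BH-FDR and Bonferroni are
applied within each (rank × factor) family. An exact-enumeration
Kruskal–Wallis (`kruskal_wallis_exact`) exists for small designs.

The replication overlap counts identically-labelled taxa FDR-significant
in both cohorts; its null distribution comes from shuffling group labels
independently in both cohorts and re-running the full screen + FDR each
time. Note the overlap is a discrete statistic whose null mass sits at
zero, so under the null its permutation p concentrates at 1 — the test is
conservative by construction, and the calibration suite checks type-I
validity rather than exact uniformity for this one statistic (the KW and
BioEnv p-values are checked for uniformity directly).

Redundancy collapsing: a significant (family, child genus) pair is one
taxon, not two, when the genus carries ≥ 82% of the family's mean
abundance in every group; the classified genus is kept, else the family.
Pairwise shifts use Mann–Whitney U on all individuals (zeros are data),
Bonferroni-corrected for the 6 pairs within each taxon and cohort;
direction is the sign of the mean difference, with the ubiquity direction
reported separately (a shift can be carried by carriage rather than load).
A contrast is "replicated" when Bonferroni-significant in both cohorts
with matching abundance direction.

Covariate regressions fit, per taxon, log10 abundance among possessors
(OLS, possessors ≥ 10) and presence/absence over everyone (logistic),
each with group only and with group + age + sex + BMI; the group factor
is coded with full-rank dummies against the largest group as reference.
Overall-model significance is the F test (linear) or LR test (logistic)
against the intercept-only model.

## Imbalance-aware classification

Features: rarefy to 10,000 (configurable), collapse to genus with
higher-rank fallback, drop taxa present in fewer than
floor(rarest-group/2) samples, close to relative abundance,
arcsin(√·) transform. One binary random forest per group (one-vs-all),
stratified k-fold CV with resampling applied only to training folds:
*downsampling* truncates the majority to the minority size; *SMOTE*
doubles the minority by k-NN interpolation (k = 5, reduced when the
minority is tiny) and downsamples the majority to match — implemented
in-package. ROC curves are averaged on a common FPR grid; the final
model refit on resampled full data supplies the out-of-bag error, and
importances are scaled to percent of the maximum. The leakage property —
pure-noise features must give AUC ≈ 0.5 under both schemes, and moving
resampling outside the split must break that — is a permanent regression
test.

## FST and percentile ranking

Per-variant Weir–Cockerham (1984) two-population θ̂ = a/(a+b+c) from
genotype counts, with missing genotypes excluded per variant per
population (complete-case); negative estimates are reported as computed.
Variants with global MAF < 0.01, < 2 called diploids in a population, or
monomorphic-and-identical in both populations are skipped. The
multi-locus summary is the weighted Σa/Σ(a+b+c) — the plain mean of
per-variant ratios is biased downward by Jensen's inequality, and the
calibration tests use the weighted form. Percentiles use strict
"higher-than" counting against same-chromosome and genome-wide
backgrounds per population pair; the 95%/99% flags are inclusive (≥) and
require both backgrounds to agree. Population-pair exclusion is a config
list, not hard-coded.

## Synthetic-data generator

Counts are Dirichlet-multinomial (default overdispersion 200) around a
log-normal base composition (log-sd 1.5), with per-sample depth uniform
on a configurable range and per-(sample, taxon) Bernoulli zero inflation
(default carriage 0.7) applied before renormalisation. Planted effects
multiply a taxon's expected relative abundance in the affected group
before closure, so realized fold changes are damped for abundant taxa —
tests use tolerance bands, not exact ratios, and plant on low-abundance
taxa when checking fold recovery. Taxonomy (25 families, 20% unclassified
genera) is drawn from a dedicated `taxonomy_seed` so paired cohorts share
lineage strings the way real cohorts share a reference taxonomy, while
base profiles and noise remain cohort-specific. Covariates are drawn
inside the QC window by construction (age U[18, 55], BMI N(25, 4)
truncated to (10, 60), sex Bernoulli(0.5)); a configurable co-occurring
family block is driven by a shared latent log-normal factor. Default
group sizes mirror the four-level, ~90%-majority imbalance of a large US
crowd-sourced cohort (1237/88/37/13); tests and the acceptance script use
proportionally scaled-down sizes, chosen as the package's own problem
sizes and stated next to each computed quantity.

Variant panels follow the Balding–Nichols model: ancestral frequency
U(0.05, 0.95), per-population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F),
diploid genotypes binomial. Constructed outliers use deterministic
opposite-tail placement around a mid-range ancestral frequency
(p ± √(F_out·p(1−p))) so that outlier recovery is a property of the
estimator and ranking, not of lucky beta draws.

**What passing tests do and do not show.** The generator reproduces
compositionality, overdispersion, zero inflation, class imbalance and
cross-cohort replication structure; it does not simulate sequencing
error, chimeras, phylogenetic relatedness, batch effects between cohorts,
or covariate–group confounding. Null calibration and planted-effect
recovery on this generator therefore validate the statistical machinery,
not the biological interpretation of any particular real-data result.

## Numerical choices and degenerate inputs

Permutation comparisons use a 1e-12 slack so ties at the observed
statistic count as hits. All-tied taxa get H = 0, p = 1 and a flag.
All-zero samples are rejected by beta diversity with the sample named.
Constant families are excluded from co-occurrence with a warning.
Group-ablation subsets with fewer than two groups are skipped with a
note. A/U mean abundance includes zero-count samples by default
(possessors-only behind a flag; the ratio-of-means alternative for the
group mean A/U is likewise a flag). Co-occurrence clusters are connected
components of the Bonferroni-significant positive-edge graph at
rho ≥ 0.3 — an explicit formalisation of what is usually read off a
clustermap by eye — with cluster-associated families defined by ≥ 3
significant positive links into a cluster.

## Known limitations

Spearman co-occurrence on closed compositions partially mitigates but
does not remove closure-induced dependence (no SparCC-style correction;
see Non-goals). Multi-class classification is deliberately absent: on
data this imbalanced it collapses to the majority class. The adapted
BioEnv p-value is one-sided toward positive correlation. UniFrac-type
metrics need a phylogeny and are out of scope.
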