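# microsig

Detection of reproducible group-associated signatures in 16S gut-microbiota
cohorts.

## The problem

Observational gut-microbiome cohorts routinely ask whether a categorical
host factor — ethnicity is the motivating case, but any self-declared group
label works — leaves a detectable and, critically, *reproducible* imprint
on stool 16S profiles. Two things make this hard: the community signal is
subtle (inter-individual variation dominates, ANOSIM R values are typically
well below 0.1), and cohorts are severely imbalanced (one majority class
can be ~90% of samples), which breaks naive classifiers and inflates
naive pair-counting statistics. `microsig` implements the full inference
stack for this design as a tested, reusable library:

* **Distinguishability** on consensus rarefaction distance matrices:
  ANOSIM (with exact enumeration for small designs), multi-term
  sequential-SS PERMANOVA (`dm ~ ethnicity + age + sex + bmi`), and an
  adapted BioEnv test that scores one metadata variable at a time by
  shuffling only that variable among the full encoded block.
* **Community structure**: intra- vs inter-group beta-diversity contrasts
  (all-pairs and per-individual-mean modes), per-group ubiquity sets with
  abundance/ubiquity (A/U) stability statistics, and Bonferroni-masked
  Spearman co-occurrence clusters of families.
* **Per-taxon screens**: Kruskal–Wallis across groups at every collapse
  rank with BH-FDR and Bonferroni correction, cross-cohort replication
  overlap with a label-permutation null, taxonomic-redundancy collapsing
  (≥82% parent-abundance rule), pairwise Mann–Whitney shifts with
  direction and replication flags, and linear/logistic covariate
  regressions on abundance and presence.
* **Imbalance-aware classification**: one-vs-all random forests with
  SMOTE or downsampling applied strictly *inside* the cross-validation
  training folds (the suite contains a regression test that fails if
  resampling ever leaks outside the split).
* **Population genetics**: per-variant Weir–Cockerham (1984) FST between
  population pairs with chromosome-wide and genome-wide percentile ranks
  and 95%/99% outlier flags.
* **Synthetic data**: a Dirichlet-multinomial cohort generator (planted
  group effects, covariates, zero inflation, co-occurring family blocks)
  and a Balding–Nichols variant-panel generator, so every stage is
  testable without any external download.

## Core statistics

ANOSIM: with distances rank-transformed once (average ranks on ties),

    R = (r̄_between − r̄_within) / (n(n−1)/4),

and p from label permutations using the (1 + hits)/(1 + permutations)
convention. PERMANOVA partitions the Gower-centred inner-product matrix
G = −½ J D² J with sequential (Type-I) sums of squares per model term,
pseudo-F = (SS_t/df_t)/(SS_res/df_res). The Weir–Cockerham per-variant
estimator is the ratio of variance components θ̂ = a/(a+b+c) from genotype
counts (observed heterozygosity included); the multi-locus summary is the
weighted form Σa / Σ(a+b+c).

## Worked example

Two paired synthetic cohorts with a planted 5-fold reduction of one family
in the Asian-Pacific Islander group:

```python
import microsig as ms

effects = [ms.PlantedEffect("f__Family03", "Asian-Pacific Islander",
                            fold_change=0.2)]
sizes = {"Caucasian": 120, "Asian-Pacific Islander": 30,
         "Hispanic": 20, "African American": 10}
cfg_a = ms.SimulationConfig(seed=1, n_samples_per_group=sizes,
                            n_otus=120, depth_range=(2000, 6000))
cfg_b = ms.SimulationConfig(seed=2, n_samples_per_group=sizes,
                            n_otus=120, depth_range=(2000, 6000))
(ta, ma), (tb, mb) = ms.generate_paired_cohorts(cfg_a, cfg_b, effects)

dm = ms.consensus_distance(ta, "bray_curtis", depth=1000,
                           n_rarefactions=100, seed=0)
res = ms.anosim(dm, ma["ethnicity"], n_perm=999, seed=0,
                method="permutation")
print(f"ANOSIM R = {res.R:.3f}, p = {res.p:.3f}")

fam_a = ms.collapse_taxonomy(ta, "family")
fam_b = ms.collapse_taxonomy(tb, "family")
rec_a = ms.kruskal_by_group(fam_a, ma["ethnicity"])
null = ms.overlap_permutation_null([fam_a], ma["ethnicity"],
                                   [fam_b], mb["ethnicity"],
                                   n_perm=1000, seed=0)
print(f"replication overlap = {null.overlap['family']}, "
      f"permutation p = {null.permutation_p['family']:.4f}")
top = rec_a.iloc[0]
print(f"top taxon: {top['taxon'].split(';')[-1].strip()} "
      f"(H = {top['H']:.1f}, p_fdr = {top['p_fdr']:.2e})")
```

prints

```
ANOSIM R = 0.013, p = 0.349
replication overlap = 1, permutation p = 0.0010
top taxon: f__Family03 (H = 43.4, p_fdr = 5.12e-08)
```

This is the expected shape of the science: one planted taxon barely moves
whole-community distinguishability (R ≈ 0.01, not significant), yet the
taxon-level screen finds it decisively in both cohorts, and the one-taxon
overlap is already more than any of the 1,000 label-permuted runs achieve
(p = 1/1001). Whole-community R grows with the number of planted taxa.

A CLI mirrors the file-to-file steps (`microsig qc`, `diversity`,
`distinguish`, `structure`, `taxa`, `fst`, `simulate`); run
`microsig --help` for the options.

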