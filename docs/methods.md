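# Methods

## Model and rationale

The package analyses an aligned haploid marker — the mitochondrial control
region (mtCR), maternally inherited and hypervariable — in samples from
estuaries monitored around a hatchery release program. Two properties of the
marker carry the whole inference:

1. **Near-unique haplotypes in the wild.** With very large effective
   population size and a high control-region mutation rate, almost every
   wild-born individual carries a distinct haplotype. Identity of two
   haplotypes within a site is therefore strong evidence of maternal sibship
   rather than identity-by-state coincidence.
2. **Matroclinous inheritance without mutation over the study horizon.**
   Offspring carry their dam's haplotype exactly; release-to-recapture spans
   months, so per-generation mutation is ignored and kinship calls use exact
   string identity (a mismatch-tolerant mode is deliberately not the
   default: the sibship argument is built on exact sharing).

Hatchery cohorts descend from few dams with highly skewed fecundity, so
released animals arrive as a few large maternal families. The stocking
signal is the excess of within-site haplotype sharing over the background
sharing measured at never-stocked reference estuaries, corroborated by exact
haplotype matches to genotyped broodstock.

## Estimators and numerical conventions

- **Haplotype identity** is exact string equality over all aligned columns,
  N and gaps included. Merging "compatible-under-missing" sequences would
  require an arbitrary merge order; with clean Sanger consensus data the
  distinction is marginal.
- **Distances** count differing columns where both sequences have a definite
  base; columns with N or a gap in either sequence are excluded pair by pair
  (*pairwise deletion*), and the per-pair comparable-site count is kept so
  π is a true per-site proportion. A complete-deletion mode (drop a column
  for everyone if anyone is missing) is available as a configuration switch.
- **Haplotype diversity** uses the unbiased estimator
  h = n/(n−1)(1 − Σp²), identical to the fraction of unordered pairs that
  differ — the form the brute-force test oracle uses.
- **Percent divergence** (within/between populations) is the raw mean
  pairwise per-site difference × 100 — no Jukes–Cantor correction and no
  subtraction of within-population diversity ("gross", not "net"),
  consistent with within ≈ between ≈ π for a panmictic stock. Note that for
  a population split into two identical copies the between mean includes
  each sequence paired with its own copy, so between = within·(n−1)/n
  exactly, not within.
- **AMOVA/PhiPT** partitions *squared* difference counts (not per-site
  rates): one-level design, unbalanced group sizes handled through the
  n0 coefficient. A negative among-population component is truncated to
  zero for PhiPT and percentage reporting; the raw component is retained in
  the result for transparency. The permutation test permutes individual
  labels among populations with group sizes fixed and uses the
  add-one-to-both rule p = (1 + #{Φ_perm ≥ Φ_obs})/(1 + n_perm); comparisons
  use the truncated statistic, which coincides with the raw comparison
  whenever the observed PhiPT is positive and is conservative (p = 1)
  otherwise. Measured type-I error at α = 0.05 on panmictic splits is
  ≈ 0.04–0.05. Pairwise PhiPT analyses each population pair independently
  on its sub-matrix, with independent child seeds per pair so results do not
  depend on traversal order. Default 999 permutations.
- **PCoA** is classical metric scaling: eigendecomposition of the Gower
  double-centered −½d² matrix, coordinates scaled by √λ for positive
  eigenvalues. Count distances are near-Euclidean, so no Cailliez/Lingoes
  correction is applied; negative eigenvalues are reported untouched because
  corrections change variance percentages opaquely. Axis signs are fixed by
  forcing the largest-magnitude coordinate positive, making plots
  reproducible across BLAS builds. An all-zero distance matrix yields
  all-zero coordinates with a warning, not an error.
- **Sharing statistics.** An individual shares when its haplotype occurs
  ≥ 2 times in the reference set. For temporal profiles the reference set is
  the *whole site sample* and only membership is grouped by collection trip
  (monthly binning available), so a family split across trips still counts.
- **Contribution estimate** = max(0, sharing%_stocked − background), with
  background the mean of the reference-site sharing percentages (min/max
  aggregations available; the mean is symmetric and stable). The estimate is
  flagged as an upper bound: identical-by-state background sharing inflates
  it, while hatchery families represented by a single sampled individual are
  invisible, biasing it low — the parameter-recovery tests quantify both
  effects against the generator's counting law.
- **Count comparisons across sites** (haplotype, private-allele and
  polymorphic-locus counts) use chi-square goodness-of-fit against equal
  expectations; mean alleles per site uses one-way ANOVA over per-column
  allele counts. Pairwise comparisons are Bonferroni-corrected (the only
  multiple-comparison procedure offered) and summarized as compact-letter
  displays via insert-and-absorb.
- **Stocking epoch** is derived per sample with a strict `<` comparison of
  collection date against the site's first non-zero release date; reference
  sites are always "pre" so their full time series strengthens the
  pre-stocking structure analysis. IUPAC ambiguity codes other than N are
  collapsed to N with a logged warning (ambiguities are resolved upstream
  during consensus calling; downstream statistics need one missing symbol).

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
not sequence evolution:

- **Wild pool.** A random ancestral sequence with a designated fraction of
  polymorphic columns (default 294/716 ≈ 0.41). Each variable column gets a
  major allele plus one minor (or three equifrequent minors when the
  per-column target heterozygosity exceeds ½, feasible up to ¾), with minor
  frequency solving 2q(1−q) = π·L/P — so the expected mean pairwise per-site
  divergence equals the target π (default 0.023) *by construction*. The pool
  holds `wild_pool_size` (default 12 000) distinct haplotypes; sampling wild
  individuals uniformly with replacement from a finite pool produces the
  reference-site background sharing (~1–2% at n ≈ 170) without inventing a
  pedigree. Configurations where the per-column heterozygosity would exceed
  0.75, or where the pool collision rate exceeds the background target, are
  rejected as infeasible.
- **Hatchery families.** `n_dams` (default 46) distinct wild haplotypes are
  set aside as dams; each stocked site's releases stem from `n_families`
  (default 9) of them with lognormal(σ = 1) fecundity weights; offspring
  inherit the dam haplotype exactly. Dams are removed from the wild sampling
  pool — they are physically in the hatchery — which makes broodstock
  matches at reference sites exactly zero rather than rare pool collisions.
- **Estuary time series.** Each collection trip draws each individual from
  the hatchery families with the cohort's true fraction m, otherwise from
  the wild pool. The default scenario mirrors a two-season release program:
  two reference estuaries (168/170 samples), an ocean-open stocked estuary
  (234 samples, m = 0.08 in post-release cohorts), and a closed lagoon
  (253 samples) with m = 1 before it re-opens to the sea and m halving per
  trip afterwards (the dilution schedule after re-opening is a free
  parameter — no empirical schedule exists), plus 46 broodstock. Totals
  match the monitoring design (871 samples of 716 bp).
- The default assumes a *fully genotyped* broodstock
  (`n_broodstock_sampled = n_dams`), so stocked-site broodstock-match rates
  equal the hatchery fraction; field programs with incomplete broodstock
  records see far lower match rates, which can be emulated by lowering
  `n_broodstock_sampled`.
- Identical config + seed ⇒ byte-identical FASTA/CSV outputs (a single
  `numpy` PCG64 stream drives everything in a fixed order).

**What passing tests show — and don't.** The generator has no recombination,
no per-column rate heterogeneity beyond the two/four-allele scheme, no
alignment error, gaps or missing data (those paths are tested with
hand-built inputs), and background sharing arises purely from finite-pool
collisions rather than shallow coancestry. Recovery of known mixture
fractions on these data validates the estimators' arithmetic and
calibration, not robustness to real-data artifacts such as mis-scored
ambiguities or undetected alignment slips.

## Problem sizes used in tests and the acceptance script

Oracle agreement runs on ≥ 100 random instances with N ≤ 12 against plain
pair-enumeration reimplementations. Type-I-error calibration uses 250
panmictic splits (2 × 15 samples, 199 permutations). Parameter recovery uses
mixtures at m ∈ {0, 0.05, 0.2, 0.8} with 250 stocked samples over three
replicate seeds. The acceptance script runs the full 871-sample default
scenario with 999 permutations; the complete suite finishes in well under a
minute on one core.

## Known limitations

- PhiPT is a haploid distance-based F_ST analogue; no allele-frequency F_ST,
  no hierarchical (region/population) AMOVA.
- No likelihood-based sibship reconstruction (COLONY-style); kinship groups
  are exact-identity clusters and inherit the background false-merge rate.
- No model-corrected distances (K2P/GTR) and no maximum-likelihood
  phylogenetics: tree building is delegated to external tools, the package
  only exports alignments.
- Polymorphic-site counts depend on the missing-data convention; with
  sporadic Ns the pairwise-deletion convention can shift counts by a few
  sites relative to complete-deletion software defaults.
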