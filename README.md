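# haplostock

Population-genetic assessment of aquaculture-based stock enhancement using a
hypervariable, maternally inherited marker — the mitochondrial control region
(mtCR).

Stock-enhancement programs release hatchery-reared juveniles (here, penaeid
prawns) into estuaries and need two genetic answers:

1. **Is the wild population structured?** If the recipient estuaries hold a
   single panmictic stock, stocking from a distant source does not disturb
   local genetic structure. This is tested with haplotype/nucleotide
   diversity, distance-based AMOVA with the PhiPT statistic, pairwise PhiPT
   permutation tests, and principal coordinate analysis (PCoA).
2. **Did released animals survive in the wild?** Hatchery cohorts descend
   from few dams, so released animals arrive in large maternal families.
   Because nearly every wild individual carries a unique mtCR haplotype,
   *haplotype sharing within a site is a proxy for maternal sibship*: excess
   sharing at stocked sites over the background measured at unstocked
   reference estuaries — plus exact haplotype matches to sampled hatchery
   broodstock — is the stocking signal, and the background-corrected sharing
   percentage is an upper bound on the hatchery contribution.

`haplostock` implements both branches as a library + CLI, together with a
seeded synthetic-data generator (wild pool with calibrated diversity,
skewed maternal families, mixed estuary time series) so the whole pipeline is
testable end to end without any sequence download.

## Statistics

For a sample of `n` haploid sequences collapsed into haplotypes with
frequencies `p_i`:

- haplotype (gene) diversity, unbiased: `h = n/(n−1) · (1 − Σ p_i²)`
- nucleotide diversity: `π = mean over pairs of d_ij / L_ij`, where `d_ij`
  counts differing sites and `L_ij` the mutually non-missing sites
  (pairwise deletion of gaps/N)
- one-level AMOVA on squared distances: `SS_total = Σ_{i<j} d²_ij / N`,
  `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`, variance components via mean
  squares with the unbalanced-design coefficient
  `n0 = (N − Σ n_g²/N)/(k−1)`, and
  `PhiPT = max(0, σ²_a / (σ²_a + σ²_w))`, tested by permuting individuals
  among populations (`p = (1 + #{Phi_perm ≥ Phi_obs}) / (1 + n_perm)`)
- PCoA: eigendecomposition of the Gower double-centered `−½ d²` matrix;
  negative eigenvalues are reported, not corrected
- sharing: an individual "shares" when ≥ 2 individuals at its site carry the
  identical haplotype; corrected contribution =
  `max(0, sharing%_stocked − mean sharing%_reference)` (an upper bound).

## Worked example

Simulate the default four-estuary study design (two reference estuaries, an
ocean-open stocked estuary, a closed stocked lagoon, 46 hatchery broodstock;
871 samples of 716 bp) and analyze it:

```bash
python -c "
import haplostock as hs
hs.simulate_estuary_timeseries(hs.default_scenario(seed=1)).write('demo')"
haplostock analyze --fasta demo/alignment.fasta --metadata demo/metadata.csv \
    --calendar demo/release_calendar.csv -o demo_report --seed 1 --n-perm 999
cat demo_report/summary.txt
```

prints

```
Pre-stocking diversity (pooled per site):
  Corunna: n=170, 170 haplotypes, h=1.000, pi=2.23%, 292 polymorphic sites
  Durras: n=168, 167 haplotypes, h=1.000, pi=2.25%, 289 polymorphic sites
  Hatchery: n=46, 46 haplotypes, h=1.000, pi=2.40%, 222 polymorphic sites
  Tabourie: n=50, 49 haplotypes, h=0.999, pi=2.20%, 216 polymorphic sites

AMOVA: PhiPT=0.002 (p=0.068, 999 permutations); 0.2% of variance among populations

Haplotype sharing within sites:
  Corunna: 0/170 sharing (0.0%), 0 shared groups
  Durras: 2/168 sharing (1.2%), 1 shared groups
  Tabourie: 23/234 sharing (9.8%), 10 shared groups
  Wallagoot: 147/253 sharing (58.1%), 9 shared groups

Background-corrected stocking contribution (upper bound):
  Tabourie: raw 9.8% - background 0.6% -> 9.2%
  Wallagoot: raw 58.1% - background 0.6% -> 57.5%
```

Reading: the pre-stocking populations are effectively panmictic (nearly every
animal has a unique haplotype, PhiPT ≈ 0, non-significant), while the two
stocked sites — and only they — show excess haplotype sharing. The closed
lagoon ("Wallagoot") shows the strongest signal: its 9 shared groups are the
9 simulated maternal families, and its early post-release cohorts are ~100%
sharing because the lagoon received no natural recruits. The report directory
also contains the pairwise-PhiPT table (PhiPT below the diagonal, permutation
p above), the within/between percent-divergence table, PCoA coordinates and
plots, and a machine-readable stocking dossier (JSON).

The CLI also exposes each stage separately (`simulate`, `diversity`,
`amova`, `sharing`, `pcoa`); the same functionality is available as plain
functions (`haplostock.amova_phipt`, `haplostock.temporal_sharing_profile`,
…).

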