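# Methods

This note records the models, conventions and numerical choices behind
`chlamypop`, in the spirit of a simulator/estimator package's model
documentation. Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Panel model and estimators

The data model is a panel of `n` haploid strains typed at biallelic
SNPs, with a per-site missing sentinel and a *callable mask*: the set
of positions sequenced in every strain, which is the denominator `L`
of every per-base quantity. "Strict mode" (the default everywhere)
restricts statistics to sites called in all strains, mirroring
analyses that keep only fully-sequenced sites; a pairwise-complete
mode for θ_π (per-pair difference counts over per-pair shared lengths)
is available where panels are gappier.

- θ_W = S/(a_n L), a_n = Σ_{i=1}^{n−1} 1/i. With L = 0 the value is
  NaN ("undefined"), never 0.
- θ_π: per site with j alternate alleles, the mean pairwise difference
  is j(n−j)/C(n,2); summed over complete sites and divided by L.
- Folded SFS: class i = min(alt, n−alt), i = 1..⌊n/2⌋. The neutral
  expectation folds the 1/i spectrum:
  E[η_i] ∝ (1/i + 1/(n−i))/(1 + δ_{i,n−i}), normalised to the observed
  S. The chi-square against it pools classes from the high-frequency
  end until every pooled expectation reaches 5, then conditions on the
  total. This reference distribution assumes (quasi-)independent
  sites; under strong linkage the statistic is anti-conservative, which
  is why the calibration test uses panels of many short, unlinked loci
  (see "What the generator does and does not emulate").
- Site classes: every position gets exactly one primary label with
  precedence CDS > UTR > intron > intergenic (painted in ascending
  precedence so the strongest label wins at overlaps). Codon identity
  at overlapping CDSs is taken from the first gene by coordinate, then
  id. Codons are extracted strand-aware by concatenating CDS blocks in
  coding order, so codons split across introns are handled; a CDS
  whose length is not a multiple of 3 gets a warning and no codon
  subclassing. A position is fourfold-degenerate when all four bases
  at its codon offset encode the same amino acid (standard code).
- Distances: fraction of jointly-called SNPs at which two strains
  differ. Neighbor joining is the standard Saitou–Nei agglomeration;
  Q-matrix ties break to the lexicographically smallest index pair and
  negative branch lengths clamp to zero with a warning, so the tree is
  a deterministic function of the distance matrix up to row order.
- PCA: per-site mean-centred (optionally variance-scaled) 0/1 calls,
  SVD, scores ordered by variance; each component's sign is fixed so
  its largest-magnitude score is positive.
- r²: since calls are 0/1, D²/(p_A q_A p_B q_B) equals the squared
  Pearson correlation of the two call vectors, which is how the
  all-pairs grid is computed. Monomorphic slices are an error
  ("undefined"), not 0. "Linked" means same chromosome throughout.
- ρ per chromosome is fit to the binned decay curve by pair-count-
  weighted least squares of E[r²](d) = a/(1 + ρd) + 1/n over ρ ≥ 0,
  with the amplitude `a` profiled out in closed form at each candidate
  ρ (33-point log grid, then bounded refinement). The textbook version
  of this moment model fixes a = 1, but in coalescent samples the
  near-zero-distance expectation of r² sits well below 1 and varies
  genealogy to genealogy; the free amplitude absorbs that baseline and
  leaves ρ identified by the decay *shape*, which is what makes the
  estimator rank-accurate across two orders of magnitude (the
  recovery test). A curve whose best fit is no better than a constant
  returns the ρ = 0 boundary. The genome-wide ρ is the plain average
  of per-chromosome estimates. ρ is always carried per base and
  additionally reported per Mb, the scale on which a genome-wide value
  like 218 combines with r = 10⁻⁷ Morgans/base to give
  N_e = ρ/(2r) ≈ 1.1×10³ outcrossing generations.
- Marey map: 4-parameter logistic cM(x) = A + (B−A)/(1+e^{−k(x−m)})
  with B ≥ A and k ≥ 0 enforced through the parameterisation
  (A, B−A ≥ 0, m, k ≥ 0), so the fitted map never decreases; at least
  five markers are required. The local recombination rate is the
  analytic derivative, reported in cM/kb.

## The synthetic-data generator

The generator is a direct Hudson-style coalescent with recombination
for haploid samples, written in-package (an established simulator is
used only as an independent oracle in the tests). Lineages carry their
ancestral genome segments with the bitmask of descendant samples;
waiting times are exponential in the usual rates (pairwise coalescence
1, per-lineage recombination ρ/2 per breakable base, mutation θ/2 per
ancestral base with θ = 2N_e μ, time in units of N generations), and
segments that reach their local MRCA are dropped so mutations map
directly to carrier sets. Infinite-sites mutations arrive on a
continuous coordinate and are snapped to distinct integers (collisions
push right, or left at the chromosome end), preserving order and pair
distances to under a base. Two subpopulations coalesce only within
their group until `split_depth` (coalescent units), then merge.

Defaults describe the study conditions the package targets:

| parameter | default | why |
|---|---|---|
| `n_per_group` | 6 | two groups of six ≈ a 12-isolate panel |
| `theta_per_base` | 0.002 | species-wide diversity of ~2 SNPs/kb |
| `rho_per_base` | 2.18×10⁻⁴ | per-Mb reading of a genome-wide ρ ≈ 218 |
| `split_depth` | 0.35 | gives a fixed-difference fraction of order 1% while the groups remain cleanly recoverable |
| `chromosome_lengths` | 17 × 100 kb | desk-scale stand-in for a ~120 Mb, 17-chromosome genome |
| intergenic fraction | 0.20 (chr15: 0.48) | typical chromosomes ~12–28% intergenic, one intergenic-rich outlier |
| `intergenic_diversity_scale` | 0.5 | intergenic θ_W roughly half the genome-wide value |
| `ambiguous_tract_rate` | 0.15 | N-tracts inside intergenic runs; intergenic-rich chromosomes become reference-poor |
| `missing_rate` | 0.02 | small per-call dropout, as in low-coverage panels |

Gene models are deterministic repeating cassettes (5′ UTR, three CDS
exons with codons split across two introns, 3′ UTR, intergenic spacer,
alternating strand) sized to the per-chromosome class fractions; the
reference is random sequence with N-tracts centred in intergenic runs.
Strain metadata plants a latitude cline: Group II strains sit ~9°
south of Group I with 1° Gaussian noise, a monotone link that any
group-separating axis of variation will pick up.

**What the generator emulates** — the statistical structure the
estimators consume: two diverged groups, class-dependent diversity,
reference incompleteness collocated with intergenic DNA, missingness,
recombination with the right rate parameterisation. **What it does
not** — read-level error, alignment artefacts, gene-density variation
beyond the periodic cassette, realistic chromosome lengths, or
selection; and because the cassette layout is periodic, intergenic
fraction varies mostly *between* chromosomes, so window-level
correlations between intergenic content and diversity are much weaker
than in real annotation. Passing tests therefore certify estimator
correctness and parameter recovery under the stated model, not
robustness to upstream bioinformatic artefacts.

## Numerical and design choices

- Coordinates: 1-based inclusive at VCF/GFF interfaces, half-open
  0-based internally; windows tile from position 1 and the last
  partial window keeps its true length as denominator.
- The SNP quality filter is strictly greater than the threshold
  (default 30); records with indel alleles are counted and set aside;
  multi-allelic SNPs are dropped from the biallelic matrix.
  Heterozygous genotypes in a nominally haploid panel are an error;
  homozygous-diploid coding (0/0, 1/1) is accepted.
- Near-duplicate strains: every pair closer than the threshold
  (default 0.01, motivated by reference-derived strain pairs being
  "nearly identical") marks its later-sorting member for exclusion, so
  chains keep exactly their first-sorting strain.
- The windowed moving average is a trailing mean over up to 10 windows
  of the same chromosome.
- Chromosome-contrast ANOVA: window θ_W, one chromosome vs the rest,
  F with df (1, N−2); zero within-group variance with unequal means is
  reported as F = ∞.
- Chi-square pooling rule and the conditioning on totals are as above;
  Spearman uses average ranks and flags constant inputs as undefined.
- Determinism: every stochastic step flows from one
  `numpy.random.Generator` seeded by the config; identical seeds give
  byte-identical emitted files and pipeline tables.
- Problem sizes in the test suite (200 × 1 Mb panels for θ recovery,
  a 10-point ρ grid × 50 replicates of 3 × 150 kb panels, 1 200 × 80 b
  unlinked loci for SFS calibration, 20 default panels for structure
  recovery) were chosen as the smallest scales at which the respective
  Monte-Carlo error bands are informative.

## Known limitations

- The ρ estimator is rank-accurate but biased in absolute terms (its
  moment model is an approximation); absolute calibration would need a
  likelihood-based machinery that is deliberately out of scope.
- θ_π's pairwise-complete mode treats invariant sites as co-called for
  both strains except at SNP columns, which is exact only when
  invariant-site missingness is independent of pair identity.
- The four-gamete count assumes infinite sites; on real data recurrent
  mutation inflates it.
- The NJ tree is a point estimate; no bootstrap support is computed.
- STRUCTURE-style admixture inference and likelihood-based ρ (e.g.
  pairwise/composite likelihood) are intentionally not implemented;
  group labels come from metadata or tree clades.
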