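# Methods

This note documents the models, conventions and design decisions behind
each stage, what the synthetic generator does and does not emulate, and the
numerical choices that affect results.

## Genotype model and conventions

Genotypes are stored as 0/1/2 copies of a per-locus B allele (−1 missing).
The B allele is the minor allele observed at load time; nucleotide labels
are retained so reports can print genotypes like "AG". Positions are
1-based base pairs (PLINK MAP convention) and segment intervals are closed
`[start, end]`. Missing calls are never imputed by the core container;
stages that need complete data state their handling (PCA and LD pruning
mean-impute per locus for the computation only; IBS and kinship work on
pairwise-complete loci).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the biology that produces it:

* **Drift structure.** Breed allele frequencies are drawn from the
  Balding–Nichols beta distribution around a shared ancestral frequency
  p₀ ~ U(0.1, 0.9): `p_b ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)`, so that
  E[p_b] = p₀ and Var(p_b) = F·p₀(1−p₀). F defaults to 0.07, the order of
  the genome-wide differentiation reported among Italian goat breeds, and
  may be set per breed (e.g. to create a long-isolated outlier breed).
* **Adaptive clines.** A subset of SNPs has breed frequencies
  `clamp(α + β·env_b, 0.02, 0.98)` with α centring the cline at 0.5. The
  default adaptive fraction is 15/3015 ≈ 0.5%, the order of the
  significant-SNP fraction in real array panels, and β = 0.3 per
  standardized environment unit, chosen for roughly 80% nominal power of
  the per-genotype tests on a ~500-animal panel. Both matter beyond power:
  if adaptive SNPs are made a few percent of the panel, their shared breed
  pattern dominates the leading principal component and the structure
  correction itself absorbs the signal.
* **Genotypes and phase.** Within breeds, haplotype alleles are i.i.d.
  Bernoulli(p_b), so genotypes are exactly Hardy–Weinberg and the data are
  emitted phased. There is no linkage disequilibrium beyond what drift
  induces, no selection through time, and no coalescent realism —
  passing tests on these data validate the statistical machinery, not
  robustness to LD, phasing error, or ascertainment bias of real arrays.
* **Environment.** Default is a single standardized north–south gradient
  (linspace 1 → −1 over breeds) whose future value is shifted by −0.15,
  mimicking the sign and order of projected 2070 bioclimatic deltas.
* **Planted IBD.** Each plan entry copies one donor haplotype segment
  verbatim onto haplotype 1 of the first *k* members of both breeds, so
  every carrier cross-pair is identical over the segment; the number of
  marker slots is chosen so the physical span equals the requested length
  exactly. The truth record lists every carrier cross-pair.

## QC cascade

Order is fixed: marker call-rate/MAF filters, then sample call rate, then
duplicates (IBS > 0.99) and relatives, then per-dataset steps (LD pruning
and subsampling for the structure dataset; kinship and georeference filters
for the landscape dataset). Every removal is written to a report with
stage, reason and statistic, and the per-stage size log mirrors the
dataset-accounting table such surveys publish.

Decisions where the convention was open:

* **Relatedness without pedigrees** is screened by the opposing-homozygote
  count (the computable analogue of a Mendelian-error count between
  putative close relatives). The default threshold of 100 discordant
  homozygotes presumes an array-scale panel (~50k markers); on small
  simulated panels it must be scaled down accordingly.
* Pairs flagged as duplicate/related are pruned by removing the animal
  occurring in multiple flagged pairs, else the member with higher
  missingness (sample-id order breaks exact ties, for determinism).
* **LD pruning** uses the indep-pairwise convention: window 50 SNPs, step
  5, removing the later SNP in map order of any pair with r² > 0.2.
* **Kinship** uses the method-of-moments IBS decomposition (per-locus
  expected IBS-state probabilities under IBD 0/1/2, solved sequentially),
  without small-sample bias-correction terms; π̂ = P(IBD1)/2 + P(IBD2),
  greedy removal above 0.25 (the second-degree midpoint convention).
* **Representative subsampling** keeps, per oversized breed, a seeded
  farthest-point traversal of the within-breed 1−IBS matrix — a
  deterministic way to preserve within-breed spread; expected
  heterozygosity of the kept subset stays within a few percent of the full
  breed on simulated data.

## Population structure

IBS distance is `1 − shared alleles / (2 × jointly called loci)`, pairwise
complete. Classical MDS double-centers −D²/2 and eigendecomposes; negative
eigenvalues (non-Euclidean part) are excluded from variance proportions,
and requesting more axes than positive eigenvalues truncates with a
warning.

Reynolds distance is reported as the co-ancestry coefficient θ itself;
`sqrt(θ)` and `−ln(1−θ)` variants are selectable since distance-based tree
software differs in which form it consumes. Trees are Saitou–Nei NJ;
bootstrap resamples loci with individuals fixed (the standard choice for
SNP trees); the majority-rule consensus is built from our own bipartition
counts with mean branch lengths over the replicates containing each split,
which also makes the output bit-deterministic for a given seed. Supports
are bipartition percentages; rooting on the outgroup is for display only.

## Haplotype sharing

A breed pair's statistic is the median over all inter-breed individual
pairs of the per-pair total shared length (all four haplotype pairings
summed), with non-sharing pairs contributing 0 and the midpoint convention
for even counts. Because the median zero-fills, a breed pair where fewer
than half the animal pairs share anything scores 0 — the sparse sharing
pattern seen in real panels arises naturally. An alternative reading
(median of pooled segment lengths) is available via `mode="segment_pool"`;
the per-pair-sum reading is the default. Lengths are reported in Mb at 3
decimals.

The naive detector reports maximal identical-allele runs between haplotype
pairs with physical span ≥ 0.2 Mb by default (the reporting floor used
with HMM-based detectors). On drifted populations a detected run can
extend past a truly-IBD segment by chance matches (per-SNP match
probability p² + q²), so detected segments slightly overestimate planted
lengths at coarse marker spacing; the planted interval itself is always
recovered in full, being a literal copy.

## Genotype–environment association

The per-genotype coding turns each observed genotype of each SNP into a
binary presence response, so a SNP contributes up to three tests.
Genotypes seen in fewer than 5 animals are skipped, as are near-constant
responses (present in more than n−5), which would otherwise invite
separation. Logistic fits use IRLS (max 50 iterations, deviance tolerance
1e−8); non-convergence and quasi-separation (|η| > 30) are flagged but the
result is kept. G = deviance drop, p from χ²₁, and BH correction is
applied over the pooled (genotype × variable) family by default, with a
per-variable option.

Structure correction uses principal components of the standardized,
mean-imputed genotype matrix. The automatic choice keeps the leading run
of eigenvalues above the broken-stick expectation (floored at 2) — an
automated stand-in for reading a scree plot — and is overridable. Two
caveats are inherent to this design and visible in the synthetic
experiments:

* With a breed-constant environmental variable, animals within a breed are
  pseudo-replicates; chance correlations between drifted neutral breed
  frequencies and the variable produce more false positives than the
  nominal FDR suggests (a few percent of neutral SNPs under the default
  conditions). More PCs reduce this at a direct cost in power.
* If a large coherent set of SNPs follows the gradient, the leading PCs
  align with the gradient and absorb the signal.

The environmental-variable panel is reduced before testing by iteratively
removing one of the two most correlated variables (seeded random choice)
until all pairwise r² < 0.7. The threshold applies to r² as is
conventional for "|r²| < 0.7" reduction rules; thresholding |r| instead is
available via `on="r"`. A map from each removed variable to its retained
proxy is returned. Grids use the ESRI ASCII dialect; point extraction is
nearest-cell with no interpolation, and terrain slope uses Horn's
eight-neighbour gradient in degrees (border cells absent), with the cell's
physical edge length supplied separately when grids are in geographic
units.

## Climate projection

Breeds are grouped by the Köppen–Geiger class of their rearing area. The
humidity rule maps dry-summer/steppe classes {Csa, Csb, BSk (and BSh)} to
DRY and no-dry-season classes {Cfa, Cfb, Dfb, Dfc, EF} to NOTDRY. The
temperature rule maps hot-summer classes {Csa, Cfa} to HOT. The bundled
reference classification for 32 Italian breeds is internally consistent
with this map; note that published methods texts sometimes state the HOT
rule as {Csa, Dfa} while their own breed table marks Cfa breeds as hot and
contains no Dfa class — the map here follows the table and is fully
configurable rather than silently resolved.

Per candidate SNP (an association hit), a one-way ANOVA on per-breed MAF
(or oriented frequency, selectable — the screening scale is genuinely
ambiguous in the field) between the two groups screens group-differentiated
SNPs at p < 0.05; a single pooled OLS across all breeds of the focal-allele
frequency on the associated variable's current value gives one regressor b
(one b serves both groups, matching how the published worked example
applies the same slope to each); SNPs with slope p ≥ 0.05 are dropped. The
focal allele is the allele composing the flagged genotype (the B allele
for heterozygote associations). Each group's projection is
`p_future = clamp(p_current + b·Δ, 0, 1)` with Δ = future − current group
mean of the variable — the sign convention that reproduces the published
worked example exactly — and genotype triples follow from Hardy–Weinberg.

This is deliberately a first-order extrapolation of a fitted
frequency–environment cline: no drift, migration, selection dynamics or
generation structure. Clamping at the [0, 1] boundary is flagged on the
record. Exact arithmetic on printed 4-decimal inputs can differ from
published truncated values by one unit in the last digit (e.g. 0.58025
printed as 0.5802); comparisons in the tests allow exactly that one-ulp
slack and no more.

## Pipeline and reproducibility

Stages exchange plain TSV/Newick/PHYLIP files; every numeric output
carries a provenance header (stage, parameters, seed) and the run manifest
records per-stage dataset sizes and SHA-256 checksums, so a rerun with the
same config and seed is verifiably identical. The projection stage refuses
to run without association output. Problem sizes used in the test suite
(hundreds of animals, a few thousand markers) are scaled-down versions of
the array-panel design the defaults describe; the statistical structure,
not the panel size, is what the assertions exercise.

## Known limitations

* The association engine tests one variable at a time against one genotype
  presence; it is not a multivariate or mixed-model method, and inherits
  the pseudo-replication caveat above on breed-constant variables.
* The naive IBD detector is exact-match only — appropriate for synthetic
  phased data, not for real data with genotyping error (use an HMM-based
  detector upstream and ingest its segments).
* Kinship estimates omit finite-sample corrections; with very small panels
  the π̂ scale is biased and the second-degree cut should be revisited.
* The projection model treats breed groups as panmictic units with
  instantaneous frequency response; its outputs rank direction and
  relative magnitude of change, not absolute future frequencies.
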