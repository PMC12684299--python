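# Methods

`islepop` re-creates, at desk scale, the comparative-genomic workflow used
to contrast small, isolated island populations with their large mainland
counterparts: genotype-quality masking, outgroup-based allele
polarisation, calibrated runs-of-homozygosity (ROH) inbreeding metrics,
genetic-load quantification through the relative abundance of derived
alleles, and scans for differentially fixed coding variants.  A forward
Wright–Fisher simulator generates the study design synthetically, so every
stage can be validated against known truth without external data.

## The simulator

**Model.** Discrete, non-overlapping generations; a monoecious diploid
Wright–Fisher population with fitness-weighted parent sampling (selfing
excluded; two distinct parents per offspring).  Per-site genotype fitness
is 1, 1−hs, 1−s for ancestral-homozygote, heterozygote and
derived-homozygote, multiplicative across sites.  Recombination follows
the Haldane model at marker positions: crossover probability between
adjacent variant sites is `r · d` Morgans (`r` in cM/Mb converted to
Morgans/bp; `d` the inter-site distance), chromosomes assort
independently.  Mutation is infinite-sites — each new mutation occupies a
never-used genome coordinate, so the founder allele at every site is
unambiguous and serves as the true ancestral allele.

**Demography.** A single mainland population of `n_mainland` diploids
runs for a burn-in of `total_generations − split_generation` generations;
then `n_island` individuals are copied to found an isolated island
population (no migration afterwards) and both populations evolve to the
present.  The reference scenario uses 500 mainland / 50 island diploids
and a 200-generation split — an intentionally severe, but uncalibrated,
bottleneck: the real populations' demographic parameters are not
published, so all comparisons made with the simulator are qualitative
(directions and orderings), never numeric matches to field data.

**Standing variation.** Running a 500-diploid population to mutation–drift
equilibrium takes tens of thousands of generations; instead, generation
zero is seeded from each class's stationary site-frequency spectrum as a
Poisson random field: allele-count intensities are the neutral `θ/i`
spectrum weighted by Wright's stationary density `w̄(q)^{2N}` with
`w̄(q) = 1 − 2hs·q(1−q) − s·q²`.  For a neutral class this is exactly the
`1/i` spectrum (expected site count `θ·H_{2N−1}`); for a strongly
recessive class it confines standing variation to low frequencies — the
masked-load regime a forward run would equilibrate to, in which
deleterious alleles hide in mainland heterozygotes until island
inbreeding exposes them.  Seeding a selected class from the *neutral*
spectrum instead hands both populations common recessive variants whose
continued purging in the large mainland (through p² homozygote exposure)
swamps the island–mainland purging contrast; that regime is avoided by
design.  Seeding intensity is proportional to μ, so `μ = 0` still yields
a monomorphic founder population, and a short forward burn-in (50
generations by default) precedes the split.

**Pedigree truth.** Kinship is propagated forward exactly
(`K'_{ij} = ¼(K_{f_i f_j}+K_{f_i m_j}+K_{m_i f_j}+K_{m_i m_j})`, diagonal
`½(1+F_i)`), giving every sampled individual's realised pedigree
inbreeding relative to the generation-zero founders.  In the reference
scenario this reproduces the classical expectation
`F ≈ 1−(1−1/2N)^t` in both populations.

**Mutation classes and the toy annotator.** Each site is assigned one of
four classes — synonymous, tolerated missense, deleterious missense,
loss-of-function (LoF) — with fractions 0.40 / 0.25 / 0.20 / 0.15.  These
fractions emulate an exome-like panel enriched for functional classes
(genome-wide LoF fractions of ~1–2% would leave too few LoF sites for
stable per-category statistics at a 20 Mb genome).  Classes map to
VEP-style consequence strings (`synonymous_variant`, `missense_variant`,
and a LoF string drawn from the stop/start/frameshift/splice set), and
missense sites receive an amino-acid exchangeability (EX) score drawn
uniformly from (0.01, 0.256] for the deleterious class and [0.30, 0.95]
for the tolerated class, clear of the classification boundary.  EX scores
are consumed from the annotation table throughout; the package does not
ship or recompute an exchangeability matrix.  Genes are modelled as
contiguous 50 kb tiles — adequate for gene-level set operations, with no
pretence of realistic gene structure.

**Sequencing noise.** Truth genotypes stay clean inside the simulator.
At VCF emission, each genotype receives a Poisson(`mean_depth`, default
30×) read depth; heterozygotes split reads Binomial(DP, 0.5) between
alleles, homozygotes put all reads on their allele, so AD always sums to
DP.  A fraction of sites (default 0.1) place the *derived* allele on the
reference genome, so polarisation is genuinely exercised rather than
trivially reading the REF column.  Outgroup tables carry three genotype
columns, by default all homozygous for the true ancestral allele;
configurable fractions of sites are made discordant (one outgroup
homozygous derived) or heterozygous to exercise the polarisation filter.

**What the simulator does not emulate.** Genotype-calling errors (the
noise model perturbs depth fields, never calls), mapping artefacts and
repeat regions, linked-selection background effects, gene conversion,
migration after the split, overlapping generations, and realistic genome
architecture.  Tests passing on simulated data therefore validate the
*implementations* and the drift/selection logic, not robustness to the
full error structure of real resequencing data.

## Masking

* **Allelic balance** — a heterozygote whose minor-allele read fraction
  `min(AD)/DP` is strictly below 0.25 becomes missing.  Homozygotes are
  never touched.
* **Depth** — any called genotype with depth strictly below 0.5× or
  strictly above 2× the sample's genome-wide mean depth becomes missing.
  The mean is computed from the raw depth field over *sequenced*
  genotypes (DP > 0).  Because both masks read only the immutable
  depth/AD fields, they are idempotent and commute — the masking order
  cannot change the result (property-tested).

Boundary values (exactly 0.25, exactly 0.5×/2×) are retained in all
rules.  Masking only ever converts calls to missing; it never alters a
genotype's value, and site/sample dimensions are preserved.

## Polarisation

A site is retained iff all three outgroups are genotyped, homozygous,
mutually identical, and their shared allele equals the site's REF or ALT;
that allele is ancestral and the other is derived.  Genotypes are recoded
to derived-allele counts (flipped where the reference carries the derived
allele).  Sites with no derived allele observed in the ingroup are then
removed; sites *fixed* for the derived allele are kept — they are
variable relative to the ancestor, enter the species-wide site counts,
and carry realised load.  On simulated data with concordant outgroups
this recovers the true ancestral allele at 100% of retained sites.

## ROH detection and F_ROH

The window caller follows the PLINK 1.9 `--homozyg` dialect: a scanning
window of `window_snps` consecutive SNPs is a *hit* if it contains at
most `window_het_allowance` (default 1) heterozygous and at most
`window_missing_allowance` (default 5) missing calls; a SNP is
ROH-eligible when its fraction of hit windows strictly exceeds
`window_hit_threshold` (default 0.05; ties are non-eligible); maximal
runs of eligible SNPs are split at inter-SNP gaps above `max_gap_kb`
(default 1000) and reported if they satisfy the SNP-count
(`min_snps`), length (`min_length_kb`) and density
(`max_density_kb_per_snp`, default 50) thresholds.  Windows are only
formed where `window_snps` SNPs exist, so chromosome-edge SNPs belong to
fewer windows.  The implementation is exactly equivalent to a literal
brute-force enumeration of these rules (property-tested on random
instances up to 1000 SNPs).

Two deliberate parameter choices differ from raw PLINK defaults:

* `min_snps` is calibrated per dataset as
  `L = ⌈ln(α/(n_s·n_i)) / ln(1−het)⌉` with α = 0.05 — the run length at
  which an all-homozygous stretch arising by chance (given mean
  heterozygosity `het`, over `n_s` SNPs and `n_i` individuals) has
  family-wise probability below α.  The ceiling is conservative.  The
  scanning window length is set equal to `L`.
* `min_length_kb` defaults to 100 kb rather than PLINK's 1000 kb floor,
  because the age classification below needs sub-megabase ("historical")
  ROH to be detectable at all.  Both are configurable.

`F_ROH = L_ROH / L_ROH,HOM`: the ROH total is normalised by the ROH total
of a *synthetic homozygous* copy of the same genome (every het forced
homozygous, missingness preserved) under identical parameters.  This
denominator is the maximal detectable ROH length given the genome's own
SNP spacing and missingness, absorbing artefacts that a fixed genome-size
denominator would mistake for outbreeding.  By construction
F_ROH ∈ [0, 1] and equals 1 for a fully homozygous genome.

## ROH age classes

The expected coalescent age of a ROH of length `l` Mb under recombination
rate `r` cM/Mb is `g = 100/(2rl)` generations (equivalently
`l = 50/(rg)`).  With the rhesus macaque genome-wide average
`r = 0.448 cM/Mb` and a 110-generation horizon, the boundary length is
50/(0.448·110) ≈ 1.01 Mb, rounded to 1 Mb: segments ≥ 1 Mb are classed
*contemporary* (≈ the last 1200 years at an 11-year generation time) and
shorter segments *historical*.  Classification uses physical length and
the single genome-wide rate only; no per-segment recombination map is
attempted.  Contemporary and historical lengths partition L_ROH exactly.

## Genetic load

Consequence strings are mapped to four categories: LoF (transcript
ablation, stop gained/lost, start lost, frameshift, splice region, splice
donor, splice acceptor — splice *region* is included by design even
though it is an unusually permissive LoF member), deleterious missense
(EX ≤ 0.256, boundary inclusive), tolerated missense (EX > 0.256), and
synonymous; anything else is reported as excluded.  Missense without an
EX score is an error, not a silent default.

Per individual and category:

* `RA = (n_het + 2·n_hom) / (2·n_p)` — the relative abundance of derived
  alleles, where `n_p` counts the category's derived positions across
  *all* genomes of the species, island and mainland pooled.  Missing
  genotypes are excluded from `n_het`/`n_hom` but a site stays in `n_p`
  whenever any genome carries its derived allele.  Under pure drift the
  expected value of RA is conserved through a bottleneck, so
  island–mainland RA differences per category diagnose selection
  (purging depresses the island's LoF RA relative to synonymous).
* derived homozygosity `n_hom / (n_het + n_hom)` — rises as inbreeding
  converts masked into realised load; undefined (reported missing) for an
  individual carrying no derived allele in the category.  This is a
  per-individual statistic; a pooled-population alternative would weight
  individuals by their derived-site counts and is not offered.

Genes fixed homozygous for LoF variants in a population are those with at
least one LoF site where every non-missing genotype is homozygous derived
and at least one individual is genotyped.  Group comparisons use Welch's
unequal-variance t-test, reported as "not testable" (with the reason)
when either group has fewer than three genomes.

## Differentially fixed variants

A coding site is differentially fixed when all non-missing island
genotypes are homozygous for one allele, all non-missing mainland
genotypes homozygous for the other, and both populations have ≥ 1 called
genotype.  Missing genotypes do not disqualify a site (a strict
all-genotyped rule would empty small sample sets; the permissive rule is
the default and the scan is symmetric in the two populations).  Genes
containing *any* LoF variant in the combined dataset are then removed, as
drift in putative pseudogenes produces spurious fixation; the surviving
gene sets can be intersected across species, reporting genes present in
at least two sets and in all sets.

## Numerical and reproducibility choices

One `numpy` PCG64 generator seeded from the configuration drives every
stochastic stage; derived seeds for emission noise are spawned from the
same root.  Identical configurations give byte-identical outputs, and the
pipeline writes a JSON manifest of parameters and SHA-256 output hashes
(the output directory path itself is excluded — location is environment,
not a parameter).  Degenerate inputs fail loudly: all-missing samples in
heterozygosity, unsequenced samples in depth masking, zero `n_p` in RA,
`het ∈ {0, 1}` in the L formula, a zero F_ROH denominator with a nonzero
numerator.  F_ROH returns 0 when both totals are empty.

## Problem sizes

The reference scenario uses a 4 × 5 Mb genome with μ = 1e-8 and
1 cM/Mb, yielding ≈ 1500–2000 emitted SNPs per run — enough for stable
per-category load statistics and multi-hundred-SNP ROH tracks while a
20-seed grid completes in minutes on one CPU.  The seed-grid experiments
(20 seeds each for the drift-only and purging scenarios) and all tests
run the full pipeline, including VCF emission and re-parsing, for every
seed.

## Known limitations

* Demography is illustrative; none of the paper-scale counts (fixed-LoF
  gene counts, genome-wide SNP totals, absolute F_ROH values) are
  reproduced, only directions and invariances.
* The stationary-density weighting used to seed selected classes is the
  diffusion approximation of the equilibrium spectrum, not an exact
  forward equilibrium; it ignores linkage among selected sites.
* The L calibration uses the pooled island + mainland mean
  heterozygosity, which mixes two very different diversity levels; the
  per-species pooling mirrors the analysis design but makes L sensitive
  to the island/mainland sampling ratio.
* Gene tiles, single-consequence annotations and uniform EX scores are
  placeholders for real VEP output; the interfaces accept real tables
  unchanged.
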