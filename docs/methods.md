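# Methods

`migrascan` implements a replicated resident–migrant selection-scan
pipeline for structured populations: Hudson F_ST outlier scans with
control-comparison exclusion, a PCA-based per-SNP selection statistic,
cross-population extended haplotype homozygosity (XP-EHH), gene-proximity
annotation, and SNP-level versus gene-level parallelism classification —
together with a structured-population simulator that makes every stage
verifiable at desk scale with known ground truth.

## Study design model

The analysis contrasts resident (year-round) and migratory populations of
one species whose eastern and western clades diverged independently, so
the same phenotypic contrast can be replicated across evolutionary
lineages. Three **case** comparisons pair a resident unit against its
clade's pooled migrants (two single-resident cases in the west, one
pooled two-population resident case in the east). **Control** comparisons
— migrant vs. migrant and resident vs. resident within a clade — capture
differentiation caused by demography rather than migratory phenotype;
any case outlier overlapping a control outlier is discarded.

## Simulator

### Allele frequencies: hierarchical Balding–Nichols

Ancestral frequencies are uniform on `ancestral_maf_range` (default
0.05–0.5). A clade frequency is drawn from a Beta distribution with mean
p and variance `F_clade·p(1−p)`; each population's frequency drifts
likewise around its clade frequency with `F_pop`. F = 0 short-circuits to
an exact copy. Beta draws are clipped to [1e−6, 1−1e−6] so sites stay
polymorphic at the ancestral level; sites may still fix by sampling and
are handled downstream (monomorphic sites are excluded from statistics
that are undefined on them). The closed-form consequence — expected
Hudson F_ST between two populations with independent drift F equals F —
is what the recovery checks exploit. An explicit coalescent would be more
realistic but has no closed-form acceptance surface at this runtime.

### Haplotypes: founder mosaics

Per population, `n_founders` (default 24) founder haplotypes are drawn
site-wise Bernoulli at the population frequency. Each sampled haplotype
copies one founder and switches to a uniformly chosen founder with
probability `recomb_switch_prob` (default 0.01) between adjacent sites,
giving linkage that decays with distance — sufficient for EHH statistics
without a genetic map. Two consequences worth knowing:

- sampled alleles at a site are exchangeable but correlated (two
  haplotypes share a founder with probability 1/n_founders), so realized
  differentiation between populations slightly exceeds `F_pop`. Statistics
  that only need allele frequencies can use the linkage-free sampler
  `simulate_genotypes` (iid Binomial(2, p) dosages), which matches the
  drift parameters exactly; the drift-recovery checks do.
- there is no mutation or gene conversion; all variation is standing.

### Sweeps: instantaneous haplotype replacement

A hard sweep is modelled as its end state: one randomly chosen donor
haplotype is copied over `sweep_carrier_fraction` (default 0.9) of the
target population's haplotypes at every site within `sweep_radius_bp`
(default 30 kb) of the sweep core, producing a long shared haplotype at
high frequency — the signature XP-EHH detects. When a pooled case unit
(the two eastern residents) is swept, its populations share the donor, as
selection on the same standing variant would. Forward simulation with
selection coefficients is deliberately avoided: the scans only see the
post-sweep state.

### Default scenario

Eight populations of 12 diploids in two clades (two residents + two
migrant pools per clade), 5,000 SNPs on a 4 Mb chromosome, `F_clade`
0.15 over `F_pop` 0.03, 24 genes of 10 kb, three sweep genes assigned
round-robin to the resident case units. These sizes keep a full pipeline
run near ten seconds while leaving ≥100 sliding windows (the resolution
the 99th-percentile outlier rule needs) and ≥100 scan sites (the
resolution the rank p-value rule needs). What the simulator does **not**
emulate: genotyping error, genotype imputation artefacts, variable
recombination/mutation rate, linked background selection, and realistic
demography (split times, Ne). Passing tests therefore demonstrate the
statistical machinery is correct and calibrated on data satisfying its
assumptions, not that the biological conclusions of any particular data
set are robust to those real-data complications.

## Statistics

### Site filters

Sites are kept when minor-allele frequency (on called alleles) is ≥ 0.05
and the missing-call fraction is ≤ 0.25. F_ST and π use called-allele
counts; the PCA scan mean-imputes missing dosages per site — standard
practice for each family.

### Hudson F_ST

Per site, with alt frequencies p₁, p₂ and called-allele counts n₁, n₂:

    num = (p₁ − p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    den = p₁(1−p₂) + p₂(1−p₁)

Windows (50 kb span, 25 kb step, tiling from coordinate 0) aggregate as
Σnum/Σden (ratio of sums), which is robust to low-information sites;
windows with no defined site are omitted. Outliers are values strictly
above the empirical 99th-percentile (linear-interpolation quantile);
ties at the threshold are excluded, and fewer than 100 values yield no
calls at q = 0.99.

Exclusion semantics: case outlier **windows** are excluded by overlap
with any control outlier window, then merged (half-open BED arithmetic;
intervals touching only at a boundary do not merge). Case outlier
**sites** are excluded by exact-position match with control outlier
sites *and* by overlap with control outlier windows — a control-flagged
region marks the locus as demography-confounded for every variant in it.
The asymmetry (control sites do not void whole case windows) is
deliberate: a single noise site should not erase 50 kb of signal.

### PCA selection scan

Dosages restricted to one clade are standardized per site (mean-imputed,
centred, scaled by √(2p(1−p))). With u the leading unit eigenvector of
the sample covariance S = XXᵀ/L and λ its eigenvalue, the per-site
statistic is the eigenvalue-normalized squared loading

    D_j = (x̃_j · u)² / λ ,

referred to χ²(1) (sum over the top k components against χ²(k) when
k > 1). The eigenvalue normalization matters: the raw squared correlation
with a PC estimated from the same sites is inflated by exactly λ, and
without it null p-values fail uniformity. Monomorphic sites are excluded.

### XP-EHH

For a core site, a population's EHH at extension d is the probability two
randomly drawn haplotypes are identical over the interval from the core
to d; the pooled cross-population form partitions by core-site alleles
too, so EHH(0) is the core-site haplotype homozygosity (the
carrier-restricted `ehh` helper instead starts at 1). iHH integrates the
EHH decay curve over physical distance by the trapezoid rule outward in
both directions, stopping at the last site with EHH ≥ 0.05 (the segment
crossing below the cutoff is excluded; chromosome ends truncate
naturally). The statistic is ln(iHH_A/iHH_B), standardized genome-wide
(unbinned) to mean 0, sd 1; residents are side A by pipeline convention,
so positive scores mean selection in residents. Significance is
rank-based: p = rank(|z|)/L with ties sharing the mean rank, significant
when −log₁₀(p) > 2 (strict). Sites where either integral is zero are
skipped and logged. Distances are physical bp throughout — no genetic
map is assumed.

The implementation refines haplotype-group partitions incrementally
outward (O(m) per extension step with early truncation); a brute-force
pair-enumeration oracle written independently from the definition checks
it exactly on small instances.

### Population structure

Single-read sampling draws one allele per sample per site (a fair coin on
heterozygotes), centres by the sampled-allele frequency and scales by
√(p(1−p)); pair covariances average products over sites where both
samples are called and the draw is polymorphic. This is the
genotype-level proxy of sampling one sequencing read, which removes
depth-dependent bias; read-level input is out of scope. Related samples
(covariance ≥ 0.3) form graph edges; one sample per connected component
is kept — greatest call rate, ties broken lexicographically (the
keep-one-per-pair rule generalized to clusters).

Windowed nucleotide diversity uses π_site = 2·c_ref·c_alt/(n(n−1)) summed
per non-overlapping 10 kb window and divided by the full window length in
bp, so positions absent from the variant table count as invariant; the
caller supplies chromosome lengths and the final partial window uses its
true length. No MAF filter is applied to π input.

### Parallelism classification

Per level (SNP, gene), per-comparison outlier sets are intersected into
the exclusive Venn regions; the report carries the membership matrix,
region counts, union, shared-by-≥2 and shared-by-all (the region counts
are asserted to sum to the union on every run). Genes are attached to
outlier items when the bp distance between half-open intervals is ≤ 25 kb
(inclusive at exactly 25,000; 0 when overlapping). Directionality of a
shared gene takes the XP-EHH sign at the best (largest |z|) significant
site within the gene ± 25 kb per sharing comparison; genes with an
undetermined sign in any sharing comparison are excluded from the
concordant fraction's denominator. Functional categories are simplified
to genic / proximal-regulatory (≤ 25 kb, non-overlapping) / intergenic.

## Verification scenarios

The acceptance checks (`scripts/acceptance.py`, `tests/test_acceptance.py`)
use three kinds of input:

1. **Published-count worked examples** — the relatedness filter on 202
   samples with six related pairs, the gene-level Venn with totals
   29/21/28 and overlaps 6/8/4/9, and the timing-gene tally (17 shared +
   13 single) — rebuilt as explicit inputs and pushed through the real
   code paths.
2. **Drift recovery** — two populations × 25 diploids at F = 0.10 over
   20,000 linkage-free sites, ten seeds; genome-wide ratio-of-sums F_ST
   must sit within ±0.02 of F.
3. **Planted-sweep end-to-end** — the default scenario plus one
   clade-wide sweep (every western population swept with independent
   donors), ten seeds. Resident sweeps must show significant positive
   XP-EHH in their own comparison (≥ 80% of genes); the clade-wide sweep,
   being visible to the migrant–migrant and resident–resident controls,
   must never survive into a post-exclusion case window set of its clade.
4. **Null calibration** — F = 0 linkage-free genotypes on a sparse-gene
   chromosome (6,000 sites / 24 Mb / 30 genes) so the 25 kb gene-proximity
   footprint is a small genome fraction, as at genome scale. Outlier
   calls must run near 1%, PCA-scan p-values must pass a KS uniformity
   test, and no gene may reach the triple Venn region (each in ≥ 9/10
   seeds). The mosaic haplotype path is deliberately not used here: its
   founder sharing is real relatedness structure, which a null for the
   PCA scan must not contain.

## Numerical and edge-case conventions

- VCF positions are 1-based; all interval arithmetic is 0-based
  half-open, converted exactly once (`site pos → [pos−1, pos)`).
- Undefined values (zero called alleles, zero F_ST denominator, zero iHH)
  are flagged/NaN, never coerced to 0.
- Eigenvector signs follow the largest-magnitude-loading-positive rule.
- All randomness flows from a single seed through named
  `numpy.random.SeedSequence` children; identical (config, seed) pairs
  reproduce byte-identical outputs, independent of `--threads`.

## Known limitations

- Hard-call VCF input only; genotype-likelihood machinery for low
  coverage data is out of scope (the single-read-sampling covariance is a
  genotype-level proxy).
- Phasing is assumed done upstream; unphased input stops XP-EHH.
- The exact-position site-level exclusion cannot remove a confounded
  variant that no control flags (e.g. a locus where both migrant pools
  agree and both resident donors agree but the sides differ); region
  overlap composition mitigates but cannot eliminate this.
- One Manhattan-plot-ready TSV per scan is written; plotting itself is
  left to the user.
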