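# migrascan

Replicated resident–migrant selection scans for structured populations.

Seasonal migration is a polygenic trait that populations repeatedly gain
and lose. When a species contains independently derived resident and
migratory populations — as when its eastern and western clades have
separate evolutionary origins — the same phenotypic contrast can be
tested in replicate, and loci that respond in more than one lineage
distinguish **parallel** evolution (the same SNP or gene reused) from
**convergent** evolution (different genes, same phenotype). `migrascan`
implements the full scan pipeline for this design:

- **Hudson F_ST** outlier scans, per site and in 50 kb sliding windows
  (25 kb step), with outliers strictly above the empirical 99th
  percentile. Case comparisons (resident vs. migrant within a clade) are
  cleaned by **control comparisons** (migrant–migrant and
  resident–resident), removing differentiation driven by demography
  rather than migratory phenotype:
  `num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)`,
  `den = p₁(1−p₂) + p₂(1−p₁)`, windows as Σnum/Σden.
- A **PCA-based selection scan**: per-SNP eigenvalue-normalized squared
  loading `D_j = (x̃_j·u)²/λ` on the leading component(s), referred to
  χ²(1), flagging sites at p < 0.05.
- **XP-EHH**: `ln(iHH_A/iHH_B)` with iHH the trapezoid-integrated EHH
  decay over physical distance (truncated at EHH < 0.05), standardized
  genome-wide; residents are side A, so positive scores mean selection in
  the resident population. Significance is rank-based on |z| with
  −log₁₀(p) > 2.
- **Gene-proximity annotation** (within 25 kb, inclusive) and a
  **parallelism report**: Venn-region membership of outliers across the
  replicate comparisons at SNP and gene level, XP-EHH directionality
  concordance of shared genes, and a simplified functional categorization
  (genic / proximal-regulatory / intergenic).
- Supporting structure statistics: single-read-sampling covariance and
  PCA, relatedness filtering (covariance ≥ 0.3, keep one per cluster),
  and windowed nucleotide diversity (π per 10 kb, invariant-site aware).
- A **simulator** (`migrascan.simdata`) generating phased structured
  populations with hierarchical Balding–Nichols drift, founder-mosaic
  recombination, and planted hard sweeps with known truth, written as
  standard VCF/BED/TSV.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

A config either points at a phased VCF + BED annotation + population map,
or asks for a simulated scenario. The default scenario is eight
populations (two residents and two migrant pools per clade) of 12
diploids, 5,000 SNPs on a 4 Mb chromosome, with three hard sweeps planted
in the resident case units:

```yaml
# config.yaml
seed: 42
outdir: run
simulation:
  n_sweep_genes: 3
cases:
  - {label: AZ_vs_west_mig,  a: [AZ],     b: [Wmig1, Wmig2]}
  - {label: CAn_vs_west_mig, a: [CAn],    b: [Wmig1, Wmig2]}
  - {label: east_res_vs_mig, a: [FL, AL], b: [Emig1, Emig2]}
controls:
  - {label: west_mig_vs_mig, a: [Wmig1], b: [Wmig2], role: control-migrant-migrant}
  - {label: west_res_vs_res, a: [AZ],    b: [CAn],   role: control-resident-resident}
  - {label: east_mig_vs_mig, a: [Emig1], b: [Emig2], role: control-migrant-migrant}
  - {label: east_res_vs_res, a: [FL],    b: [AL],    role: control-resident-resident}
```

```sh
$ migrascan classify --config config.yaml
gene-level union 15, shared by >=2: 6, shared by all: 1
```

The run directory then holds per-comparison scan TSVs, the structure
outputs and the parallelism report. From this run's `manifest.json` and
`venn_regions_gene.tsv`:

- 5,000 simulated sites, 4,486 surviving the MAF/missingness filters;
- each case comparison has 44 significant XP-EHH sites, all with
  positive (resident-directed) scores — the planted sweeps;
- gene-level Venn regions:

  | comparisons                     | n_items |
  |---------------------------------|---------|
  | AZ only                         | 2       |
  | CAn only                        | 3       |
  | East only                       | 4       |
  | AZ ∩ East                       | 3       |
  | CAn ∩ East                      | 2       |
  | AZ ∩ CAn ∩ East                 | 1       |

  i.e. a union of 15 genes near post-exclusion outliers, 6 shared by two
  or more comparisons. Genes reached by outliers in several comparisons
  are the parallel-evolution candidates; singleton regions are
  lineage-specific (convergent) signal or noise;
- per-population mean π ≈ 3.5×10⁻⁴/bp, uniform across populations, as
  expected with equal simulated diversity.

Every stage is also exposed as a subcommand (`simulate`, `filter`,
`structure`, `fst`, `pcascan`, `xpehh`, `classify`, `run`), all driven by
the same config; `--seed` overrides the config seed and identical
(config, seed) pairs reproduce byte-identical outputs.

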