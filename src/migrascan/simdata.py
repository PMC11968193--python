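"""Structured-population simulator with planted hard sweeps.

The generator emulates the statistical structure the scan pipeline
assumes: two deeply diverged clades, hierarchical drift within each clade
(Balding-Nichols allele frequencies: root -> clade -> population),
founder-mosaic recombination so linkage decays with physical distance,
resident populations carrying recent hard sweeps in which the selected
haplotype segregates at high frequency, and a gene annotation track that
includes the swept ("migration-linked") genes.

The Balding-Nichols model draws a population frequency around ancestral
frequency ``p`` from a Beta distribution with mean ``p`` and variance
``F * p * (1 - p)``, so the drift parameter ``F`` has a closed-form F_ST
interpretation that the scan statistics can be validated against.

A hard sweep is modelled as its end state: a randomly chosen donor
haplotype is copied over a fraction of the population's haplotypes at
every site within a radius of the sweep core, producing the long shared
haplotype at high frequency that haplotype statistics detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from migrascan.containers import MIGRANT, RESIDENT, HaplotypeMatrix, PopulationMap

_BETA_CLIP = 1e-6  # keep ancestral-level frequencies polymorphic

DEFAULT_POPULATIONS = {
    # label -> (phenotype, n_diploids), grouped by clade.  Mirrors the study
    # design: two resident populations plus two migrant pools per clade; the
    # two eastern residents are analysed as one pooled case unit.
    "west": [
        ("AZ", RESIDENT, 12),
        ("CAn", RESIDENT, 12),
        ("Wmig1", MIGRANT, 12),
        ("Wmig2", MIGRANT, 12),
    ],
    "east": [
        ("FL", RESIDENT, 12),
        ("AL", RESIDENT, 12),
        ("Emig1", MIGRANT, 12),
        ("Emig2", MIGRANT, 12),
    ],
}


@dataclass
class SimConfig:
    """Scenario parameters for the simulator.

    Defaults are the desk-scale study conditions every verification run
    uses: 8 populations of 12 diploids in two clades, 5,000 SNPs on a
    4 Mb chromosome, clade-level drift 0.15 over population-level drift
    0.03, and hard sweeps carried by 90% of the target population's
    haplotypes.
    """

    populations_per_clade: dict[str, list[tuple[str, str, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_POPULATIONS.items()}
    )
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    F_clade: float = 0.15
    F_pop: float = 0.03
    L_sites: int = 5000
    chrom: str = "chr1"
    chrom_length_bp: int = 4_000_000
    recomb_switch_prob: float = 0.01
    n_founders: int = 24
    n_genes: int = 24
    gene_length_bp: int = 10_000
    n_sweep_genes: int = 3
    sweep_carrier_fraction: float = 0.9
    sweep_radius_bp: int = 30_000
    # optional explicit plan: gene index (0-based, among sweep genes) ->
    # list of population-label groups; populations within a group share the
    # donor haplotype (a pooled case unit swept together).
    sweep_plan: list[list[list[str]]] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"ancestral_maf_range must lie in (0, 0.5], got {(lo, hi)}")
        for name in ("F_clade", "F_pop"):
            f = getattr(self, name)
            if not (0 <= f < 1):
                raise ValueError(f"{name} must be in [0, 1), got {f}")
        if not (0 <= self.recomb_switch_prob <= 1):
            raise ValueError("recomb_switch_prob must be in [0, 1]")
        if not (0 <= self.sweep_carrier_fraction <= 1):
            raise ValueError("sweep_carrier_fraction must be in [0, 1]")
        if self.n_sweep_genes > self.n_genes:
            raise ValueError("n_sweep_genes must not exceed n_genes")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.L_sites < 1 or self.chrom_length_bp < self.L_sites:
            raise ValueError("need chrom_length_bp >= L_sites >= 1")

    @property
    def population_labels(self) -> list[str]:
        return [lab for pops in self.populations_per_clade.values() for lab, _, _ in pops]

    def popmap(self) -> PopulationMap:
        sample_pop: dict[str, str] = {}
        pheno: dict[str, str] = {}
        clade_of: dict[str, str] = {}
        for clade, pops in self.populations_per_clade.items():
            for label, phenotype, n in pops:
                pheno[label] = phenotype
                clade_of[label] = clade
                for i in range(n):
                    sample_pop[f"{label}_{i:03d}"] = label
        return PopulationMap(sample_pop, pheno, clade_of)


@dataclass
class TruthTable:
    """Ground truth of a simulated scenario.

    ``genes``: gene_id, chrom, start, end (0-based half-open), swept_pops
    (comma-joined labels, empty for neutral genes).
    ``site_freqs``: per-site ancestral frequency and per-population
    expected (drifted) frequency.
    """

    genes: pd.DataFrame
    site_freqs: pd.DataFrame

    def swept_populations(self, gene_id: str) -> list[str]:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        val = row.iloc[0]["swept_pops"]
        return [] if not val else val.split(",")

    @property
    def sweep_genes(self) -> pd.DataFrame:
        return self.genes.loc[self.genes["swept_pops"] != ""].reset_index(drop=True)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Beta draw with mean p and variance F*p*(1-p); F=0 returns p exactly."""
    if F == 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return np.clip(rng.beta(a, b), _BETA_CLIP, 1 - _BETA_CLIP)


def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray, TruthTable]:
    """Draw site positions and hierarchical per-population allele frequencies.

    Returns ``(freqs, positions, truth)`` where ``freqs`` has one column
    per population label plus ``ancestral``, ``positions`` are strictly
    increasing 1-based site positions, and ``truth`` carries the gene
    annotation (sweeps not yet assigned) and the frequency table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    if lo == hi:
        raise ValueError("degenerate ancestral_maf_range (zero width)")
    L = config.L_sites
    positions = np.sort(
        rng.choice(np.arange(1, config.chrom_length_bp + 1), size=L, replace=False)
    )
    p_anc = rng.uniform(lo, hi, size=L)
    cols = {"ancestral": p_anc}
    for clade, pops in config.populations_per_clade.items():
        p_clade = _balding_nichols(rng, p_anc, config.F_clade)
        for label, _, _ in pops:
            cols[label] = _balding_nichols(rng, p_clade, config.F_pop)
    freqs = pd.DataFrame(cols)
    genes = _draw_genes(config, rng)
    site_freqs = freqs.copy()
    site_freqs.insert(0, "pos", positions)
    site_freqs.insert(0, "chrom", config.chrom)
    truth = TruthTable(genes=genes, site_freqs=site_freqs)
    return freqs, positions, truth


def _draw_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place non-overlapping genes of fixed length along the chromosome."""
    n, glen = config.n_genes, config.gene_length_bp
    span = config.chrom_length_bp
    if n * glen > span:
        raise ValueError("genes do not fit on the chromosome")
    # evenly partition, then jitter the gene inside its slot
    slot = span // n
    starts = np.arange(n) * slot + rng.integers(0, max(slot - glen, 1), size=n)
    return pd.DataFrame(
        {
            "gene_id": [f"gene{idx:03d}" for idx in range(n)],
            "chrom": config.chrom,
            "start": starts,
            "end": starts + glen,
            "strand": rng.choice(["+", "-"], size=n),
            "swept_pops": "",
        }
    )


def simulate_haplotypes(
    freqs: pd.DataFrame,
    positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> HaplotypeMatrix:
    """Sample phased haplotypes as founder mosaics.

    Per population, ``n_founders`` founder haplotypes are drawn site-wise
    Bernoulli at the population frequency; each output haplotype copies a
    founder and switches to a uniformly chosen founder with probability
    ``recomb_switch_prob`` between adjacent sites, so allelic association
    decays with site distance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    popmap = config.popmap()
    L = len(positions)
    blocks = []
    samples: list[str] = []
    for clade, pops in config.populations_per_clade.items():
        for label, _, n_dip in pops:
            p = freqs[label].to_numpy()
            founders = (rng.random((config.n_founders, L)) < p).astype(np.int8)
            n_hap = 2 * n_dip
            haps = np.empty((n_hap, L), dtype=np.int8)
            for h in range(n_hap):
                switch = rng.random(L) < config.recomb_switch_prob
                switch[0] = True
                seg = np.cumsum(switch) - 1
                choice = rng.integers(0, config.n_founders, size=seg[-1] + 1)
                haps[h] = founders[choice[seg], np.arange(L)]
            blocks.append(haps)
            samples.extend(f"{label}_{i:03d}" for i in range(n_dip))
    sites = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "id": [f"snp{j}" for j in range(L)],
        }
    )
    return HaplotypeMatrix(sites, np.vstack(blocks), samples)


def simulate_genotypes(
    freqs: pd.DataFrame,
    positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Linkage-free genotypes: per-sample dosage ~ Binomial(2, pop frequency).

    The frequency-level counterpart of :func:`simulate_haplotypes` for
    statistics that only use allele frequencies (F_ST, pi, PCA): every
    allele draw is independent, so realized differentiation matches the
    drift parameters exactly, without the founder-bottleneck correlation
    the mosaic process adds.
    """
    from migrascan.containers import GenotypeMatrix

    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    L = len(positions)
    blocks = []
    samples: list[str] = []
    for clade, pops in config.populations_per_clade.items():
        for label, _, n_dip in pops:
            p = freqs[label].to_numpy()
            blocks.append(rng.binomial(2, p, size=(n_dip, L)).astype(float))
            samples.extend(f"{label}_{i:03d}" for i in range(n_dip))
    sites = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "id": [f"snp{j}" for j in range(L)],
        }
    )
    return GenotypeMatrix(sites, np.vstack(blocks), samples)


def plant_sweep(
    haps: HaplotypeMatrix,
    popmap: PopulationMap,
    populations: str | list[str],
    core_bp: int,
    radius_bp: int,
    carrier_fraction: float,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Overwrite a fraction of each target population's haplotypes with one
    shared donor haplotype at every site within ``radius_bp`` of ``core_bp``.

    When several populations are given they share the donor (drawn from the
    first), emulating selection on the same standing haplotype in a pooled
    case unit.  Sites outside the radius are untouched, as are all other
    populations.
    """
    if not (0 <= carrier_fraction <= 1):
        raise ValueError("carrier_fraction must be in [0, 1]")
    if isinstance(populations, str):
        populations = [populations]
    pos = haps.sites["pos"].to_numpy()
    if not (pos.min() - radius_bp <= core_bp <= pos.max() + radius_bp):
        raise ValueError(f"sweep core {core_bp} outside the simulated chromosome")
    region = np.abs(pos - core_bp) <= radius_bp
    if not region.any():
        raise ValueError("sweep radius contains no sites")
    alleles = haps.alleles.copy()
    sample_index = {s: i for i, s in enumerate(haps.samples)}
    donor = None
    for pop in populations:
        members = popmap.samples_of(pop)
        hap_rows = np.array(
            [2 * sample_index[s] + k for s in members for k in (0, 1)]
        )
        if donor is None:
            donor_row = rng.choice(hap_rows)
            donor = alleles[donor_row, region].copy()
        n_carriers = int(round(carrier_fraction * len(hap_rows)))
        carriers = rng.choice(hap_rows, size=n_carriers, replace=False)
        alleles[np.ix_(carriers, np.flatnonzero(region))] = donor
    return HaplotypeMatrix(haps.sites.copy(), alleles, list(haps.samples))


def _default_sweep_plan(config: SimConfig) -> list[list[list[str]]]:
    """Round-robin: sweep gene i targets case unit i mod n_units.

    A case unit is a single resident population, except that all resident
    populations of a clade that are analysed pooled (more than one resident
    in the clade sharing the case side) still sweep independently here;
    pooled units are only formed for clades with >= 2 residents, where both
    residents share the donor so the pooled case set carries one haplotype.
    """
    units: list[list[str]] = []
    for clade, pops in config.populations_per_clade.items():
        residents = [lab for lab, ph, _ in pops if ph == RESIDENT]
        if len(residents) >= 3:
            raise ValueError("at most two residents per clade are supported")
        if clade == "east" and len(residents) == 2:
            units.append(residents)  # pooled East-style case unit
        else:
            units.extend([[r] for r in residents])
    if not units:
        raise ValueError("no resident populations to sweep")
    return [[units[i % len(units)]] for i in range(config.n_sweep_genes)]


def simulate(config: SimConfig) -> tuple[HaplotypeMatrix, TruthTable, PopulationMap]:
    """Full scenario: frequencies -> haplotypes -> planted sweeps.

    Sweeps are centred on the first ``n_sweep_genes`` genes (evenly spread
    over the chromosome by construction) following ``config.sweep_plan``
    or the default round-robin over resident case units.  All randomness
    derives from ``config.seed``.
    """
    rng_freq, rng_hap, rng_sweep, _rng_spare = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
    ]
    freqs, positions, truth = simulate_frequencies(config, rng_freq)
    haps = simulate_haplotypes(freqs, positions, config, rng_hap)
    popmap = config.popmap()

    plan = config.sweep_plan or _default_sweep_plan(config)
    if len(plan) != config.n_sweep_genes:
        raise ValueError("sweep_plan length must equal n_sweep_genes")
    # spread the sweep genes across the chromosome: every k-th gene
    stride = max(config.n_genes // max(config.n_sweep_genes, 1), 1)
    gene_rows = [i * stride for i in range(config.n_sweep_genes)]
    genes = truth.genes
    for gi, groups in zip(gene_rows, plan):
        core = int((genes.at[gi, "start"] + genes.at[gi, "end"]) // 2)
        swept: list[str] = []
        for group in groups:
            haps = plant_sweep(
                haps,
                popmap,
                list(group),
                core,
                config.sweep_radius_bp,
                config.sweep_carrier_fraction,
                rng_sweep,
            )
            swept.extend(group)
        genes.at[gi, "swept_pops"] = ",".join(swept)
    return haps, truth, popmap


def apply_missingness(
    geno_dosages: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Mask a random fraction of genotype calls (returns a copy)."""
    out = np.asarray(geno_dosages, dtype=float).copy()
    if rate > 0:
        out[rng.random(out.shape) < rate] = np.nan
    return out


# ---------------------------------------------------------------------------
# output writers


def write_vcf(haps: HaplotypeMatrix, path: str | Path, chrom_length: int) -> None:
    """Write phased haplotypes as a minimal VCF v4.2 with GT fields."""
    path = Path(path)
    sites = haps.sites
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sites["chrom"].unique()
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom},length={chrom_length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(haps.samples)
            + "\n"
        )
        A = haps.alleles
        for j in range(haps.n_sites):
            row = sites.iloc[j]
            gts = "\t".join(
                f"{A[2 * i, j]}|{A[2 * i + 1, j]}" for i in range(haps.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row.get('id', '.') or '.'}\t"
                f"{row.get('ref', 'A')}\t{row.get('alt', 'T')}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene intervals as BED4 (0-based half-open)."""
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_truth(truth: TruthTable, genes_path: str | Path, freqs_path: str | Path) -> None:
    truth.genes.to_csv(genes_path, sep="\t", index=False)
    truth.site_freqs.to_csv(freqs_path, sep="\t", index=False, float_format="%.8g")


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    popmap.to_frame().to_csv(path, sep="\t", index=False)


def write_outputs(
    haps: HaplotypeMatrix,
    truth: TruthTable,
    popmap: PopulationMap,
    outdir: str | Path,
    chrom_length: int,
) -> dict[str, Path]:
    """Write the VCF / BED / truth TSV / popmap bundle the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "simulated.vcf",
        "bed": outdir / "genes.bed",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_freqs": outdir / "truth_freqs.tsv",
        "popmap": outdir / "popmap.tsv",
    }
    write_vcf(haps, paths["vcf"], chrom_length)
    write_bed(truth.genes, paths["bed"])
    write_truth(truth, paths["truth_genes"], paths["truth_freqs"])
    write_popmap(popmap, paths["popmap"])
    return paths
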