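"""Standard-format I/O and the site filters that define the analysed SNP set.

VCF parsing goes through cyvcf2; only biallelic SNPs are kept (multiallelic
and non-SNP records are dropped with a logged count).  The minor-allele
frequency and missingness filters are applied here because they determine
every downstream site set.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from migrascan.containers import GenotypeMatrix, HaplotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

_NUCS = {"A", "C", "G", "T"}


def read_vcf(path: str | Path, phased: bool = False) -> GenotypeMatrix | HaplotypeMatrix:
    """Read a VCF into a genotype (dosage) or phased haplotype matrix.

    With ``phased=True`` every GT must use the phased separator ``|``;
    any unphased call is a hard error.  Multiallelic and non-SNP records
    are skipped (count logged).
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, ids = [], [], [], [], []
    geno_rows = []
    hap_rows = []
    n_dropped = 0
    for rec_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1 or var.REF not in _NUCS or var.ALT[0] not in _NUCS:
            n_dropped += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        if phased:
            alleles = np.empty((2 * len(samples),), dtype=np.int8)
            for i, g in enumerate(gts):
                if len(g) < 3 or not g[-1]:
                    raise ValueError(
                        f"{path}: record {rec_no} ({var.CHROM}:{var.POS}) "
                        f"sample {samples[i]} is not phased"
                    )
                a0, a1 = g[0], g[1]
                if a0 < 0 or a1 < 0:
                    raise ValueError(
                        f"{path}: record {rec_no} has a missing call; phased "
                        "haplotype input must be fully called"
                    )
                alleles[2 * i] = a0
                alleles[2 * i + 1] = a1
            hap_rows.append(alleles)
        else:
            dose = np.array(
                [np.nan if g[0] < 0 or g[1] < 0 else g[0] + g[1] for g in gts],
                dtype=float,
            )
            geno_rows.append(dose)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        ids.append(var.ID or ".")
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "id": ids}
    )
    if phased:
        alleles = (
            np.stack(hap_rows, axis=1) if hap_rows else np.empty((2 * len(samples), 0), np.int8)
        )
        return HaplotypeMatrix(sites, alleles, samples)
    dosages = (
        np.stack(geno_rows, axis=1) if geno_rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(sites, dosages, samples)


def filter_sites(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing_fraction: float = 0.25,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop sites failing the MAF or missingness thresholds.

    A site is retained when its overall minor-allele frequency, computed on
    called alleles only, is >= ``maf_min`` and its fraction of missing
    genotype calls is <= ``max_missing_fraction``.  Returns the filtered
    matrix and a report of dropped sites with the reason(s).
    """
    D = geno.dosages
    n_samples = D.shape[0]
    called = ~np.isnan(D)
    n_called_alleles = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.nansum(D, axis=0) / n_called_alleles
    maf = np.minimum(alt_freq, 1 - alt_freq)
    miss_frac = 1 - called.sum(axis=0) / n_samples
    fail_maf = (n_called_alleles == 0) | (maf < maf_min)
    fail_miss = miss_frac > max_missing_fraction
    keep = ~(fail_maf | fail_miss)
    reasons = []
    for j in np.flatnonzero(~keep):
        why = []
        if fail_maf[j]:
            why.append("maf")
        if fail_miss[j]:
            why.append("missingness")
        reasons.append(
            {
                "chrom": geno.sites.at[j, "chrom"],
                "pos": geno.sites.at[j, "pos"],
                "reason": "+".join(why),
            }
        )
    report = pd.DataFrame(reasons, columns=["chrom", "pos", "reason"])
    return geno.subset_sites(keep), report


def allele_frequencies(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    populations: str | list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """Pooled alt-allele counts and frequency per site for a population set.

    Counts use called alleles only; merged sets are pooled *before*
    counting, so the result is the count-weighted pool, not a mean of
    per-population frequencies.  Sites where the pool has zero called
    alleles get ``defined=False`` and NaN frequency, never 0.
    """
    samples = popmap.samples_of(populations)
    if not samples:
        raise ValueError(f"no samples in populations {populations!r}")
    idx = [geno.samples.index(s) for s in samples]
    D = geno.dosages[idx]
    called = ~np.isnan(D)
    n_called = 2 * called.sum(axis=0)
    alt = np.nansum(D, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    out = geno.sites[["chrom", "pos"]].copy()
    out["alt_count"] = alt.astype(int)
    out["called_alleles"] = n_called.astype(int)
    out["frequency"] = freq
    out["defined"] = n_called > 0
    return out


def read_popmap(path: str | Path) -> PopulationMap:
    """Read the TSV population map: sample, population, phenotype, clade."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "population", "phenotype", "clade"}
    if not required.issubset(df.columns):
        raise ValueError(f"population map must have columns {sorted(required)}")
    sample_pop = dict(zip(df["sample"].astype(str), df["population"].astype(str)))
    pheno, clade = {}, {}
    for _, row in df.iterrows():
        pop = str(row["population"])
        pheno[pop] = str(row["phenotype"])
        clade[pop] = str(row["clade"])
    return PopulationMap(sample_pop, pheno, clade)


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    """Read BED3+name gene intervals (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"][:_ncols(path)],
    )
    if "gene_id" not in df.columns:
        df["gene_id"] = [f"interval{i}" for i in range(len(df))]
    if "strand" not in df.columns:
        df["strand"] = "."
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def _ncols(path: str | Path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(len(line.rstrip("\n").split("\t")), 6)
    return 4


def read_gff_genes(path: str | Path) -> pd.DataFrame:
    """Extract gene lines from a GFF3 as 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name") or f"gene{len(rows)}"
            rows.append(
                {
                    "gene_id": gid,
                    "chrom": parts[0],
                    "start": int(parts[3]) - 1,  # GFF is 1-based inclusive
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
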