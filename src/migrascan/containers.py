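"""In-memory containers shared by every stage of the pipeline.

Coordinate conventions
----------------------
VCF positions are 1-based; all interval arithmetic (genes, windows,
outlier regions) is 0-based half-open, BED style.  The conversion happens
exactly once: a site at VCF position ``pos`` occupies the interval
``[pos - 1, pos)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]

RESIDENT = "resident"
MIGRANT = "migrant"


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("chrom", "pos") if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks required columns: {missing}")
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index
    if not np.array_equal(order.to_numpy(), sites.index.to_numpy()):
        raise ValueError("sites must be sorted by (chrom, pos)")
    return sites.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Per-sample alt-allele dosage over an ordered list of biallelic sites.

    ``dosages`` is a float array of shape (n_samples, n_sites) holding
    0/1/2 with ``nan`` for missing calls.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        if self.n_sites == 0:
            return np.ones(self.n_samples)
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(self.sites.copy(), self.dosages[idx], list(keep))

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.dosages[:, mask],
            list(self.samples),
        )


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 alleles, one row per haplotype (two per diploid sample).

    Haplotypes ``2*i`` and ``2*i + 1`` belong to sample ``i``.
    """

    sites: pd.DataFrame
    alleles: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError(
                f"allele shape {self.alleles.shape} inconsistent with "
                f"{len(self.samples)} diploid samples x {len(self.sites)} sites"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_of_haplotype(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_samples), 2)

    def to_genotypes(self) -> GenotypeMatrix:
        dos = self.alleles.reshape(self.n_samples, 2, self.n_sites).sum(axis=1)
        return GenotypeMatrix(self.sites.copy(), dos.astype(float), list(self.samples))

    def subset_samples(self, keep: list[str]) -> "HaplotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        hap_idx = np.column_stack([np.asarray(idx) * 2, np.asarray(idx) * 2 + 1]).ravel()
        return HaplotypeMatrix(self.sites.copy(), self.alleles[hap_idx], list(keep))


@dataclass
class PopulationMap:
    """sample -> population plus population -> (phenotype, clade).

    Phenotype is "resident" or "migrant"; clade labels are free-form
    (conventionally "east" / "west").
    """

    sample_population: dict[str, str]
    population_phenotype: dict[str, str]
    population_clade: dict[str, str]

    def __post_init__(self) -> None:
        pops = set(self.sample_population.values())
        unknown = pops - set(self.population_phenotype)
        if unknown:
            raise ValueError(f"populations without phenotype: {sorted(unknown)}")
        unknown = pops - set(self.population_clade)
        if unknown:
            raise ValueError(f"populations without clade: {sorted(unknown)}")
        bad = {
            p: ph
            for p, ph in self.population_phenotype.items()
            if ph not in (RESIDENT, MIGRANT)
        }
        if bad:
            raise ValueError(f"phenotype must be resident/migrant, got {bad}")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.sample_population.values()))

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.population_clade.values()))

    def samples_of(self, populations) -> list[str]:
        """Samples belonging to any of the given populations, in map order."""
        wanted = set([populations] if isinstance(populations, str) else populations)
        missing = wanted - set(self.population_phenotype)
        if missing:
            raise KeyError(f"unknown populations: {sorted(missing)}")
        return [s for s, p in self.sample_population.items() if p in wanted]

    def populations_in_clade(self, clade: str, phenotype: str | None = None) -> list[str]:
        out = []
        for p in self.populations:
            if self.population_clade[p] != clade:
                continue
            if phenotype is not None and self.population_phenotype[p] != phenotype:
                continue
            out.append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": s,
                "population": p,
                "phenotype": self.population_phenotype[p],
                "clade": self.population_clade[p],
            }
            for s, p in self.sample_population.items()
        ]
        return pd.DataFrame(rows, columns=["sample", "population", "phenotype", "clade"])


@dataclass
class ComparisonSpec:
    """One pairwise contrast: population set A versus population set B.

    ``role`` is "case" for a resident-vs-migrant contrast (A must be the
    resident side so positive XP-EHH means selection in residents) or one
    of the control roles used for demographic-background exclusion.
    """

    label: str
    pops_a: tuple[str, ...]
    pops_b: tuple[str, ...]
    role: str = "case"

    ROLES = ("case", "control-migrant-migrant", "control-resident-resident")

    def __post_init__(self) -> None:
        self.pops_a = tuple(self.pops_a)
        self.pops_b = tuple(self.pops_b)
        if self.role not in self.ROLES:
            raise ValueError(f"role must be one of {self.ROLES}, got {self.role!r}")
        if not self.pops_a or not self.pops_b:
            raise ValueError("both population sets must be nonempty")

    def validate_against(self, popmap: PopulationMap) -> None:
        for pop in self.pops_a + self.pops_b:
            if pop not in popmap.population_phenotype:
                raise ValueError(f"comparison {self.label!r}: unknown population {pop!r}")
        if self.role == "case":
            pheno_a = {popmap.population_phenotype[p] for p in self.pops_a}
            pheno_b = {popmap.population_phenotype[p] for p in self.pops_b}
            if pheno_a != {RESIDENT} or pheno_b != {MIGRANT}:
                raise ValueError(
                    f"case comparison {self.label!r} must pair residents (A) "
                    f"against migrants (B); got A={pheno_a}, B={pheno_b}"
                )
            clades = {popmap.population_clade[p] for p in self.pops_a + self.pops_b}
            if len(clades) != 1:
                raise ValueError(
                    f"case comparison {self.label!r} must stay within one clade, "
                    f"got {sorted(clades)}"
                )
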