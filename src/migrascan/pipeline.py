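"""End-to-end pipeline: simulate/load -> filter -> structure -> scans ->
replicated-comparison classification, from a single declarative config.

Every stage writes its TSV outputs into the run directory and records
counts in ``manifest.json``.  All randomness derives from the single
config seed through named ``numpy.random.SeedSequence`` children, so a
given (config, seed) pair reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import migrascan
from migrascan import replicate, scanstats, simdata, variant_io
from migrascan.containers import (
    ComparisonSpec,
    GenotypeMatrix,
    HaplotypeMatrix,
    PopulationMap,
)
from migrascan import popstructure

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "maf_min": 0.05,
    "max_missing_fraction": 0.25,
    "fst_window_bp": 50_000,
    "fst_step_bp": 25_000,
    "outlier_quantile": 0.99,
    "gene_distance_bp": 25_000,
    "xpehh_neglog10_p": 2.0,
    "pca_scan_p": 0.05,
    "relatedness_threshold": 0.3,
    "pi_window_bp": 10_000,
}

# stable per-stage substream indices off the root SeedSequence
_STAGE_STREAMS = {"simulate": 0, "srs": 1}


@dataclass
class PipelineConfig:
    """Declarative run description (see ``from_yaml``)."""

    seed: int
    outdir: str
    simulation: simdata.SimConfig | None = None
    vcf: str | None = None
    annotation: str | None = None
    popmap: str | None = None
    cases: list[ComparisonSpec] = field(default_factory=list)
    controls: list[ComparisonSpec] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    gene_categories: str | None = None

    def __post_init__(self) -> None:
        overrides = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if overrides:
            raise ValueError(f"unknown thresholds: {sorted(overrides)}")
        for k, v in self.thresholds.items():
            if v != DEFAULT_THRESHOLDS[k]:
                logger.info("threshold override: %s = %r (default %r)", k, v, DEFAULT_THRESHOLDS[k])
        self.thresholds = {**DEFAULT_THRESHOLDS, **self.thresholds}
        if self.simulation is None and not (self.vcf and self.annotation and self.popmap):
            raise ValueError("config needs either a simulation block or input paths")
        if not self.cases:
            raise ValueError("config must define at least one case comparison")
        for spec in self.cases:
            if spec.role != "case":
                raise ValueError(f"comparison {spec.label!r} listed under cases must have role 'case'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = None
        if "simulation" in raw:
            sim_kwargs = dict(raw["simulation"])
            if "populations_per_clade" in sim_kwargs:
                sim_kwargs["populations_per_clade"] = {
                    clade: [tuple(p) for p in pops]
                    for clade, pops in sim_kwargs["populations_per_clade"].items()
                }
            sim_kwargs.setdefault("seed", raw["seed"])
            sim = simdata.SimConfig(**sim_kwargs)
        cases = [
            ComparisonSpec(c["label"], tuple(c["a"]), tuple(c["b"]), "case")
            for c in raw.get("cases", [])
        ]
        controls = [
            ComparisonSpec(c["label"], tuple(c["a"]), tuple(c["b"]), c["role"])
            for c in raw.get("controls", [])
        ]
        return cls(
            seed=int(raw["seed"]),
            outdir=str(raw.get("outdir", "migrascan_run")),
            simulation=sim,
            vcf=raw.get("vcf"),
            annotation=raw.get("annotation"),
            popmap=raw.get("popmap"),
            cases=cases,
            controls=controls,
            thresholds=dict(raw.get("thresholds", {})),
            gene_categories=raw.get("gene_categories"),
        )


def default_comparisons(popmap: PopulationMap) -> tuple[list[ComparisonSpec], list[ComparisonSpec]]:
    """The replicated study design on the default simulated populations:
    one case per resident unit against its clade's pooled migrants, plus
    migrant-migrant and resident-resident controls per clade."""
    cases, controls = [], []
    for clade in popmap.clades:
        residents = popmap.populations_in_clade(clade, "resident")
        migrants = popmap.populations_in_clade(clade, "migrant")
        if not residents or not migrants:
            continue
        if clade == "east" and len(residents) > 1:
            cases.append(
                ComparisonSpec(f"{clade}_res_vs_mig", tuple(residents), tuple(migrants), "case")
            )
        else:
            for res in residents:
                cases.append(
                    ComparisonSpec(f"{res}_vs_{clade}_mig", (res,), tuple(migrants), "case")
                )
        if len(migrants) >= 2:
            controls.append(
                ComparisonSpec(
                    f"{clade}_mig_vs_mig", (migrants[0],), tuple(migrants[1:]),
                    "control-migrant-migrant",
                )
            )
        if len(residents) >= 2:
            controls.append(
                ComparisonSpec(
                    f"{clade}_res_vs_res", (residents[0],), tuple(residents[1:]),
                    "control-resident-resident",
                )
            )
    return cases, controls


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    snp_report: replicate.ParallelismReport | None
    gene_report: replicate.ParallelismReport | None
    case_outlier_windows: dict[str, pd.DataFrame]
    case_outlier_sites: dict[str, pd.DataFrame]
    xpehh: dict[str, pd.DataFrame]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    manifest: dict = {
        "package": "migrascan",
        "version": migrascan.__version__,
        "seed": config.seed,
        "thresholds": th,
        "stages": {},
    }
    streams = np.random.SeedSequence(config.seed).spawn(8)

    # ----- stage: inputs (simulate or load) -------------------------------
    if config.simulation is not None:
        haps, truth, popmap = simdata.simulate(config.simulation)
        chrom_lengths = {config.simulation.chrom: config.simulation.chrom_length_bp}
        paths = simdata.write_outputs(
            haps, truth, popmap, outdir / "simulated", config.simulation.chrom_length_bp
        )
        annotation = truth.genes
        manifest["stages"]["simulate"] = {
            "n_samples": haps.n_samples,
            "n_sites": haps.n_sites,
            "n_genes": len(truth.genes),
            "n_sweep_genes": len(truth.sweep_genes),
        }
    else:
        haps = variant_io.read_vcf(config.vcf, phased=True)
        popmap = variant_io.read_popmap(config.popmap)
        if str(config.annotation).endswith((".gff", ".gff3")):
            annotation = variant_io.read_gff_genes(config.annotation)
        else:
            annotation = variant_io.read_bed_genes(config.annotation)
        chrom_lengths = {
            chrom: int(grp["pos"].max()) + th["fst_window_bp"]
            for chrom, grp in haps.sites.groupby("chrom")
        }
        manifest["stages"]["load"] = {
            "n_samples": haps.n_samples,
            "n_sites": haps.n_sites,
            "n_genes": len(annotation),
        }
    if not isinstance(haps, HaplotypeMatrix):
        raise ValueError("pipeline needs phased input for XP-EHH")
    geno = haps.to_genotypes()
    if config.simulation is not None and config.simulation.missing_rate > 0:
        # optional masking of genotype calls; haplotypes stay fully called
        # (phased input is assumed imputed upstream)
        geno.dosages = simdata.apply_missingness(
            geno.dosages,
            config.simulation.missing_rate,
            np.random.default_rng(streams[2]),
        )

    cases = list(config.cases)
    controls = list(config.controls)
    for spec in cases + controls:
        spec.validate_against(popmap)

    # ----- stage: site filters -------------------------------------------
    geno_f, drop_report = variant_io.filter_sites(
        geno, th["maf_min"], th["max_missing_fraction"]
    )
    drop_report.to_csv(outdir / "filtered_sites.tsv", sep="\t", index=False)
    keep_pos = set(zip(geno_f.sites["chrom"], geno_f.sites["pos"]))
    hap_mask = np.array(
        [(c, p) in keep_pos for c, p in zip(haps.sites["chrom"], haps.sites["pos"])]
    )
    haps_f = HaplotypeMatrix(
        haps.sites.loc[hap_mask].reset_index(drop=True),
        haps.alleles[:, hap_mask],
        list(haps.samples),
    )
    manifest["stages"]["filter"] = {
        "sites_in": geno.n_sites,
        "sites_out": geno_f.n_sites,
        "dropped": int(geno.n_sites - geno_f.n_sites),
    }
    assert geno_f.n_sites <= geno.n_sites

    # ----- stage: population structure -----------------------------------
    srs_seed = int(np.random.default_rng(streams[1]).integers(2**31 - 1))
    cov = popstructure.srs_covariance(geno_f, seed=srs_seed)
    pd.DataFrame(cov.matrix, index=cov.samples, columns=cov.samples).to_csv(
        outdir / "covariance.tsv", sep="\t"
    )
    retained, rel_report = popstructure.relatedness_filter(
        cov, th["relatedness_threshold"], geno_f.call_rates()
    )
    rel_report.to_csv(outdir / "related_dropped.tsv", sep="\t", index=False)
    pd.Series(retained, name="sample").to_csv(
        outdir / "retained_samples.tsv", sep="\t", index=False
    )
    if len(retained) < geno_f.n_samples:
        geno_f = geno_f.subset_samples(retained)
        haps_f = haps_f.subset_samples(retained)
        popmap = PopulationMap(
            {s: p for s, p in popmap.sample_population.items() if s in set(retained)},
            popmap.population_phenotype,
            popmap.population_clade,
        )
    scores, eigvals = popstructure.pca(geno_f, k=min(4, geno_f.n_samples - 1))
    pca_df = pd.DataFrame(
        scores, index=geno_f.samples, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    )
    pca_df.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pi_rows = []
    pi_tables = []
    for pop in popmap.populations:
        windows, mean_pi = popstructure.windowed_pi(
            geno_f, popmap, pop, chrom_lengths, th["pi_window_bp"]
        )
        windows.insert(0, "population", pop)
        pi_tables.append(windows)
        pi_rows.append({"population": pop, "mean_pi": mean_pi})
    pd.concat(pi_tables).to_csv(outdir / "pi_windows.tsv", sep="\t", index=False)
    pd.DataFrame(pi_rows).to_csv(outdir / "pi_means.tsv", sep="\t", index=False)
    manifest["stages"]["structure"] = {
        "samples_in": len(cov.samples),
        "samples_retained": len(retained),
        "related_dropped": len(cov.samples) - len(retained),
        "pca_eigenvalues": [float(v) for v in eigvals],
    }

    # ----- stage: F_ST scans ---------------------------------------------
    def scan_comparison(spec: ComparisonSpec):
        sites = scanstats.fst_table(geno_f, popmap, spec.pops_a, spec.pops_b)
        windows = scanstats.fst_windows(sites, th["fst_window_bp"], th["fst_step_bp"])
        defined = sites.loc[sites["defined"]].reset_index(drop=True)
        site_mask = scanstats.percentile_outliers(
            defined["fst"].to_numpy(), th["outlier_quantile"]
        )
        win_mask = scanstats.percentile_outliers(
            windows["fst"].to_numpy(), th["outlier_quantile"]
        )
        out_sites = replicate.sites_to_intervals(defined.loc[site_mask])
        out_windows = windows.loc[win_mask, ["chrom", "start", "end"]].reset_index(drop=True)
        return sites, windows, out_sites, out_windows

    case_sites_raw: dict[str, pd.DataFrame] = {}
    case_windows_raw: dict[str, pd.DataFrame] = {}
    control_out_sites: list[pd.DataFrame] = []
    control_out_windows: list[pd.DataFrame] = []
    fst_counts = {}
    for spec in cases + controls:
        sites, windows, out_sites, out_windows = scan_comparison(spec)
        sites.to_csv(outdir / f"fst_sites_{spec.label}.tsv", sep="\t", index=False)
        windows.to_csv(outdir / f"fst_windows_{spec.label}.tsv", sep="\t", index=False)
        if spec.role == "case":
            case_sites_raw[spec.label] = out_sites
            case_windows_raw[spec.label] = out_windows
        else:
            control_out_sites.append(out_sites)
            control_out_windows.append(out_windows)
        fst_counts[spec.label] = {
            "role": spec.role,
            "defined_sites": int(sites["defined"].sum()),
            "windows": len(windows),
            "outlier_sites": len(out_sites),
            "outlier_windows": len(out_windows),
        }
    manifest["stages"]["fst"] = fst_counts

    # ----- stage: control exclusion + merge ------------------------------
    case_out_sites: dict[str, pd.DataFrame] = {}
    case_out_windows: dict[str, pd.DataFrame] = {}
    excl_counts = {}
    for label in case_sites_raw:
        # sites are excluded by control sites (exact position) and by any
        # control outlier window covering them: a control-flagged region
        # marks the locus as demography-confounded for every variant in it
        s = replicate.exclude_control_outliers(
            case_sites_raw[label], control_out_sites + control_out_windows
        )
        w = replicate.exclude_control_outliers(case_windows_raw[label], control_out_windows)
        w = replicate.merge_overlapping(w)
        case_out_sites[label] = s
        case_out_windows[label] = w
        s.to_csv(outdir / f"outlier_sites_{label}.tsv", sep="\t", index=False)
        w.to_csv(outdir / f"outlier_windows_{label}.tsv", sep="\t", index=False)
        excl_counts[label] = {
            "sites_before": len(case_sites_raw[label]),
            "sites_after": len(s),
            "windows_before": len(case_windows_raw[label]),
            "windows_after": len(w),
        }
        assert len(s) <= len(case_sites_raw[label])
    manifest["stages"]["exclusion"] = excl_counts

    # ----- stage: PCA selection scan per clade ---------------------------
    pca_scan_counts = {}
    for clade in popmap.clades:
        pops = popmap.populations_in_clade(clade)
        if len(popmap.samples_of(pops)) < 3:
            continue
        scan = scanstats.pca_selection_scan(geno_f, popmap, pops, k=1)
        scan.to_csv(outdir / f"pcascan_{clade}.tsv", sep="\t", index=False)
        pca_scan_counts[clade] = {
            "defined_sites": int(scan["defined"].sum()),
            "significant": int((scan["pvalue"] < th["pca_scan_p"]).sum()),
        }
    manifest["stages"]["pca_scan"] = pca_scan_counts

    # ----- stage: XP-EHH per case comparison -----------------------------
    xpehh_results: dict[str, pd.DataFrame] = {}
    xpehh_counts = {}
    for spec in cases:
        xp = scanstats.xpehh_scan(
            haps_f, popmap, spec.pops_a, spec.pops_b,
            neglog10_threshold=th["xpehh_neglog10_p"],
        )
        xp.to_csv(outdir / f"xpehh_{spec.label}.tsv", sep="\t", index=False)
        xpehh_results[spec.label] = xp
        xpehh_counts[spec.label] = {
            "defined_sites": int(xp["defined"].sum()),
            "significant": int(xp["significant"].sum()),
            "significant_resident": int((xp["significant"] & (xp["z"] > 0)).sum()),
            "significant_migrant": int((xp["significant"] & (xp["z"] < 0)).sum()),
        }
    manifest["stages"]["xpehh"] = xpehh_counts

    # ----- stage: parallelism classification -----------------------------
    snp_report = gene_report = None
    if len(case_out_sites) >= 2:
        snp_sets = {
            lab: set(zip(df["chrom"], df["start"])) for lab, df in case_out_sites.items()
        }
        snp_report = replicate.classify_parallelism(snp_sets, level="snp")
        gene_sets = {}
        for lab in case_out_sites:
            items = pd.concat([case_out_sites[lab], case_out_windows[lab]])
            if len(items):
                hits = replicate.genes_near(items, annotation, th["gene_distance_bp"])
                gene_sets[lab] = set(hits["gene_id"])
            else:
                gene_sets[lab] = set()
        gene_report = replicate.classify_parallelism(gene_sets, level="gene")
        for rep, name in ((snp_report, "snp"), (gene_report, "gene")):
            rep.region_table().to_csv(outdir / f"venn_regions_{name}.tsv", sep="\t", index=False)
            rep.membership.to_csv(outdir / f"{name}_membership.tsv", sep="\t")
        manifest["stages"]["parallelism"] = {
            "snp_union": snp_report.union_size,
            "snp_shared_two_plus": snp_report.shared_two_plus,
            "gene_union": gene_report.union_size,
            "gene_shared_two_plus": gene_report.shared_two_plus,
            "gene_shared_all": gene_report.shared_all,
        }
        if config.gene_categories:
            cats = pd.read_csv(config.gene_categories, sep="\t")
            catmap = dict(zip(cats.iloc[:, 0], cats.iloc[:, 1]))
            replicate.category_sharing(gene_report, catmap).to_csv(
                outdir / "category_sharing.tsv", sep="\t", index=False
            )

        # directionality over genes shared by >= 2 comparisons
        shared = gene_report.membership.index[gene_report.membership.sum(axis=1) >= 2]
        gi = annotation.set_index("gene_id")
        shared_items = pd.DataFrame(
            {
                "item": list(shared),
                "chrom": [gi.at[g, "chrom"] for g in shared],
                # widen to the gene-proximity window so the best scan site
                # near (not only inside) the gene determines the sign
                "start": [max(int(gi.at[g, "start"]) - th["gene_distance_bp"], 0) for g in shared],
                "end": [int(gi.at[g, "end"]) + th["gene_distance_bp"] for g in shared],
            }
        )
        direction, fraction = replicate.directionality_concordance(
            shared_items, gene_report.membership, xpehh_results
        )
        direction.to_csv(outdir / "directionality.tsv", sep="\t", index=False)
        manifest["stages"]["directionality"] = {
            "shared_genes": len(shared_items),
            "concordant_fraction": None if np.isnan(fraction) else fraction,
        }

    # ----- stage: functional categorization ------------------------------
    func_counts = {}
    for lab, s in case_out_sites.items():
        if len(s) == 0:
            continue
        fc = replicate.functional_categorize(s, annotation, th["gene_distance_bp"])
        fc.to_csv(outdir / f"functional_categories_{lab}.tsv", sep="\t", index=False)
        func_counts[lab] = fc["category"].value_counts().to_dict()
    manifest["stages"]["functional"] = func_counts

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        outdir=outdir,
        manifest=manifest,
        snp_report=snp_report,
        gene_report=gene_report,
        case_outlier_windows=case_out_windows,
        case_outlier_sites=case_out_sites,
        xpehh=xpehh_results,
    )
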