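"""Selection statistics: Hudson F_ST (site and sliding-window) with
percentile outlier calling, the PCA-based chi-square selection scan, and
cross-population extended haplotype homozygosity (XP-EHH) with rank-based
significance.

Estimator choices
-----------------
F_ST uses the Hudson estimator in ratio-of-sums form with the standard
finite-sample correction of the numerator,

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

with n the called-allele counts.  Windows aggregate as sum(num)/sum(den)
(ratio of sums), which is robust to low-information sites.

XP-EHH follows the cross-population form: per core site, each
population's pooled-haplotype EHH decay curve is integrated over physical
distance (trapezoid, truncated once EHH drops below 0.05), and the score
is ln(iHH_A / iHH_B), standardized genome-wide.  Positive standardized
scores point to a sweep in population A (the resident side, by pipeline
convention).  Significance is rank-based on |score|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from migrascan.containers import GenotypeMatrix, HaplotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05


# ---------------------------------------------------------------------------
# Hudson F_ST


def fst_site(p1, n1, p2, n2):
    """Hudson F_ST numerator and denominator, vectorized.

    ``p`` are alt-allele frequencies, ``n`` called-allele counts (>= 2).
    Sites with denominator 0 (both populations fixed for the same allele)
    are undefined; callers should mask them.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_table(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    pops_a,
    pops_b,
    min_alleles: int = 2,
) -> pd.DataFrame:
    """Per-site Hudson F_ST between two (possibly pooled) population sets."""
    from migrascan.variant_io import allele_frequencies

    fa = allele_frequencies(geno, popmap, pops_a)
    fb = allele_frequencies(geno, popmap, pops_b)
    ok = (
        fa["defined"].to_numpy()
        & fb["defined"].to_numpy()
        & (fa["called_alleles"].to_numpy() >= min_alleles)
        & (fb["called_alleles"].to_numpy() >= min_alleles)
    )
    num = np.full(len(fa), np.nan)
    den = np.full(len(fa), np.nan)
    num[ok], den[ok] = fst_site(
        fa.loc[ok, "frequency"],
        fa.loc[ok, "called_alleles"],
        fb.loc[ok, "frequency"],
        fb.loc[ok, "called_alleles"],
    )
    out = fa[["chrom", "pos"]].copy()
    out["num"] = num
    out["den"] = den
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    out["defined"] = ok & (den > 0)
    return out


def fst_windows(
    fst_sites: pd.DataFrame, window_bp: int = 50_000, step_bp: int = 25_000
) -> pd.DataFrame:
    """Sliding-window ratio-of-sums F_ST.

    Windows tile each chromosome from 0 with the given span and step;
    windows containing no defined site are omitted.
    """
    if step_bp > window_bp:
        raise ValueError("step must not exceed window span")
    rows = []
    defined = fst_sites.loc[fst_sites["defined"]]
    for chrom, grp in defined.groupby("chrom", sort=True):
        pos0 = grp["pos"].to_numpy() - 1  # 0-based coordinate of the site
        num = grp["num"].to_numpy()
        den = grp["den"].to_numpy()
        if len(pos0) == 0:
            continue
        last_start = (pos0.max() // step_bp) * step_bp
        for start in range(0, int(last_start) + 1, step_bp):
            end = start + window_bp
            inwin = (pos0 >= start) & (pos0 < end)
            if not inwin.any():
                continue
            s_num = num[inwin].sum()
            s_den = den[inwin].sum()
            if s_den <= 0:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_sites": int(inwin.sum()),
                    "fst": s_num / s_den,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "fst"])


def percentile_outliers(values, q: float = 0.99) -> np.ndarray:
    """Boolean mask of values strictly above the empirical q-quantile
    (linear-interpolation quantile).  With fewer values than the quantile
    can resolve (< 1/(1-q)), warns and flags nothing."""
    values = np.asarray(values, dtype=float)
    if len(values) < 1.0 / (1.0 - q):
        warnings.warn(
            f"only {len(values)} values for the q={q} quantile; no outliers called",
            stacklevel=2,
        )
        return np.zeros(len(values), dtype=bool)
    threshold = np.quantile(values, q)
    return values > threshold


# ---------------------------------------------------------------------------
# PCA-based selection scan


def pca_selection_scan(
    geno: GenotypeMatrix, popmap: PopulationMap | None = None,
    populations=None, k: int = 1,
) -> pd.DataFrame:
    """Per-SNP selection statistic from the leading principal component(s).

    Dosages are standardized per site (missing mean-imputed, centred,
    scaled by sqrt(2p(1-p))).  For each site j the statistic is the
    eigenvalue-normalized squared loading on the top-k components,

        D_j = sum_{c<=k} (x_j . u_c)^2 / lambda_c,

    which is chi-square with k degrees of freedom for sites not involved
    in the structure the components capture.  Monomorphic sites are
    excluded (``defined=False``).
    """
    from migrascan.popstructure import pca_from_covariance, standardized_dosages

    if populations is not None:
        if popmap is None:
            raise ValueError("popmap required when restricting populations")
        geno = geno.subset_samples(popmap.samples_of(populations))
    if k < 1:
        raise ValueError("k must be >= 1")
    X, keep = standardized_dosages(geno)
    L = X.shape[1]
    if L == 0:
        raise ValueError("no polymorphic sites")
    cov = X @ X.T / L
    scores, eigvals = pca_from_covariance(cov, k)
    D = np.zeros(L)
    for c in range(k):
        u = scores[:, c]
        proj = X.T @ u
        D += proj**2 / eigvals[c]
    pval = stats.chi2.sf(D, df=k)
    out = geno.sites[["chrom", "pos"]].copy()
    out["stat"] = np.nan
    out["pvalue"] = np.nan
    out.loc[keep, "stat"] = D
    out.loc[keep, "pvalue"] = pval
    out["defined"] = keep
    return out


# ---------------------------------------------------------------------------
# EHH / XP-EHH


def ehh_curve(
    alleles: np.ndarray,
    core: int,
    direction: int,
    include_core: bool = True,
    stop_below: float | None = None,
) -> np.ndarray:
    """EHH at each extension step outward from the core site.

    ``alleles`` is an (m haplotypes x L sites) 0/1 array; ``direction``
    is +1 (rightward) or -1 (leftward).  Step 0 is the core site itself:
    with ``include_core`` the partition starts from core-site alleles
    (pooled cross-population form), otherwise all haplotypes start in one
    group (carrier-restricted form, EHH(0) = 1).

    EHH(d) = sum_g C(m_g, 2) / C(m, 2) over groups g of haplotypes
    identical on the interval from the core to step d; non-increasing in
    d.  If ``stop_below`` is set, extension stops after the first step
    whose EHH falls below it.
    """
    m, L = alleles.shape
    if m < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    denom = m * (m - 1) / 2.0
    group = np.zeros(m, dtype=np.int64)
    out = []
    j = core
    first = True
    while 0 <= j < L:
        col = alleles[:, j]
        if first and not include_core:
            pass  # single group at the core
        else:
            # refine the partition by this site's alleles
            key = group * 2 + col
            _, group = np.unique(key, return_inverse=True)
        first = False
        counts = np.bincount(group)
        ehh = float((counts * (counts - 1)).sum() / 2.0 / denom)
        out.append(ehh)
        if stop_below is not None and ehh < stop_below:
            break
        j += direction
    return np.asarray(out)


def ehh(haps: HaplotypeMatrix, core: int, direction: int) -> np.ndarray:
    """Carrier-restricted EHH curve (EHH(0) = 1) for pre-selected
    haplotypes; see :func:`ehh_curve`."""
    return ehh_curve(haps.alleles, core, direction, include_core=False)


def _ihh_one_side(
    alleles: np.ndarray, positions: np.ndarray, core: int, direction: int,
    cutoff: float,
) -> float:
    """Trapezoidal integral of the pooled EHH curve on one side of the core.

    Integration runs outward over physical distance and stops at the last
    site whose EHH is still >= cutoff (the segment crossing below the
    cutoff is excluded).
    """
    curve = ehh_curve(alleles, core, direction, include_core=True, stop_below=cutoff)
    ihh = 0.0
    for step in range(1, len(curve)):
        if curve[step] < cutoff:
            break
        j_prev = core + direction * (step - 1)
        j_here = core + direction * step
        dist = abs(float(positions[j_here]) - float(positions[j_prev]))
        ihh += 0.5 * (curve[step] + curve[step - 1]) * dist
    return ihh


def ihh(
    alleles: np.ndarray, positions: np.ndarray, core: int, cutoff: float = EHH_CUTOFF
) -> float:
    """Two-sided integrated EHH of a pooled haplotype sample at a core site."""
    return _ihh_one_side(alleles, positions, core, +1, cutoff) + _ihh_one_side(
        alleles, positions, core, -1, cutoff
    )


def xpehh_raw(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    positions: np.ndarray,
    cutoff: float = EHH_CUTOFF,
) -> np.ndarray:
    """Unstandardized XP-EHH = ln(iHH_A / iHH_B) per core site.

    Sites where either integral is zero are NaN (skipped, logged by the
    caller).
    """
    L = haps_a.shape[1]
    if haps_b.shape[1] != L or len(positions) != L:
        raise ValueError("both populations must cover identical sites")
    out = np.full(L, np.nan)
    for j in range(L):
        ia = ihh(haps_a, positions, j, cutoff)
        ib = ihh(haps_b, positions, j, cutoff)
        if ia > 0 and ib > 0:
            out[j] = np.log(ia / ib)
    return out


def rank_pvalues(scores: np.ndarray) -> np.ndarray:
    """Rank-based p-values of absolute scores: p_i = rank_i / L with rank 1
    the largest |score|; ties share the mean rank."""
    scores = np.asarray(scores, dtype=float)
    L = len(scores)
    if L < 100:
        raise ValueError("rank p-values need at least 100 scores")
    ranks = stats.rankdata(-np.abs(scores), method="average")
    return ranks / L


def xpehh_scan(
    haps: HaplotypeMatrix,
    popmap: PopulationMap,
    pops_a,
    pops_b,
    cutoff: float = EHH_CUTOFF,
    neglog10_threshold: float = 2.0,
) -> pd.DataFrame:
    """Full XP-EHH scan between two population sets over shared sites.

    Returns per site: raw and standardized scores, rank p-value,
    significance flag (-log10 p strictly greater than the threshold) and
    the selected population side ("A" for positive scores).
    """
    A = haps.subset_samples(popmap.samples_of(pops_a)).alleles
    B = haps.subset_samples(popmap.samples_of(pops_b)).alleles
    positions = haps.sites["pos"].to_numpy().astype(float)
    raw = xpehh_raw(A, B, positions, cutoff)
    defined = np.isfinite(raw)
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.info("xpehh: skipped %d sites with zero iHH", n_skipped)
    z = np.full_like(raw, np.nan)
    sd = raw[defined].std()
    if defined.sum() >= 2 and sd > 0:
        z[defined] = (raw[defined] - raw[defined].mean()) / sd
    elif defined.sum() >= 2:
        z[defined] = 0.0
    pv = np.full_like(raw, np.nan)
    pv[defined] = rank_pvalues(z[defined])
    out = haps.sites[["chrom", "pos"]].copy()
    out["raw"] = raw
    out["z"] = z
    out["pvalue"] = pv
    with np.errstate(invalid="ignore", divide="ignore"):
        out["significant"] = defined & (-np.log10(np.where(defined, pv, 1.0)) > neglog10_threshold)
    out["selected_population"] = np.where(
        out["significant"], np.where(out["z"] > 0, "A", "B"), ""
    )
    out["defined"] = defined
    return out
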