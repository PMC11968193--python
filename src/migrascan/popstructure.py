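"""Population-structure statistics: single-read-sampling covariance and
PCA, relatedness filtering, and windowed nucleotide diversity.

Single-read sampling draws one allele per individual per site — the
genotype-level proxy of sampling one sequencing read — which removes
depth-dependent bias from the covariance before eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from migrascan.containers import GenotypeMatrix, PopulationMap


@dataclass
class CovarianceResult:
    """Symmetric sample x sample standardized genetic covariance."""

    matrix: np.ndarray
    pair_site_counts: np.ndarray
    samples: list[str]


def srs_covariance(geno: GenotypeMatrix, seed: int) -> CovarianceResult:
    """Single-read-sampling covariance between samples.

    One allele is sampled uniformly from each sample's two alleles at each
    called site (dosage 1 yields a fair coin; dosage 0/2 is forced).  The
    sampled 0/1 allele is centred by the site's sampled-allele frequency
    and scaled by sqrt(p(1-p)); the covariance of a pair averages the
    product over sites where both samples are called and the sampled draw
    is polymorphic.
    """
    if geno.n_samples < 2:
        raise ValueError("srs_covariance needs at least 2 samples")
    rng = np.random.default_rng(seed)
    D = geno.dosages
    # sampled allele: 0 if dosage 0, 1 if dosage 2, Bernoulli(1/2) if 1
    draw = rng.random(D.shape)
    with np.errstate(invalid="ignore"):
        X = np.where(D == 1, (draw < 0.5).astype(float), D / 2.0)
    X[np.isnan(D)] = np.nan
    p = np.nanmean(X, axis=0)
    poly = (p > 0) & (p < 1)
    X[:, ~poly] = np.nan  # monomorphic in the sampled draw: excluded
    with np.errstate(invalid="ignore"):
        Z = (X - p) / np.sqrt(p * (1 - p))
    M = (~np.isnan(Z)).astype(float)
    Z0 = np.nan_to_num(Z)
    counts = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (Z0 @ Z0.T) / counts
    cov[counts == 0] = np.nan
    return CovarianceResult(cov, counts.astype(int), list(geno.samples))


def relatedness_filter(
    cov: CovarianceResult,
    threshold: float = 0.3,
    call_rates: np.ndarray | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Keep one sample per related cluster (pairwise covariance >= threshold).

    Related pairs form graph edges; within each connected component the
    sample with the greatest call rate is kept (ties broken by
    lexicographic sample name), the rest dropped.  Returns the retained
    sample list (input order) and a report of dropped samples.
    """
    samples = cov.samples
    n = len(samples)
    if call_rates is None:
        call_rates = np.ones(n)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    C = cov.matrix
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(C[i, j]) and C[i, j] >= threshold:
                g.add_edge(i, j)
    dropped_rows = []
    drop: set[int] = set()
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            continue
        # greatest call rate wins; ties -> lexicographically first name
        keep = min(comp, key=lambda i: (-call_rates[i], samples[i]))
        for i in comp:
            if i != keep:
                drop.add(i)
                dropped_rows.append(
                    {
                        "dropped": samples[i],
                        "kept": samples[keep],
                        "covariance": C[i, keep],
                    }
                )
    retained = [s for i, s in enumerate(samples) if i not in drop]
    report = pd.DataFrame(dropped_rows, columns=["dropped", "kept", "covariance"])
    return retained, report


def pca_from_covariance(cov: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigendecomposition of a sample covariance matrix.

    Returns (scores, eigenvalues) with columns ordered by descending
    eigenvalue.  Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be below the number of samples ({n})")
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    vals = w[order]
    vecs = v[:, order]
    for c in range(vecs.shape[1]):
        imax = np.argmax(np.abs(vecs[:, c]))
        if vecs[imax, c] < 0:
            vecs[:, c] = -vecs[:, c]
    return vecs, vals


def standardized_dosages(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, centred, sqrt(2p(1-p))-scaled dosages.

    Returns (X, keep_mask) where monomorphic / all-missing sites are
    dropped from X and flagged False in the mask.
    """
    D = geno.dosages.copy()
    with np.errstate(invalid="ignore"):
        site_mean = np.nanmean(D, axis=0)
    miss = np.isnan(D)
    D[miss] = np.take(site_mean, np.where(miss)[1])
    p = site_mean / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    X = (D[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    return X, keep


def pca(geno: GenotypeMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the standardized-dosage sample covariance (see
    :func:`standardized_dosages`)."""
    X, _ = standardized_dosages(geno)
    cov = X @ X.T / X.shape[1]
    return pca_from_covariance(cov, k)


def windowed_pi(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    populations: str | list[str],
    chrom_lengths: dict[str, int],
    window_bp: int = 10_000,
) -> tuple[pd.DataFrame, float]:
    """Nucleotide diversity per non-overlapping window, per base pair.

    Per site, pi = 2 * c_ref * c_alt / (n * (n - 1)) with called-allele
    counts; a window's pi divides the summed site values by the full
    window length in bp (positions absent from the variant table are
    treated as invariant).  The final partial window uses its true
    length.  Returns the window table and the mean of window pi values.
    """
    from migrascan.variant_io import allele_frequencies

    freqs = allele_frequencies(geno, popmap, populations)
    n = freqs["called_alleles"].to_numpy().astype(float)
    alt = freqs["alt_count"].to_numpy().astype(float)
    ref = n - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(n >= 2, 2.0 * ref * alt / (n * np.maximum(n - 1, 1)), 0.0)
    rows = []
    for chrom, grp_idx in freqs.groupby("chrom", sort=True).groups.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"no chromosome length given for {chrom!r}")
        clen = chrom_lengths[chrom]
        pos0 = freqs.loc[grp_idx, "pos"].to_numpy() - 1  # 0-based
        vals = pi_site[np.asarray(grp_idx)]
        n_windows = int(np.ceil(clen / window_bp))
        win_of_site = pos0 // window_bp
        sums = np.bincount(win_of_site, weights=vals, minlength=n_windows)
        counts = np.bincount(win_of_site, minlength=n_windows)
        for w in range(n_windows):
            start = w * window_bp
            end = min(start + window_bp, clen)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_sites": int(counts[w]),
                    "pi": sums[w] / (end - start),
                }
            )
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"])
    mean_pi = float(windows["pi"].mean()) if len(windows) else float("nan")
    return windows, mean_pi
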