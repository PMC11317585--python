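"""Population-genomic diagnostics for segregating chromosomal inversions.

A large polymorphic inversion leaves three joint signatures in a sample of
diploid genotypes: principal-component analysis of the region separates
samples into three clusters (the two arrangement homokaryotypes and the
heterokaryotypes between them); heterokaryotypes show elevated
heterozygosity across the region; and suppressed recombination keeps
arrangement-tagged SNPs in strong mutual linkage disequilibrium relative to
the flanking background. This module computes those diagnostics, infers
per-sample inversion dosage (0/1/2) by deterministic one-dimensional
3-means on PC1, combines the three signatures into an inversion call, and
tests karyotype-phenotype association with Wilcoxon rank-sum tests.

Differentiation between sample groups is measured with the Weir & Cockerham
(1984) variance-component estimator of F_ST: per-site components a (among
groups), b (among individuals within groups) and c (within individuals),
with the windowed estimate sum(a)/sum(a+b+c) — the "weighted" convention
used by vcftools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthpop import GenotypeDataset

__all__ = [
    "FstComponents",
    "wc_fst_site",
    "wc_fst_components",
    "fst_windows",
    "groups_from_column",
    "sample_heterozygosity",
    "ld_r2",
    "pca_region",
    "infer_karyotypes",
    "detect_inversion",
    "wilcoxon_assoc",
]


@dataclass(frozen=True)
class FstComponents:
    """Weir-Cockerham (1984) per-site variance components for two groups."""

    a: float  # among-group
    b: float  # among individuals within groups
    c: float  # within individuals (heterozygosity)
    usable: bool

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if (self.usable and denom != 0.0) else np.nan


def wc_fst_components(
    dosages: np.ndarray, mask1: np.ndarray, mask2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP Weir-Cockerham components for two sample groups.

    ``dosages`` is (samples x SNPs) with -1 missing; returns per-SNP arrays
    (a, b, c, usable). Sites where either group has fewer than two
    non-missing genotypes, or that are monomorphic over both groups, are
    flagged unusable (components set to NaN).
    """
    r = 2.0
    stats_per_group = []
    for mask in (mask1, mask2):
        g = dosages[mask].astype(float)
        ok = g >= 0
        n_i = ok.sum(axis=0)  # diploid individuals sampled
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(ok, g, 0.0).sum(axis=0) / (2 * n_i)
            h_i = np.where(ok, g == 1, False).sum(axis=0) / n_i
        stats_per_group.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats_per_group

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2

    usable = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c, usable


def wc_fst_site(dosages_g1: np.ndarray, dosages_g2: np.ndarray) -> FstComponents:
    """Weir-Cockerham components at a single site, from the two groups'
    dosage vectors (-1 missing)."""
    g1 = np.asarray(dosages_g1).reshape(-1, 1)
    g2 = np.asarray(dosages_g2).reshape(-1, 1)
    stacked = np.vstack([g1, g2])
    m1 = np.arange(len(stacked)) < len(g1)
    a, b, c, usable = wc_fst_components(stacked, m1, ~m1)
    return FstComponents(float(a[0]), float(b[0]), float(c[0]), bool(usable[0]))


def groups_from_column(
    ds: GenotypeDataset, column: str, values: tuple | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two boolean sample masks from a metadata column (e.g. phenotype 1 vs 0)."""
    col = ds.samples[column]
    if values is None:
        values = tuple(sorted(col.dropna().unique(), reverse=True))
        if len(values) != 2:
            raise ValueError(f"column {column!r} is not two-valued: {values}")
    return (col == values[0]).to_numpy(), (col == values[1]).to_numpy()


def fst_windows(
    ds: GenotypeDataset,
    groups: tuple[np.ndarray, np.ndarray],
    window: int = 10_000,
    step: int = 10_000,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST between two sample groups.

    Windows are half-open [w, w + window) in bp, tiled every ``step`` from
    the region start (default 1); the window estimate is the weighted ratio
    sum(a) / sum(a+b+c) over usable SNPs. Empty windows are reported with a
    missing value so window coordinates are reproducible.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    mask = ds.snp_mask(chrom, start, end)
    sub = ds.subset(mask)
    if sub.n_snps == 0:
        raise ValueError("no SNPs in the requested region")
    a, b, c, usable = wc_fst_components(sub.dosages, *groups)
    denom = a + b + c

    lo = start if start is not None else 1
    hi = end if end is not None else int(sub.positions.max())
    out = []
    for chrom_name in pd.unique(sub.chrom):
        on_chrom = sub.chrom == chrom_name
        for w0 in range(lo, hi + 1, step):
            in_w = on_chrom & (sub.positions >= w0) & (sub.positions < w0 + window)
            use = in_w & usable
            n_use = int(use.sum())
            fst = float(a[use].sum() / denom[use].sum()) if n_use and denom[use].sum() != 0 else np.nan
            out.append(
                {
                    "chrom": chrom_name,
                    "start": w0,
                    "end": w0 + window,
                    "n_snps": n_use,
                    "fst": fst,
                }
            )
    return pd.DataFrame(out)


def sample_heterozygosity(
    ds: GenotypeDataset,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> np.ndarray:
    """Per-sample proportion of heterozygous calls among non-missing calls
    in the region (NaN for samples with no calls)."""
    mask = ds.snp_mask(chrom, start, end)
    if not mask.any():
        raise ValueError("no SNPs in the requested region")
    g = ds.dosages[:, mask]
    called = (g >= 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, (g == 1).sum(axis=1) / called, np.nan)


def ld_r2(
    ds: GenotypeDataset,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
    max_snps: int = 300,
    seed: int = 0,
) -> dict:
    """Pairwise composite (genotype) r-squared among region SNPs.

    Monomorphic SNPs are skipped; regions larger than ``max_snps`` are
    downsampled uniformly in index with a fixed seed. Returns the matrix,
    the SNP positions used, and the mean off-diagonal r-squared.
    """
    mask = ds.snp_mask(chrom, start, end)
    idx = np.flatnonzero(mask)
    g = ds.dosages[:, idx].astype(float)
    g[g < 0] = np.nan
    poly = np.nanstd(g, axis=0) > 0
    idx, g = idx[poly], g[:, poly]
    if g.shape[1] < 2:
        raise ValueError("need at least two polymorphic SNPs for LD")
    if len(idx) > max_snps:
        keep = np.sort(np.random.default_rng(seed).choice(len(idx), max_snps, replace=False))
        idx, g = idx[keep], g[:, keep]
    if np.isnan(g).any():
        r = np.ma.corrcoef(np.ma.masked_invalid(g.T)).filled(np.nan)
    else:
        r = np.corrcoef(g.T)
    r2 = r**2
    off = ~np.eye(len(idx), dtype=bool)
    return {
        "r2": r2,
        "positions": ds.positions[idx],
        "mean_r2": float(np.nanmean(r2[off])),
    }


def pca_region(
    ds: GenotypeDataset,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
    n_components: int = 2,
    scale: bool = False,
) -> dict:
    """PCA of the region's dosage matrix (samples as observations).

    Dosages are mean-centered per SNP (missing values mean-imputed);
    ``scale=True`` additionally divides by sqrt(p(1-p)) (Patterson scaling).
    The sign of each component is fixed so its largest-magnitude SNP loading
    is positive. Returns coordinates and variance-explained fractions.
    """
    mask = ds.snp_mask(chrom, start, end)
    g = ds.dosages[:, mask].astype(float)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 SNPs")
    g[g < 0] = np.nan
    mu = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mu, g) - mu
    if scale:
        p = mu / 2.0
        denom = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        g = g / denom
    if not np.any(g != 0):
        raise ValueError("degenerate (constant) dosage matrix")
    u, sv, vt = np.linalg.svd(g, full_matrices=False)
    k = min(n_components, len(sv))
    flip = np.sign(vt[np.arange(k), np.abs(vt[:k]).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = u[:, :k] * sv[:k] * flip
    var_explained = sv**2 / (sv**2).sum()
    return {"coords": coords, "var_explained": var_explained[:k], "loadings": vt[:k] * flip[:, None]}


def _silhouette_1d(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient for a 1-D clustering (absolute distance)."""
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return 0.0
    score = np.zeros(len(x))
    d = np.abs(x[:, None] - x[None, :])
    for i in range(len(x)):
        own = labels == labels[i]
        n_own = own.sum()
        a = d[i, own].sum() / (n_own - 1) if n_own > 1 else 0.0
        b = min(d[i, labels == other].mean() for other in uniq if other != labels[i])
        score[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(score.mean())


def infer_karyotypes(pc1: np.ndarray) -> pd.DataFrame:
    """Infer inversion dosage from PC1 by deterministic 1-D 3-means.

    Centers start at the 10th/50th/90th percentiles and Lloyd iterations run
    to convergence; clusters are ordered by mean PC1 and mapped to dosages
    0/1/2. The dosage labeling is identifiable only up to the 0<->2 flip
    (PC1 orientation does not know which arrangement is 'standard'). Returns
    per-sample pc1/cluster/dosage with the occupied-cluster count and a
    silhouette-style separation score in ``attrs``.
    """
    x = np.asarray(pc1, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to infer three karyotypes")
    centers = np.quantile(x, [0.1, 0.5, 0.9])
    labels = np.zeros(x.size, dtype=int)
    for _ in range(200):
        new = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for k in range(3):
            if np.any(labels == k):
                centers[k] = x[labels == k].mean()
    occupied = np.unique(labels)
    # order occupied clusters by mean PC1 -> dosage 0..(k-1)
    order = np.argsort([x[labels == k].mean() for k in occupied])
    dosage_of = {int(occupied[o]): rank for rank, o in enumerate(order)}
    dosage = np.array([dosage_of[int(l)] for l in labels])
    out = pd.DataFrame({"pc1": x, "cluster": labels, "dosage": dosage})
    out.attrs["n_clusters"] = int(len(occupied))
    out.attrs["separation"] = _silhouette_1d(x, labels)
    return out


def detect_inversion(
    ds: GenotypeDataset,
    chrom: str,
    start: int,
    end: int,
    min_snps: int = 20,
    min_separation: float = 0.6,
    min_het_ratio: float = 1.5,
    min_r2_ratio: float = 2.0,
    max_ld_snps: int = 300,
) -> dict:
    """Combined inversion classification for a candidate region.

    Declares a putative segregating inversion when all three signatures
    exceed their thresholds: (i) three PC1 clusters with silhouette
    separation >= ``min_separation``; (ii) middle-cluster (heterokaryotype)
    over outer-cluster mean regional heterozygosity >= ``min_het_ratio``;
    (iii) mean within-region r-squared over the same-chromosome flanking
    background >= ``min_r2_ratio``. The supporting numbers are reported
    either way.
    """
    region = ds.snp_mask(chrom, start, end)
    if region.sum() < min_snps:
        raise ValueError(
            f"region {chrom}:{start}-{end} has {int(region.sum())} SNPs; "
            f"need at least {min_snps}"
        )
    pca = pca_region(ds, chrom, start, end)
    karyo = infer_karyotypes(pca["coords"][:, 0])
    het = sample_heterozygosity(ds, chrom, start, end)

    mid = karyo["dosage"].to_numpy() == 1
    outer = ~mid
    if karyo.attrs["n_clusters"] == 3 and mid.any() and outer.any():
        het_ratio = float(np.nanmean(het[mid]) / np.nanmean(het[outer]))
    else:
        het_ratio = np.nan

    inside = ld_r2(ds, chrom, start, end, max_snps=max_ld_snps)["mean_r2"]
    flank_mask = ds.snp_mask(chrom) & ~ds.snp_mask(chrom, start, end)
    if flank_mask.sum() >= 2:
        flank = ld_r2(ds.subset(flank_mask), max_snps=max_ld_snps)["mean_r2"]
        r2_ratio = float(inside / flank) if flank > 0 else np.inf
    else:
        flank, r2_ratio = np.nan, np.nan

    separation = karyo.attrs["separation"]
    is_inversion = bool(
        karyo.attrs["n_clusters"] == 3
        and separation >= min_separation
        and het_ratio >= min_het_ratio
        and r2_ratio >= min_r2_ratio
    )
    return {
        "chrom": chrom,
        "start": start,
        "end": end,
        "n_snps": int(region.sum()),
        "n_clusters": karyo.attrs["n_clusters"],
        "separation": separation,
        "het_ratio": het_ratio,
        "mean_r2_inside": inside,
        "mean_r2_flank": flank,
        "r2_ratio": r2_ratio,
        "pc1_var_explained": float(pca["var_explained"][0]),
        "is_inversion": is_inversion,
        "karyotypes": karyo,
    }


def wilcoxon_assoc(dosage: np.ndarray, phenotype: np.ndarray) -> dict:
    """Wilcoxon rank-sum test of inversion dosage between phenotype groups.

    Uses the normal approximation with tie and continuity corrections.
    The rank-biserial effect (2U/(n1*n0) - 1) is signed so that a positive
    value means phenotype-positive samples carry higher inversion dosage;
    the sign distinguishes gametic coupling from repulsion.
    """
    dosage = np.asarray(dosage, dtype=float)
    phenotype = np.asarray(phenotype)
    x1 = dosage[phenotype == 1]
    x0 = dosage[phenotype == 0]
    if x1.size == 0 or x0.size == 0:
        raise ValueError("both phenotype groups must be non-empty")
    res = stats.mannwhitneyu(
        x1, x0, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    effect = 2.0 * float(res.statistic) / (x1.size * x0.size) - 1.0
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "effect": effect,
        "n_pos": int(x1.size),
        "n_neg": int(x0.size),
    }
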