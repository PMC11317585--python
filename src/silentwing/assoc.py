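"""Per-SNP genotype-phenotype association scan.

Each SNP is tested by ordinary least squares of the binary phenotype (treated
as quantitative, 0/1) on additive allele dosage, with significance from a
Gaussian likelihood-ratio test against the intercept-only model:

    LRT = n * ln(RSS0 / RSS1)  ~  chi-square(1) under the null.

Multiple testing is handled by Bonferroni over the SNPs actually tested in a
scan (monomorphic sites excluded). Outliers are flagged either as the
empirical top 0.1% of LRT statistics (the default reading of "99.9%
significance outliers") or by a nominal raw-p cutoff.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthpop import GenotypeDataset

__all__ = ["SiteFit", "fit_site_lm", "lrt_pvalue", "scan", "call_outliers"]


class SiteFit(NamedTuple):
    """OLS fit of phenotype on dosage at one site (pairwise-complete cases)."""

    slope: float
    rss1: float
    rss0: float
    n: int
    ok: bool  # False: monomorphic or insufficient data, no statistics


def fit_site_lm(genotype: np.ndarray, phenotype: np.ndarray) -> SiteFit:
    """Least-squares slope and residual sums of squares at one SNP.

    Samples missing either value (dosage < 0 or non-finite phenotype) are
    dropped. Sites with fewer than 3 complete cases or zero dosage variance
    are flagged unusable rather than fitted.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.shape != y.shape:
        raise ValueError("genotype and phenotype vectors differ in length")
    keep = (g >= 0) & np.isfinite(g) & np.isfinite(y)
    g, y = g[keep], y[keep]
    n = g.size
    if n < 3:
        return SiteFit(np.nan, np.nan, np.nan, n, False)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        return SiteFit(np.nan, np.nan, np.nan, n, False)
    sxy = float(gc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    rss1 = max(syy - slope * sxy, 0.0)
    return SiteFit(slope, rss1, syy, n, True)


def lrt_pvalue(rss0: float, rss1: float, n: int) -> tuple[float, float, bool]:
    """Gaussian likelihood-ratio statistic and chi-square(1) p-value.

    Returns (statistic, p, separated). A perfect fit (RSS1 = 0 with RSS0 > 0)
    gives p = 0 with the separation flag set; a constant phenotype
    (RSS0 = 0) gives statistic 0, p = 1.
    """
    if rss1 > rss0 * (1 + 1e-9) + 1e-12:
        raise ValueError(f"RSS1={rss1} exceeds RSS0={rss0}; invalid fit")
    if rss0 <= 0.0:
        return 0.0, 1.0, False
    if rss1 <= 0.0:
        return np.inf, 0.0, True
    stat = n * np.log(rss0 / rss1)
    return float(stat), float(stats.chi2.sf(stat, df=1)), False


def scan(
    ds: GenotypeDataset,
    phenotype: str,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> pd.DataFrame:
    """Per-SNP LM/LRT association scan over an optional chromosome/interval.

    Bonferroni-adjusts over the m SNPs tested in this invocation
    (monomorphic sites excluded from m), and returns one row per SNP in
    position order with columns: chrom, pos, n, slope, lrt, p, p_adj,
    monomorphic, separated.
    """
    if phenotype not in ds.samples.columns:
        raise ValueError(f"phenotype column {phenotype!r} not in sample metadata")
    mask = ds.snp_mask(chrom, start, end)
    if not mask.any():
        raise ValueError("no SNPs in the requested region")
    idx = np.flatnonzero(mask)
    y = ds.samples[phenotype].to_numpy(dtype=float)

    rows = []
    for j in idx:
        fit = fit_site_lm(ds.dosages[:, j], y)
        if fit.ok:
            lrt, p, sep = lrt_pvalue(fit.rss0, fit.rss1, fit.n)
        else:
            lrt = p = np.nan
            sep = False
        rows.append(
            {
                "chrom": ds.chrom[j],
                "pos": int(ds.positions[j]),
                "n": fit.n,
                "slope": fit.slope,
                "lrt": lrt,
                "p": p,
                "monomorphic": not fit.ok,
                "separated": sep,
            }
        )
    out = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    m = int((~out["monomorphic"]).sum())
    if m == 0:
        warnings.warn("all sites monomorphic or unusable; nothing tested", stacklevel=2)
    out["p_adj"] = np.minimum(out["p"] * m, 1.0)
    out.attrs["m_tested"] = m
    return out


def call_outliers(
    results: pd.DataFrame,
    quantile: float = 0.999,
    method: str = "empirical",
) -> pd.DataFrame:
    """Flag association outliers and adjusted-p significance.

    ``method="empirical"``: outliers are tested SNPs whose LRT statistic
    exceeds the empirical ``quantile`` (default 99.9th percentile) of tested
    SNPs. ``method="nominal"``: raw p < 1 - quantile. Also adds boolean
    ``sig05``/``sig01`` columns for Bonferroni-adjusted p < 0.05 / 0.01.
    With a single tested SNP the empirical quantile is degenerate: zero
    outliers are returned with a warning.
    """
    if method not in ("empirical", "nominal"):
        raise ValueError("method must be 'empirical' or 'nominal'")
    out = results.copy()
    tested = ~out["monomorphic"]
    if tested.sum() == 0:
        raise ValueError("no tested SNPs to call outliers on")
    out["outlier"] = False
    if method == "nominal":
        out.loc[tested, "outlier"] = out.loc[tested, "p"] < (1.0 - quantile)
    elif tested.sum() < 2:
        warnings.warn("single tested SNP; empirical quantile degenerate, no outliers",
                      stacklevel=2)
    else:
        lrt = out.loc[tested, "lrt"]
        cutoff = np.quantile(lrt.to_numpy(), quantile)
        out.loc[tested, "outlier"] = lrt > cutoff
    out["sig05"] = (out["p_adj"] < 0.05).fillna(False)
    out["sig01"] = (out["p_adj"] < 0.01).fillna(False)
    return out
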