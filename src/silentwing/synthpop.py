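"""Synthetic genotype data emulating a segregating chromosomal inversion.

The generator reproduces, at reduced scale, the genomic architecture found in
Hawaiian field-cricket populations: a large autosomal inversion segregating at
intermediate frequency, whose two arrangements are divergent non-recombining
haplotype pools; a biallelic causal wing-morph locus statistically linked to
the inversion, with incomplete penetrance; population-specific gametic phase
(the causal allele riding the inverted arrangement in some populations,
"coupling", and the standard one in others, "repulsion"); and, optionally, an
X chromosome with hemizygous males.

The emergent signatures downstream code must detect — three PCA clusters,
elevated heterokaryotype heterozygosity, strong within-region LD — are
produced by drawing whole-region haplotypes from arrangement-specific allele
frequency profiles rather than by simulating recombination suppression
mechanistically.

Genotypes are stored as 0/1/2 dosage matrices (int8, -1 = missing). On the X
chromosome, hemizygous males use a "doubled" encoding (0/2) so a single
matrix type serves both chromosome types; VCF export writes male X genotypes
haploid ("0"/"1") and import re-doubles them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SynthSpec",
    "GenotypeDataset",
    "HaplotypePools",
    "make_haplotype_pools",
    "simulate_genotypes",
    "assign_phenotypes",
    "make_dataset",
    "write_vcf",
    "read_vcf",
    "write_metadata",
    "read_metadata",
    "attach_metadata",
    "parse_region",
]

X_CHROM_NAMES = frozenset({"X", "chrX", "chrx", "x"})

PHASES = ("coupling", "repulsion", "unlinked")


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic architecture.

    Defaults emulate the study scale: two wild populations of 90 males each,
    an inversion spanning 7.5-80 Mb at frequency q=0.4, 30% of inversion SNPs
    strongly differentiated between arrangements (d=0.3), a causal locus in
    the 60-70 Mb divergence zone tightly linked (0.95) to the
    phase-designated arrangement, dominant phenotype expression with
    penetrance 0.9 over a 2% background rate. Opposite phase in the two
    populations reproduces the coupling/repulsion sign flip.
    """

    phase: dict = field(
        default_factory=lambda: {"Kauai.CG": "coupling", "Hawaii.UH": "repulsion"}
    )
    n_per_pop: int = 90
    chrom: str = "chr2"
    chrom_length: int = 120_000_000
    n_snps: int = 1200
    inv_start: int = 7_500_000
    inv_end: int = 80_000_000
    q: float = 0.4  # inverted-arrangement frequency
    d: float = 0.3  # fraction of inversion SNPs divergent between arrangements
    theta: float = 0.05  # within-pool minor-allele frequency at divergent SNPs
    causal_pos: int = 65_000_000
    causal_linkage: float = 0.95  # P(causal allele | phase-designated arrangement)
    causal_freq: float = 0.3  # causal allele frequency when phase == "unlinked"
    penetrance: float = 0.9  # P(phenotype | >=1 causal allele), dominant model
    background: float = 0.02  # P(phenotype | no causal allele)
    penetrance_model: str = "dominant"  # or "recessive"
    phenotype_name: str = "Cw"
    male_fraction: float = 1.0  # the study sampled males only
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("q", "d", "theta", "causal_linkage", "causal_freq",
                     "penetrance", "background", "male_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (1 <= self.inv_start < self.inv_end <= self.chrom_length):
            raise ValueError("inversion interval must lie within the chromosome")
        if not (1 <= self.causal_pos <= self.chrom_length):
            raise ValueError("causal_pos must lie within the chromosome")
        if self.penetrance_model not in ("dominant", "recessive"):
            raise ValueError("penetrance_model must be 'dominant' or 'recessive'")
        bad = [p for p in self.phase.values() if p not in PHASES]
        if bad:
            raise ValueError(f"phase values must be in {PHASES}, got {bad}")

    @property
    def x_linked(self) -> bool:
        return self.chrom in X_CHROM_NAMES


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix with positions, chromosome labels and
    per-sample metadata; synthetic datasets also carry a truth table
    (inversion karyotype and causal genotype per sample)."""

    dosages: np.ndarray  # (n_samples, n_snps) int8; -1 = missing
    positions: np.ndarray  # int64, 1-based
    chrom: np.ndarray  # str per SNP
    samples: pd.DataFrame  # columns: sample, sex, population, phenotype flags
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ns, nv = self.dosages.shape
        if len(self.samples) != ns:
            raise ValueError("sample metadata length does not match dosage rows")
        if len(self.positions) != nv or len(self.chrom) != nv:
            raise ValueError("positions/chrom length does not match dosage columns")
        for c in pd.unique(self.chrom):
            pos = self.positions[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions must be strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_mask(self, chrom: str | None = None, start: int | None = None,
                 end: int | None = None) -> np.ndarray:
        """Boolean SNP mask for a chromosome and/or 1-based inclusive interval."""
        mask = np.ones(self.n_snps, dtype=bool)
        if chrom is not None:
            mask &= self.chrom == chrom
        if start is not None:
            mask &= self.positions >= start
        if end is not None:
            mask &= self.positions <= end
        return mask

    def subset(self, snp_mask: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            dosages=self.dosages[:, snp_mask],
            positions=self.positions[snp_mask],
            chrom=self.chrom[snp_mask],
            samples=self.samples,
            truth=self.truth,
        )


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse 'chr2' or 'chr2:7500000-80000000' into (chrom, start, end)."""
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    lo, _, hi = span.partition("-")
    return chrom, int(lo.replace(",", "")), int(hi.replace(",", ""))


@dataclass
class HaplotypePools:
    """Arrangement-specific per-SNP allele frequencies."""

    freq_std: np.ndarray
    freq_inv: np.ndarray
    inv_mask: np.ndarray  # SNPs inside the inversion interval
    divergent: np.ndarray  # SNPs with arrangement-differentiated frequencies


def _draw_positions(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    pos = rng.choice(spec.chrom_length, size=spec.n_snps, replace=False) + 1
    if spec.causal_pos not in pos:
        pos[0] = spec.causal_pos  # claim one slot for the causal locus
    return np.sort(np.unique(pos)).astype(np.int64)


def make_haplotype_pools(
    spec: SynthSpec, rng: np.random.Generator, positions: np.ndarray | None = None
) -> tuple[np.ndarray, HaplotypePools]:
    """Draw per-SNP allele frequencies for the standard and inverted
    arrangement pools.

    Outside the inversion (and at non-divergent SNPs inside it) both pools
    share a common frequency ~ Uniform(0.1, 0.9). A fraction ``d`` of
    inversion SNPs is divergent: frequency ``theta`` on the standard
    arrangement vs ``1 - theta`` on the inverted one.
    """
    if positions is None:
        positions = _draw_positions(spec, rng)
    n = len(positions)
    common = rng.uniform(0.1, 0.9, n)
    inv_mask = (positions >= spec.inv_start) & (positions <= spec.inv_end)
    divergent = inv_mask & (rng.random(n) < spec.d)
    freq_std = np.where(divergent, spec.theta, common)
    freq_inv = np.where(divergent, 1.0 - spec.theta, common)
    return positions, HaplotypePools(freq_std, freq_inv, inv_mask, divergent)


def _draw_haplotypes(
    pools: HaplotypePools, arrangement: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype per row: alleles Bernoulli(pool frequency of the row's
    arrangement) at every SNP. Conditional independence given the arrangement
    is what generates strong arrangement-tagged LD inside the region."""
    freqs = np.where(arrangement[:, None].astype(bool), pools.freq_inv, pools.freq_std)
    return (rng.random(freqs.shape) < freqs).astype(np.int8)


def _causal_allele(
    arrangement: np.ndarray, phase: str, spec: SynthSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-haplotype causal allele: linked to the phase-designated arrangement
    (coupling: inverted, repulsion: standard) with probability
    ``causal_linkage``, or arrangement-independent when phase is 'unlinked'."""
    u = rng.random(len(arrangement))
    if phase == "unlinked":
        return (u < spec.causal_freq).astype(np.int8)
    designated = arrangement == (1 if phase == "coupling" else 0)
    p = np.where(designated, spec.causal_linkage, 1.0 - spec.causal_linkage)
    return (u < p).astype(np.int8)


def simulate_genotypes(spec: SynthSpec, rng: np.random.Generator) -> GenotypeDataset:
    """Generate the genotype matrix for all populations in ``spec.phase``.

    Each diploid sample draws two arrangement labels Bernoulli(q) giving an
    inversion karyotype 0/1/2; whole-region haplotypes come from the matching
    pools; the causal locus occupies the SNP at ``causal_pos``. On an X
    chromosome males draw a single haplotype, encoded as doubled dosage.
    """
    positions, pools = make_haplotype_pools(spec, rng)
    causal_idx = int(np.flatnonzero(positions == spec.causal_pos)[0])
    x = spec.x_linked

    blocks, meta_rows, truth_rows = [], [], []
    for pop, phase in spec.phase.items():
        n = spec.n_per_pop
        male = rng.random(n) < spec.male_fraction
        haploid = x & male
        arr1 = (rng.random(n) < spec.q).astype(np.int8)
        arr2 = (rng.random(n) < spec.q).astype(np.int8)
        hap1 = _draw_haplotypes(pools, arr1, rng)
        hap2 = _draw_haplotypes(pools, arr2, rng)
        hap1[:, causal_idx] = _causal_allele(arr1, phase, spec, rng)
        hap2[:, causal_idx] = _causal_allele(arr2, phase, spec, rng)

        dos = np.where(haploid[:, None], 2 * hap1, hap1 + hap2).astype(np.int8)
        karyo = np.where(haploid, 2 * arr1, arr1 + arr2)
        causal = np.where(
            haploid, 2 * hap1[:, causal_idx], hap1[:, causal_idx] + hap2[:, causal_idx]
        )

        if spec.missing_rate > 0:
            dos[rng.random(dos.shape) < spec.missing_rate] = -1

        blocks.append(dos)
        for i in range(n):
            sid = f"{pop}_{i:03d}"
            meta_rows.append(
                {"sample": sid, "sex": "M" if male[i] else "F", "population": pop}
            )
            truth_rows.append(
                {
                    "sample": sid,
                    "karyotype": int(karyo[i]),
                    "causal_dosage": int(causal[i]),
                    "phase": phase,
                }
            )

    return GenotypeDataset(
        dosages=np.vstack(blocks),
        positions=positions,
        chrom=np.full(len(positions), spec.chrom, dtype=object),
        samples=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
    )


def assign_phenotypes(
    ds: GenotypeDataset, spec: SynthSpec, rng: np.random.Generator
) -> GenotypeDataset:
    """Draw binary phenotypes from the truth causal genotypes.

    Dominant model: any causal copy expresses with probability ``penetrance``;
    non-carriers express at the ``background`` rate. The recessive option
    requires two copies. Incomplete penetrance produces carrier samples
    scored phenotype-negative, as in the real data's misclassified minority.
    """
    if ds.truth is None or "causal_dosage" not in ds.truth:
        raise ValueError("dataset has no causal-genotype truth; generate it first")
    dose = ds.truth["causal_dosage"].to_numpy()
    carrier = dose >= (2 if spec.penetrance_model == "recessive" else 1)
    p = np.where(carrier, spec.penetrance, spec.background)
    pheno = (rng.random(len(p)) < p).astype(np.int8)
    samples = ds.samples.copy()
    samples[spec.phenotype_name] = pheno
    return replace_samples(ds, samples)


def replace_samples(ds: GenotypeDataset, samples: pd.DataFrame) -> GenotypeDataset:
    return GenotypeDataset(ds.dosages, ds.positions, ds.chrom, samples, ds.truth)


def make_dataset(spec: SynthSpec, rng: np.random.Generator) -> GenotypeDataset:
    """Convenience: simulate genotypes and assign phenotypes in one call."""
    return assign_phenotypes(simulate_genotypes(spec, rng), spec, rng)


# ---------------------------------------------------------------------------
# I/O: minimal VCF v4.2 (GT-only) + TSV metadata


def _is_x(chrom: str) -> bool:
    return chrom in X_CHROM_NAMES


def write_vcf(ds: GenotypeDataset, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT (REF=A, ALT=T throughout).

    Male samples on X chromosomes are written haploid ("0"/"1"); everything
    else diploid unphased; missing as "./." (or "." haploid).
    """
    path = Path(path)
    male = (
        (ds.samples["sex"].to_numpy() == "M")
        if "sex" in ds.samples
        else np.zeros(ds.n_samples, bool)
    )
    order = np.lexsort((ds.positions, ds.chrom.astype(str)))
    dip = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    hap = {-1: ".", 0: "0", 2: "1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(ds.chrom[order]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples["sample"]) + "\n"
        )
        for j in order:
            chrom = str(ds.chrom[j])
            haploid = male if _is_x(chrom) else np.zeros(ds.n_samples, bool)
            gts = [
                hap[int(d)] if h else dip[int(d)]
                for d, h in zip(ds.dosages[:, j], haploid)
            ]
            fh.write(
                f"{chrom}\t{int(ds.positions[j])}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeDataset:
    """Read a GT-only VCF into a GenotypeDataset.

    Haploid calls (male X) are re-doubled: "1" -> dosage 2. Sample metadata
    holds ids only; join sex/population/phenotypes with attach_metadata().
    Raises ValueError with the offending line number on malformed records.
    """
    path = Path(path)
    with open(path) as fh:
        n_header = sum(1 for line in fh if line.startswith("#"))
    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    dosages, positions, chroms = [], [], []
    i = 0
    try:
        for rec in vf:
            row = np.empty(len(sample_ids), dtype=np.int8)
            for k, s in enumerate(rec.samples.values()):
                gt = s["GT"]
                if gt is None or all(a is None for a in gt):
                    row[k] = -1
                elif len(gt) == 1:  # haploid: re-double
                    row[k] = 2 * int(gt[0])
                else:
                    row[k] = int(gt[0]) + int(gt[1])
            dosages.append(row)
            positions.append(rec.pos)
            chroms.append(rec.chrom)
            i += 1
    except Exception as err:  # noqa: BLE001 - re-raise with location
        raise ValueError(
            f"malformed VCF record at line {n_header + i + 1} of {path}: {err}"
        ) from err
    if not dosages:
        raise ValueError(f"no variant records in {path}")
    return GenotypeDataset(
        dosages=np.array(dosages, dtype=np.int8).T,
        positions=np.array(positions, dtype=np.int64),
        chrom=np.array(chroms, dtype=object),
        samples=pd.DataFrame({"sample": sample_ids}),
    )


def write_metadata(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the per-sample metadata table as TSV."""
    ds.samples.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample" not in meta.columns:
        raise ValueError(f"metadata {path} lacks a 'sample' column")
    return meta


def attach_metadata(ds: GenotypeDataset, meta: pd.DataFrame) -> GenotypeDataset:
    """Join a metadata table onto the dataset's samples (by id, order kept).

    Raises on samples present in the genotypes but absent from the metadata.
    """
    missing = set(ds.samples["sample"]) - set(meta["sample"])
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
    merged = ds.samples[["sample"]].merge(meta, on="sample", how="left")
    return replace_samples(ds, merged)
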