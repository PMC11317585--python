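"""Tests for the inversion diagnostics: F_ST, heterozygosity, LD, PCA,
karyotype inference, inversion calling and Wilcoxon association."""

import itertools

import numpy as np
import pandas as pd
import pytest

from silentwing.popscan import (
    detect_inversion,
    fst_windows,
    groups_from_column,
    infer_karyotypes,
    ld_r2,
    pca_region,
    sample_heterozygosity,
    wc_fst_components,
    wc_fst_site,
    wilcoxon_assoc,
)
from silentwing.synthpop import GenotypeDataset, SynthSpec, make_dataset


# --- independent oracle: literal transcription of the Weir & Cockerham (1984)
# two-allele variance components, computed from genotype count tables -------

def wc_oracle(counts1, counts2):
    """counts_i = (n_AA, n_Aa, n_aa) in group i; returns (a, b, c)."""
    r = 2
    groups = [counts1, counts2]
    n = [sum(g) for g in groups]
    p = [(2 * g[0] + g[1]) / (2 * ni) for g, ni in zip(groups, n)]
    h = [g[1] / ni for g, ni in zip(groups, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def dosages_from_counts(counts):
    return np.repeat([2, 1, 0], counts)


class TestWcFst:
    def test_fixed_difference_theta_one(self):
        comp = wc_fst_site([0] * 10, [2] * 10)
        assert comp.theta == pytest.approx(1.0, abs=1e-15)

    def test_identical_groups_theta_nonpositive(self):
        g = [0, 0, 1, 1, 2, 2, 1, 0, 2, 1]
        comp = wc_fst_site(g, g)
        assert comp.usable and comp.theta <= 0

    def test_worked_count_table_matches_oracle(self):
        g1 = dosages_from_counts((4, 4, 2))
        g2 = dosages_from_counts((1, 4, 5))
        comp = wc_fst_site(g1, g2)
        a, b, c = wc_oracle((4, 4, 2), (1, 4, 5))
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.b == pytest.approx(b, abs=1e-12)
        assert comp.c == pytest.approx(c, abs=1e-12)

    def test_random_sites_match_oracle(self):
        """100 random two-group sites agree with the independent formula
        transcription to 1e-12."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            c1 = tuple(rng.integers(0, 12, 3) + np.array([1, 1, 0]))
            c2 = tuple(rng.integers(0, 12, 3) + np.array([0, 1, 1]))
            comp = wc_fst_site(dosages_from_counts(c1), dosages_from_counts(c2))
            a, b, c = wc_oracle(c1, c2)
            if comp.usable:
                assert comp.a == pytest.approx(a, abs=1e-12)
                assert comp.b == pytest.approx(b, abs=1e-12)
                assert comp.c == pytest.approx(c, abs=1e-12)

    def test_small_group_or_monomorphic_excluded(self):
        assert not wc_fst_site([1], [0, 1, 2]).usable
        assert not wc_fst_site([0, 0, 0], [0, 0, 0]).usable

    def test_missing_genotypes_reduce_sample_size(self):
        full = wc_fst_site([0, 0, 1, 2], [2, 2, 1, 0])
        miss = wc_fst_site([0, 0, 1, 2, -1], [2, 2, 1, 0, -1])
        assert full.a == pytest.approx(miss.a, abs=1e-15)


class TestFstWindows:
    def make_ds(self, g1, g2, positions):
        dos = np.vstack([g1, g2]).astype(np.int8)
        n1, n2 = len(g1), len(g2)
        samples = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(n1 + n2)],
             "grp": ["a"] * n1 + ["b"] * n2}
        )
        return GenotypeDataset(
            np.vstack([np.asarray(g1), np.asarray(g2)]).astype(np.int8),
            np.asarray(positions, np.int64),
            np.full(len(positions), "chr1", object), samples,
        )

    def test_single_snp_window_equals_site_theta(self):
        rng = np.random.default_rng(3)
        g1 = rng.integers(0, 3, (8, 5))
        g2 = rng.integers(0, 3, (8, 5))
        ds = GenotypeDataset(
            np.vstack([g1, g2]).astype(np.int8),
            np.array([100, 20_100, 40_100, 60_100, 80_100], np.int64),
            np.full(5, "chr1", object),
            pd.DataFrame({"sample": [f"s{i}" for i in range(16)],
                          "grp": ["a"] * 8 + ["b"] * 8}),
        )
        groups = groups_from_column(ds, "grp", ("a", "b"))
        tab = fst_windows(ds, groups, window=10_000, step=10_000)
        for j, pos in enumerate(ds.positions):
            site = wc_fst_site(g1[:, j], g2[:, j])
            row = tab[(tab.start <= pos) & (pos < tab.end)].iloc[0]
            if site.usable:
                assert row["fst"] == pytest.approx(site.theta, abs=1e-12)
                assert row["n_snps"] == 1

    def test_window_weighting_is_sum_a_over_sum_abc(self):
        rng = np.random.default_rng(4)
        g1 = rng.integers(0, 3, (10, 40))
        g2 = rng.integers(0, 3, (10, 40))
        pos = np.sort(rng.choice(9_000, 40, replace=False)) + 1
        ds = GenotypeDataset(
            np.vstack([g1, g2]).astype(np.int8), pos.astype(np.int64),
            np.full(40, "chr1", object),
            pd.DataFrame({"sample": [f"s{i}" for i in range(20)],
                          "grp": ["a"] * 10 + ["b"] * 10}),
        )
        groups = groups_from_column(ds, "grp", ("a", "b"))
        tab = fst_windows(ds, groups, window=10_000, step=10_000)
        a, b, c, usable = wc_fst_components(ds.dosages, *groups)
        expected = np.nansum(a[usable]) / np.nansum((a + b + c)[usable])
        assert tab.iloc[0]["fst"] == pytest.approx(expected, abs=1e-12)

    def test_empty_windows_reported_missing(self):
        ds = self.make_ds([[0, 2]] * 4, [[2, 0]] * 4, [100, 95_000])
        groups = groups_from_column(ds, "grp", ("a", "b"))
        tab = fst_windows(ds, groups, window=10_000, step=10_000, start=1, end=100_000)
        assert len(tab) == 10
        middle = tab.iloc[3]
        assert middle["n_snps"] == 0 and np.isnan(middle["fst"])

    def test_permuted_labels_center_near_zero(self, default_dataset):
        ds = default_dataset
        rng = np.random.default_rng(9)
        perm = rng.permutation(ds.n_samples)
        g1 = np.zeros(ds.n_samples, bool)
        g1[perm[: ds.n_samples // 2]] = True
        tab = fst_windows(ds, (g1, ~g1), window=1_000_000, step=1_000_000)
        vals = tab["fst"].dropna().to_numpy()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se


class TestHeterozygosityAndLD:
    def test_het_extremes(self):
        ds = GenotypeDataset(
            np.array([[1, 1, 1], [0, 2, 0], [1, -1, -1]], np.int8),
            np.array([10, 20, 30], np.int64), np.full(3, "c", object),
            pd.DataFrame({"sample": list("abc")}),
        )
        het = sample_heterozygosity(ds)
        assert het[0] == 1.0 and het[1] == 0.0 and het[2] == 1.0

    def test_het_missing_sample_is_nan(self):
        ds = GenotypeDataset(
            np.array([[-1, -1], [0, 1]], np.int8),
            np.array([10, 20], np.int64), np.full(2, "c", object),
            pd.DataFrame({"sample": list("ab")}),
        )
        assert np.isnan(sample_heterozygosity(ds)[0])

    def test_duplicated_snp_r2_one_and_orthogonal_zero(self):
        dos = np.array(
            [[0, 0, 0], [0, 0, 2], [2, 2, 0], [2, 2, 2]], np.int8
        )  # col0 == col1; col2 orthogonal to col0
        ds = GenotypeDataset(
            dos, np.array([10, 20, 30], np.int64), np.full(3, "c", object),
            pd.DataFrame({"sample": list("abcd")}),
        )
        r2 = ld_r2(ds)["r2"]
        assert r2[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert r2[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_region_ld_exceeds_background(self, default_dataset):
        inside = ld_r2(default_dataset, "chr2", 7_500_000, 80_000_000, max_snps=150)
        flank = default_dataset.snp_mask("chr2") & ~default_dataset.snp_mask(
            "chr2", 7_500_000, 80_000_000
        )
        outside = ld_r2(default_dataset.subset(flank), max_snps=150)
        assert inside["mean_r2"] > 2 * outside["mean_r2"]

    def test_monomorphic_snps_skipped(self):
        dos = np.array([[0, 1], [0, 2], [0, 0], [0, 1]], np.int8)
        ds = GenotypeDataset(
            dos, np.array([10, 20], np.int64), np.full(2, "c", object),
            pd.DataFrame({"sample": list("abcd")}),
        )
        with pytest.raises(ValueError, match="polymorphic"):
            ld_r2(ds)


class TestPcaAndKaryotypes:
    def test_identical_samples_identical_coordinates(self, rng):
        row = rng.integers(0, 3, 30)
        dos = np.vstack([row, row, rng.integers(0, 3, 30), rng.integers(0, 3, 30)])
        ds = GenotypeDataset(
            dos.astype(np.int8), np.arange(1, 31, dtype=np.int64) * 10,
            np.full(30, "c", object), pd.DataFrame({"sample": list("abcd")}),
        )
        coords = pca_region(ds)["coords"]
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-10)

    def test_coordinates_invariant_under_sample_reordering(self, default_dataset):
        ds = default_dataset
        res1 = pca_region(ds, "chr2", 7_500_000, 80_000_000)
        perm = np.random.default_rng(1).permutation(ds.n_samples)
        ds2 = GenotypeDataset(ds.dosages[perm], ds.positions, ds.chrom,
                              ds.samples.iloc[perm].reset_index(drop=True))
        res2 = pca_region(ds2, "chr2", 7_500_000, 80_000_000)
        np.testing.assert_allclose(res1["coords"][perm, 0], res2["coords"][:, 0],
                                   atol=1e-8)

    def test_degenerate_matrix_raises(self):
        ds = GenotypeDataset(
            np.ones((4, 5), np.int8), np.arange(1, 6, dtype=np.int64),
            np.full(5, "c", object), pd.DataFrame({"sample": list("abcd")}),
        )
        with pytest.raises(ValueError, match="degenerate|constant"):
            pca_region(ds)

    def test_three_well_separated_groups(self):
        pc1 = np.array([-10.0] * 5 + [0.0] * 5 + [10.0] * 5)
        calls = infer_karyotypes(pc1)
        assert calls.attrs["n_clusters"] == 3
        assert calls.attrs["separation"] > 0.9
        np.testing.assert_array_equal(calls["dosage"], [0] * 5 + [1] * 5 + [2] * 5)

    def test_constant_pc1_single_cluster(self):
        calls = infer_karyotypes(np.zeros(12))
        assert calls.attrs["n_clusters"] == 1
        assert calls["dosage"].nunique() == 1

    def test_karyotype_accuracy_on_default_architecture(self, default_dataset):
        """Three PC1 clusters recover the true inversion karyotypes with
        >=95% accuracy (up to the 0<->2 arrangement flip)."""
        ds = default_dataset
        pca = pca_region(ds, "chr2", 7_500_000, 80_000_000)
        calls = infer_karyotypes(pca["coords"][:, 0])
        truth = ds.truth["karyotype"].to_numpy()
        call = calls["dosage"].to_numpy()
        acc = max((call == truth).mean(), ((2 - call) == truth).mean())
        assert calls.attrs["n_clusters"] == 3
        assert acc >= 0.95


class TestDetectInversion:
    def test_positive_call_on_default_architecture(self, default_dataset):
        rep = detect_inversion(default_dataset, "chr2", 7_500_000, 80_000_000)
        assert rep["is_inversion"]
        assert rep["n_clusters"] == 3
        assert rep["het_ratio"] >= 1.5
        assert rep["r2_ratio"] >= 2

    def test_negative_call_without_inversion(self, rng):
        ds = make_dataset(SynthSpec(q=0.0), rng)
        rep = detect_inversion(ds, "chr2", 7_500_000, 80_000_000)
        assert not rep["is_inversion"]

    def test_region_too_small_raises(self, default_dataset):
        with pytest.raises(ValueError, match="need at least"):
            detect_inversion(default_dataset, "chr2", 1, 5, min_snps=20)

    def test_neutral_x_inversion_with_unlinked_causal_locus(self):
        """A mixed-sex X dataset with a neutral inversion and a separate
        causal locus: the inversion is called, but association outliers lie
        outside the inversion interval."""
        from silentwing.assoc import call_outliers, scan

        spec = SynthSpec(
            chrom="chrX", chrom_length=300_000_000, n_snps=900,
            inv_start=95_700_000, inv_end=253_200_000, q=0.5,
            causal_pos=259_200_000, phase={"Oahu.CC": "unlinked"},
            n_per_pop=90, male_fraction=0.5, penetrance=0.95, background=0.0,
        )
        ds = make_dataset(spec, np.random.default_rng(8))
        rep = detect_inversion(ds, "chrX", 95_700_000, 253_200_000)
        assert rep["is_inversion"]
        res = call_outliers(scan(ds, "Cw"), quantile=0.995)
        best = res.loc[res["p_adj"].idxmin()]
        assert best["pos"] == spec.causal_pos  # top hit outside the inversion
        assert not 95_700_000 <= best["pos"] <= 253_200_000
        # karyotype does not separate the phenotype groups strongly
        karyo = ds.truth["karyotype"].to_numpy()
        w = wilcoxon_assoc(karyo, ds.samples["Cw"].to_numpy())
        assert abs(w["effect"]) < 0.5


class TestWilcoxon:
    def test_extreme_separation(self):
        res = wilcoxon_assoc([2, 2, 2, 0, 0, 0], [1, 1, 1, 0, 0, 0])
        assert res["effect"] == 1.0
        assert res["p"] < 0.1  # smallest attainable at n=3+3 (asymptotic)

    def test_identical_distributions(self):
        res = wilcoxon_assoc([0, 1, 2, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert res["p"] > 0.9 and abs(res["effect"]) < 1e-12

    def test_statistic_matches_exact_enumeration(self):
        """Rank-sum U for group1={0,1,1,2} vs group2={0,0,1,1} equals the
        midrank computation, and the asymptotic p is close to the exact
        enumeration p over all C(8,4) rank assignments."""
        x1, x0 = [0, 1, 1, 2], [0, 0, 1, 1]
        pooled = np.array(x1 + x0, dtype=float)
        ranks = pd.Series(pooled).rank().to_numpy()  # midranks
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        res = wilcoxon_assoc(np.array(x1 + x0), np.array([1] * 4 + [0] * 4))
        assert res["statistic"] == pytest.approx(u_obs)
        # exact null: all ways to assign 4 of the 8 observations to group 1
        stats_null = []
        for idx in itertools.combinations(range(8), 4):
            stats_null.append(ranks[list(idx)].sum() - 10)
        stats_null = np.array(stats_null)
        mid = 4 * 4 / 2
        p_exact = np.mean(np.abs(stats_null - mid) >= abs(u_obs - mid) - 1e-12)
        # at n=4+4 with ties the normal approximation is crude; both must at
        # least agree the difference is non-significant
        assert res["p"] > 0.05 and p_exact > 0.05

    def test_asymptotic_p_matches_permutation_at_moderate_n(self):
        """At the study's sample sizes (n~30 per group) the tie/continuity-
        corrected normal approximation agrees with a permutation null."""
        rng = np.random.default_rng(15)
        dosage = rng.integers(0, 3, 60)
        pheno = np.repeat([1, 0], 30)
        res = wilcoxon_assoc(dosage, pheno)
        obs = abs(res["statistic"] - 30 * 30 / 2)
        null = []
        for _ in range(20_000):
            perm = rng.permutation(dosage)
            ranks = pd.Series(perm[:30].tolist() + perm[30:].tolist()).rank()
            u = ranks[:30].sum() - 30 * 31 / 2
            null.append(abs(u - 450))
        p_perm = np.mean(np.array(null) >= obs - 1e-9)
        assert res["p"] == pytest.approx(p_perm, abs=0.03)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_assoc([1, 2], [1, 1])

    def test_phase_flip_gives_opposite_signed_effects(self, default_dataset):
        """Opposite gametic phase in the two populations flips the sign of
        the karyotype-phenotype effect, while the pooled per-SNP scan still
        ranks the causal SNP first."""
        from silentwing.assoc import scan

        ds = default_dataset
        pheno = ds.samples["Cw"].to_numpy()
        karyo = ds.truth["karyotype"].to_numpy()
        effects = {}
        for pop in ("Kauai.CG", "Hawaii.UH"):
            m = (ds.samples["population"] == pop).to_numpy()
            effects[pop] = wilcoxon_assoc(karyo[m], pheno[m])
        assert effects["Kauai.CG"]["effect"] * effects["Hawaii.UH"]["effect"] < 0
        assert effects["Kauai.CG"]["p"] < 0.01 and effects["Hawaii.UH"]["p"] < 0.01
        res = scan(ds, "Cw")
        assert res.loc[res["p_adj"].idxmin(), "pos"] == 65_000_000
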