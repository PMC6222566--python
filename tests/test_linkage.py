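"""Unit and property tests for marker QC, the regression scan, and FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aggscan as ag
from aggscan.linkage import _pairwise_r2
from aggscan.synthdata import LAB, MISSING, VINEYARD


def geno_from_array(alleles, chrom=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_strains, n_markers = alleles.shape
    chrom = chrom or ["c1"] * n_markers
    meta = pd.DataFrame(
        {"chrom": chrom, "pos": _positions(chrom), "name": [f"m{j + 1}" for j in range(n_markers)]}
    )
    return ag.GenotypeMatrix(alleles, meta, [f"s{i}" for i in range(n_strains)])


def _positions(chrom):
    pos, counter = [], {}
    for c in chrom:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c])
    return pos


def pheno(geno, values):
    return ag.PhenotypeTable(list(geno.strain_ids), np.asarray(values, dtype=float))


class TestPruneMarkers:
    def test_duplicate_markers_keep_one(self, toy_genotypes):
        pruned, log = ag.prune_markers(toy_genotypes)
        assert "m1" not in pruned.marker_names  # earlier member of the pair dropped
        assert "m2" in pruned.marker_names
        assert log.loc[log.marker == "m1", "reason"].item() == "r2"

    def test_monomorphic_marker_removed_for_maf(self, toy_genotypes):
        _, log = ag.prune_markers(toy_genotypes)
        assert log.loc[log.marker == "m5", "reason"].item() == "maf"

    def test_low_maf_removed(self):
        # 9 LAB, 1 VINEYARD: MAF 0.10 < 0.25
        col = np.array([[LAB]] * 9 + [[VINEYARD]], dtype=np.int8)
        g = geno_from_array(col)
        pruned, log = ag.prune_markers(g)
        assert pruned.n_markers == 0
        assert log.reason.item() == "maf"

    def test_excess_missing_removed(self):
        col = np.array([[LAB], [VINEYARD], [MISSING], [MISSING], [LAB], [VINEYARD]] * 2)
        g = geno_from_array(col.astype(np.int8))
        _, log = ag.prune_markers(g)
        assert log.reason.item() == "missing"

    @staticmethod
    def _brute_force_prune(geno, params):
        """Direct list-manipulation oracle for the default pruning rule."""
        alleles = geno.alleles
        retained = []
        removed = {}
        for j in range(geno.n_markers):
            if (alleles[:, j] != MISSING).sum() < 2:
                removed[j] = "insufficient_data"
                continue
            while retained and _pairwise_r2(alleles[:, retained[-1]], alleles[:, j]) > params.r2_max:
                removed[retained.pop()] = "r2"
            retained.append(j)
        final = []
        for j in retained:
            col = alleles[:, j]
            if (col == MISSING).sum() > params.max_missing:
                removed[j] = "missing"
                continue
            f = (col[col != MISSING] == LAB).mean()
            if min(f, 1 - f) < params.maf_min:
                removed[j] = "maf"
                continue
            final.append(j)
        return final, removed

    def test_matches_bruteforce_oracle_on_toy_chromosomes(self):
        rng = np.random.default_rng(50)
        params = ag.PruneParams()
        for trial in range(20):
            # blocks of near-duplicate markers with occasional noise and missing
            base = rng.integers(0, 2, (30, 1))
            cols = []
            for _ in range(6):
                col = base.copy() if rng.random() < 0.6 else rng.integers(0, 2, (30, 1))
                flip = rng.random((30, 1)) < 0.05
                col = np.where(flip, 1 - col, col)
                base = col.copy()  # flip-before-missing keeps codes valid
                miss = rng.random((30, 1)) < 0.03
                col = np.where(miss, MISSING, col)
                cols.append(col)
            g = geno_from_array(np.hstack(cols))
            pruned, log = ag.prune_markers(g, params)
            expect_keep, expect_removed = self._brute_force_prune(g, params)
            assert pruned.marker_names == [f"m{j + 1}" for j in expect_keep]
            got = dict(zip(log.marker, log.reason))
            assert got == {f"m{j + 1}": r for j, r in expect_removed.items()}

    def test_endpoint_property_on_retained_set(self):
        g = ag.simulate_cross(60, [40, 40], recomb_prob=0.01, missing_rate=0.01, seed=51)
        params = ag.PruneParams()
        pruned, log = ag.prune_markers(g, params)
        # every surviving adjacent pair within a chromosome has R^2 <= r2_max
        meta = pruned.marker_meta
        for chrom in meta.chrom.unique():
            idx = np.flatnonzero((meta.chrom == chrom).to_numpy())
            for a, b in zip(idx[:-1], idx[1:]):
                assert _pairwise_r2(pruned.alleles[:, a], pruned.alleles[:, b]) <= params.r2_max
        # surviving markers satisfy missing and MAF rules
        for j in range(pruned.n_markers):
            col = pruned.alleles[:, j]
            assert (col == MISSING).sum() <= params.max_missing
            f = (col[col != MISSING] == LAB).mean()
            assert min(f, 1 - f) >= params.maf_min
        # arithmetic balances: kept + removed = total
        assert pruned.n_markers + len(log) == g.n_markers


class TestLinkageScan:
    def test_noiseless_perfect_fit(self):
        g = ag.simulate_cross(50, [3], recomb_prob=0.5, seed=52)
        y = 5.0 + 10.0 * (g.alleles[:, 1] == VINEYARD)
        scan = ag.linkage_scan(g, pheno(g, y))
        row = scan.table.iloc[1]
        assert row["slope"] == pytest.approx(10.0)
        assert row["p"] < 1e-15

    def test_equals_pooled_ttest(self):
        rng = np.random.default_rng(53)
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(20, 61))
            g = ag.simulate_cross(n, [5, 7], recomb_prob=0.4, missing_rate=0.05,
                                  seed=int(rng.integers(2**31)))
            y = np.clip(rng.normal(10, 3, n), 0, 100)
            scan = ag.linkage_scan(g, pheno(g, y))
            for j in range(g.n_markers):
                row = scan.table.iloc[j]
                if not row["defined"]:
                    continue
                a = g.alleles[:, j]
                ok = a != MISSING
                t, p_ref = stats.ttest_ind(
                    y[ok & (a == LAB)], y[ok & (a == VINEYARD)], equal_var=True
                )
                worst = max(worst, abs(p_ref - row["p"]))
        assert worst < 1e-10

    def test_allele_coding_swap_invariance(self):
        g = ag.simulate_cross(80, [10], recomb_prob=0.4, missing_rate=0.05, seed=54)
        rng = np.random.default_rng(55)
        y = np.clip(rng.normal(15, 4, 80), 0, 100)
        scan1 = ag.linkage_scan(g, pheno(g, y))
        swapped = g.alleles.copy()
        swapped[swapped != MISSING] = 1 - swapped[swapped != MISSING]
        g2 = ag.GenotypeMatrix(swapped, g.marker_meta, g.strain_ids)
        scan2 = ag.linkage_scan(g2, pheno(g2, y))
        d1, d2 = scan1.table, scan2.table
        assert np.allclose(d1["slope"], -d2["slope"], equal_nan=True)
        assert np.allclose(d1["p"], d2["p"], equal_nan=True)

    def test_null_p_values_uniform(self):
        g = ag.simulate_cross(200, [100] * 10, recomb_prob=0.5, seed=56)
        rng = np.random.default_rng(57)
        y = np.clip(rng.normal(10, 2, 200), 0, 100)
        scan = ag.linkage_scan(g, pheno(g, y))
        frac = (scan.p[scan.defined] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_monomorphic_marker_flagged_not_dropped(self):
        alleles = np.column_stack(
            [np.zeros(20, dtype=np.int8), np.tile([0, 1], 10).astype(np.int8)]
        )
        g = geno_from_array(alleles)
        rng = np.random.default_rng(58)
        scan = ag.linkage_scan(g, pheno(g, rng.uniform(0, 30, 20)))
        assert len(scan.table) == 2
        assert not scan.table["defined"].iloc[0]
        assert np.isnan(scan.table["p"].iloc[0])
        assert scan.table["defined"].iloc[1]

    def test_zero_phenotype_variance_undefined(self):
        g = ag.simulate_cross(30, [4], recomb_prob=0.5, seed=59)
        scan = ag.linkage_scan(g, pheno(g, np.full(30, 7.0)))
        assert not scan.table["defined"].any()

    def test_mismatched_strains_rejected(self):
        g = ag.simulate_cross(10, [4], seed=60)
        p = ag.PhenotypeTable([f"x{i}" for i in range(10)], np.zeros(10))
        with pytest.raises(ValueError, match="strain ids"):
            ag.linkage_scan(g, p)


class TestPermutationFdr:
    def test_exhaustive_tiny_instance_matches_hand_enumeration(self):
        # 3 strains, 2 markers: all 6 phenotype permutations enumerated by
        # hand with linregress as the independent per-marker oracle
        alleles = np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8)
        g = geno_from_array(alleles)
        y = np.array([1.0, 2.0, 4.0])
        fdr = ag.permutation_fdr(g, pheno(g, y), exhaustive=True)

        def marker_p(x, yy):
            return stats.linregress(x, yy).pvalue

        x1, x2 = alleles[:, 0].astype(float), alleles[:, 1].astype(float)
        p_real = [marker_p(x1, y), marker_p(x2, y)]
        thresholds = sorted(set(p_real), reverse=True)
        hand_rows = []
        for thr in thresholds:
            real = sum(1 for p in p_real if p <= thr)
            perm_total = 0
            for perm in itertools.permutations(y):
                yy = np.asarray(perm)
                perm_total += sum(
                    1 for p in (marker_p(x1, yy), marker_p(x2, yy)) if p <= thr
                )
            hand_rows.append((thr, perm_total / 6.0, real))
        tab = fdr.table
        assert fdr.n_perm == 6
        for (thr, mean_perm, real), (_, row) in zip(hand_rows, tab.iterrows()):
            assert row["threshold"] == pytest.approx(thr, abs=1e-12)
            assert row["mean_permuted_hits"] == pytest.approx(mean_perm, abs=1e-12)
            assert row["real_hits"] == real
            assert row["fdr"] == pytest.approx(mean_perm / real, abs=1e-12)

    def test_null_fdr_near_one(self):
        g = ag.simulate_cross(100, [30] * 4, recomb_prob=0.4, seed=61)
        rng = np.random.default_rng(62)
        y = np.clip(rng.normal(10, 2, 100), 0, 100)
        fdr = ag.permutation_fdr(g, pheno(g, y), n_perm=100, seed=63)
        tab = fdr.table
        stable = tab[tab.real_hits >= 20]
        assert len(stable) > 0
        assert np.all(np.abs(stable.fdr - 1.0) < 0.5)

    def test_planted_qtl_low_fdr_at_peak(self):
        for seed in range(3):
            g = ag.simulate_cross(200, [20] * 5, recomb_prob=0.3, seed=70 + seed)
            truth = ag.CrossTruth(
                qtl=[(50, 2 * np.sqrt(40.0))], baseline=30.0,
                noise_sd=np.sqrt(60.0), seed=80 + seed,
            )
            p = ag.simulate_phenotypes(g, truth)
            scan = ag.linkage_scan(g, p)
            fdr = ag.permutation_fdr(g, p, n_perm=50, seed=90 + seed)
            peak_p = np.nanmin(scan.p)
            at_peak = fdr.table[fdr.table.threshold >= peak_p].iloc[-1]
            assert at_peak.fdr < 0.2

    def test_real_hits_monotone_and_seeded_reproducible(self):
        g = ag.simulate_cross(60, [25], recomb_prob=0.3, seed=64)
        rng = np.random.default_rng(65)
        y = np.clip(rng.normal(10, 2, 60), 0, 100)
        f1 = ag.permutation_fdr(g, pheno(g, y), n_perm=20, seed=66)
        f2 = ag.permutation_fdr(g, pheno(g, y), n_perm=20, seed=66)
        pd.testing.assert_frame_equal(f1.table, f2.table)
        hits = f1.table.real_hits.to_numpy()
        assert np.all(np.diff(hits) <= 0)  # thresholds decrease down the table


class TestVarianceExplained:
    def test_exact_additive_model_r2_one(self):
        g = ag.simulate_cross(100, [5, 5], recomb_prob=0.5, seed=67)
        y = 10.0 + 8.0 * (g.alleles[:, 2] == LAB) + 4.0 * (g.alleles[:, 7] == LAB)
        vr = ag.variance_explained(g, pheno(g, y), [g.marker_names[2], g.marker_names[7]])
        assert vr.joint_r2 == pytest.approx(1.0)
        assert vr.rank == 3

    def test_single_marker_equals_squared_correlation(self):
        g = ag.simulate_cross(120, [8], recomb_prob=0.4, seed=68)
        rng = np.random.default_rng(69)
        y = np.clip(5 + 6 * (g.alleles[:, 3] == LAB) + rng.normal(0, 3, 120), 0, 100)
        name = g.marker_names[3]
        vr = ag.variance_explained(g, pheno(g, y), [name])
        r = np.corrcoef(g.alleles[:, 3].astype(float), y)[0, 1]
        assert vr.single_r2[name] == pytest.approx(r * r, abs=1e-10)
        assert vr.joint_r2 == pytest.approx(r * r, abs=1e-10)

    def test_joint_at_least_max_single(self):
        g = ag.simulate_cross(150, [10, 10], recomb_prob=0.3, seed=71)
        truth = ag.CrossTruth(qtl=[(3, 8.0), (15, -5.0)], baseline=20.0, noise_sd=4.0, seed=72)
        p = ag.simulate_phenotypes(g, truth)
        names = [g.marker_names[3], g.marker_names[15]]
        vr = ag.variance_explained(g, p, names)
        assert vr.joint_r2 >= max(vr.single_r2.values()) - 1e-12

    def test_collinear_markers_reduced_rank(self):
        alleles = np.tile(np.array([[0], [1]], dtype=np.int8), (10, 2))
        g = geno_from_array(alleles)
        rng = np.random.default_rng(73)
        y = rng.uniform(0, 30, 20)
        vr = ag.variance_explained(g, pheno(g, y), ["m1", "m2"])
        assert vr.rank == 2  # intercept + one independent column

    def test_unknown_marker_rejected(self):
        g = ag.simulate_cross(20, [4], seed=74)
        with pytest.raises(KeyError):
            ag.variance_explained(g, pheno(g, np.zeros(20)), ["nope"])


class TestCallPeaks:
    def _null_fdr_table(self):
        return ag.FDRTable(
            table=pd.DataFrame(
                {"threshold": [0.05], "mean_permuted_hits": [0.0],
                 "real_hits": [1], "fdr": [0.0]}
            ),
            n_perm=10,
        )

    def test_all_p_one_gives_empty(self):
        g = ag.simulate_cross(30, [5], recomb_prob=0.5, seed=75)
        scan = ag.linkage_scan(g, pheno(g, np.full(30, 3.0)))  # all undefined
        peaks = ag.call_peaks(scan, self._null_fdr_table(), fdr_ceiling=0.5)
        assert len(peaks) == 0

    def test_two_planted_qtl_recovered_as_two_peaks(self):
        found = 0
        for seed in range(20):
            g = ag.simulate_cross(300, [30, 30], recomb_prob=0.15, seed=100 + seed)
            truth = ag.CrossTruth(
                qtl=[(10, 15.0), (45, -12.0)], baseline=30.0, noise_sd=3.0,
                seed=200 + seed,
            )
            p = ag.simulate_phenotypes(g, truth)
            scan = ag.linkage_scan(g, p)
            fdr = ag.permutation_fdr(g, p, n_perm=30, seed=300 + seed)
            peaks = ag.call_peaks(scan, fdr, fdr_ceiling=0.005, merge_gap=3)
            idx = sorted(g.marker_index(m) for m in peaks.marker)
            if len(idx) == 2 and abs(idx[0] - 10) <= 2 and abs(idx[1] - 45) <= 2:
                found += 1
        assert found >= 18

    def test_zero_ceiling_requires_zero_permuted_hits(self):
        g = ag.simulate_cross(100, [10], recomb_prob=0.5, seed=76)
        y = 5.0 + 20.0 * (g.alleles[:, 4] == LAB)
        scan = ag.linkage_scan(g, pheno(g, y))
        fdr = ag.permutation_fdr(g, pheno(g, y), n_perm=20, seed=77)
        peaks = ag.call_peaks(scan, fdr, fdr_ceiling=0.0)
        thr_ok = fdr.table[(fdr.table.fdr == 0.0)]
        if len(thr_ok) == 0:
            assert len(peaks) == 0
        else:
            assert len(peaks) >= 1
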