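"""Interval mapping: expected genotypes, scans, thresholds, intervals."""

import numpy as np
import pandas as pd
import pytest

from osteoqtl import qtl
from osteoqtl.containers import GenotypeMatrix
from osteoqtl.qtl import (
    QTLScanResult,
    composite_scan,
    expected_genotype,
    haldane_r,
    hk_scan,
    lod_support_interval,
    permutation_thresholds,
    ri_expansion,
    sex_by_genotype,
)
from osteoqtl.simulate import SimulationConfig, simulate_genotypes


def _single_marker_gm(codes, strains=None):
    strains = strains or [f"s{i}" for i in range(len(codes))]
    markers = pd.DataFrame(
        {"chrom": ["1"], "locus": ["m1"], "cM": [0.0], "Mb": [0.0]}
    )
    return GenotypeMatrix(strains, markers, np.array([[c] for c in codes]))


class TestExpectedGenotype:
    def test_observed_marker_code_returned(self):
        assert expected_genotype(0.0, (0.0, -1.0), (10.0, 1.0)) == pytest.approx(-1.0)

    def test_zero_length_interval_matches_flanks(self):
        assert expected_genotype(0.0, (0.0, -1.0), (0.0, -1.0)) == pytest.approx(-1.0)

    def test_midpoint_of_discordant_flanks_is_zero(self):
        assert expected_genotype(5.0, (0.0, -1.0), (10.0, 1.0)) == pytest.approx(0.0)

    def test_matches_two_state_chain_enumeration(self):
        # independent enumeration of the 2-state chain over both intervals
        for pos in (2.0, 3.7, 8.0):
            r1 = float(ri_expansion(haldane_r(pos)))
            r2 = float(ri_expansion(haldane_r(10.0 - pos)))
            # states +/-1 at the test point; flanks gl=-1, gr=+1
            num = {}
            for g in (-1.0, 1.0):
                t1 = (1 - r1) if g == -1.0 else r1
                t2 = (1 - r2) if g == 1.0 else r2
                num[g] = t1 * t2
            expect = sum(g * w for g, w in num.items()) / sum(num.values())
            got = expected_genotype(pos, (0.0, -1.0), (10.0, 1.0))
            assert got == pytest.approx(expect, abs=1e-12)

    def test_one_sided_conditioning_decays(self):
        near = expected_genotype(1.0, left=(0.0, 1.0))
        far = expected_genotype(50.0, left=(0.0, 1.0))
        assert 0 < far < near <= 1.0

    def test_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            expected_genotype(11.0, (0.0, -1.0), (10.0, 1.0))

    def test_no_information_is_nan(self):
        assert np.isnan(expected_genotype(5.0))


class TestHKScan:
    def test_worked_four_strain_instance(self):
        # codes {-1,-1,+1,+1}, trait {1,2,3,4}: RSS0=5, RSS1=1,
        # LRS = 4 ln 5, LOD = LRS / (2 ln 10), additive slope 1.0
        gm = _single_marker_gm("BBDD")
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=gm.strains)
        res = hk_scan(y, gm, step=None, min_strains=4)
        row = res.table.iloc[0]
        assert row["lrs"] == pytest.approx(4 * np.log(5))
        assert row["lod"] == pytest.approx(4 * np.log(5) / (2 * np.log(10)))
        assert row["additive"] == pytest.approx(1.0)

    def test_constant_trait_lrs_zero_everywhere(self, family_genotypes):
        y = pd.Series(3.14, index=family_genotypes.strains)
        res = hk_scan(y, family_genotypes, step=None)
        assert np.allclose(res.table["lrs"].dropna(), 0.0)

    def test_matches_direct_regression_at_markers(self, family_genotypes):
        # oracle: per-marker two-group OLS done independently with lstsq
        rng = np.random.default_rng(21)
        codes = family_genotypes.numeric()
        for _ in range(20):
            y = pd.Series(rng.normal(size=30), index=family_genotypes.strains)
            res = hk_scan(y, family_genotypes, step=None)
            for j in rng.choice(family_genotypes.n_markers, 5, replace=False):
                x = codes[:, j]
                ok = ~np.isnan(x)
                yy, xx = y.to_numpy()[ok], x[ok]
                X = np.column_stack([np.ones(ok.sum()), xx])
                beta, rss1, *_ = np.linalg.lstsq(X, yy, rcond=None)
                rss0 = float(np.sum((yy - yy.mean()) ** 2))
                lrs = ok.sum() * np.log(rss0 / float(rss1[0]))
                row = res.table.iloc[j]
                assert row["lrs"] == pytest.approx(lrs, rel=1e-9)
                assert row["additive"] == pytest.approx(beta[1], rel=1e-9)

    def test_lod_lrs_identity(self, family_genotypes):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=30), index=family_genotypes.strains)
        res = hk_scan(y, family_genotypes, step=1.0)
        tab = res.table.dropna(subset=["lrs"])
        assert np.allclose(tab["lod"] * 2 * np.log(10), tab["lrs"], atol=1e-9)

    def test_lrs_affine_invariant_additive_scales(self, family_genotypes):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=30), index=family_genotypes.strains)
        a = hk_scan(y, family_genotypes, step=None).table
        b = hk_scan(3.0 * y + 7.0, family_genotypes, step=None).table
        assert np.allclose(a["lrs"], b["lrs"], atol=1e-8)
        assert np.allclose(3.0 * a["additive"], b["additive"], atol=1e-8)

    def test_planted_qtl_recovered(self):
        cfg = SimulationConfig(seed=31, unknown_rate=0.0, qtl_spec=[(30, 1.0, "both")])
        gm = simulate_genotypes(cfg)
        rng = np.random.default_rng(1)
        code = gm.numeric()[:, 30]
        y = pd.Series(1.0 * code + rng.normal(0, 0.3, 60), index=gm.strains)
        res = hk_scan(y, gm, step=None)
        assert res.peak()["locus"] == gm.markers.loc[30, "locus"]


class TestPermutationThresholds:
    def test_constant_trait_thresholds_zero(self, family_genotypes):
        y = pd.Series(1.0, index=family_genotypes.strains)
        sug, sig = permutation_thresholds(y, family_genotypes, n_perm=100, seed=0, step=None)
        assert sug == 0.0 and sig == 0.0

    def test_seeded_reproducibility_and_ordering(self, family_genotypes):
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(size=30), index=family_genotypes.strains)
        a = permutation_thresholds(y, family_genotypes, n_perm=200, seed=5, step=None)
        b = permutation_thresholds(y, family_genotypes, n_perm=200, seed=5, step=None)
        assert a == b
        assert a[0] <= a[1]  # suggestive (37th pct) below significant (95th)

    def test_min_permutations_enforced(self, family_genotypes):
        y = pd.Series(np.arange(30.0), index=family_genotypes.strains)
        with pytest.raises(ValueError):
            permutation_thresholds(y, family_genotypes, n_perm=50, seed=0)


class TestSupportInterval:
    def _result(self, lods, mbs, chrom="1"):
        lrs = np.asarray(lods) * 2 * np.log(10)
        tab = pd.DataFrame(
            {
                "chrom": chrom,
                "locus": [f"m{i}" for i in range(len(lods))],
                "cM": np.arange(len(lods), dtype=float),
                "Mb": mbs,
                "lrs": lrs,
                "lod": lods,
                "additive": 0.0,
                "n": 10,
            }
        )
        return QTLScanResult(tab)

    def test_threshold_walk(self):
        # peak LOD 5, drop 1.5 -> threshold 3.5; 3.4 at 50 Mb is excluded
        res = self._result([1, 2, 5, 4, 3.4, 1], [10, 20, 30, 40, 50, 60])
        assert lod_support_interval(res, 1.5) == ("1", 30.0, 40.0)

    def test_single_position(self):
        res = self._result([2.0], [15.0])
        assert lod_support_interval(res) == ("1", 15.0, 15.0)

    def test_flat_profile_spans_chromosome(self):
        res = self._result([3.0, 3.0, 3.0], [5.0, 10.0, 15.0])
        assert lod_support_interval(res) == ("1", 5.0, 15.0)

    def test_contains_peak_and_widens_with_drop(self, family_genotypes):
        rng = np.random.default_rng(13)
        code = family_genotypes.numeric()[:, 10]
        y = pd.Series(code + rng.normal(0, 0.5, 30), index=family_genotypes.strains)
        res = hk_scan(y, family_genotypes, step=1.0)
        peak = res.peak()
        prev = None
        for drop in (0.5, 1.5, 3.0):
            chrom, lo, hi = lod_support_interval(res, drop)
            assert chrom == peak["chrom"] and lo <= peak["Mb"] <= hi
            if prev is not None:
                assert lo <= prev[0] and hi >= prev[1]
            prev = (lo, hi)


class TestCompositeScan:
    def test_empty_background_reduces_to_plain_scan(self, family_genotypes):
        rng = np.random.default_rng(17)
        y = pd.Series(rng.normal(size=30), index=family_genotypes.strains)
        plain = hk_scan(y, family_genotypes, step=None).table
        comp = composite_scan(y, family_genotypes, [], step=None).table
        pd.testing.assert_frame_equal(plain, comp)

    def test_conditioning_removes_planted_peak(self):
        cfg = SimulationConfig(seed=23, unknown_rate=0.0, qtl_spec=[(30, 1.0, "both")])
        gm = simulate_genotypes(cfg)
        rng = np.random.default_rng(3)
        y = pd.Series(gm.numeric()[:, 30] + rng.normal(0, 0.3, 60), index=gm.strains)
        plain = hk_scan(y, gm, step=None)
        marker = gm.markers.loc[30, "locus"]
        comp = composite_scan(y, gm, [marker], step=None)
        assert comp.max_lrs < 0.5 * plain.peak()["lrs"]
        # positions inside the exclusion window are masked
        near = comp.table[
            (comp.table["chrom"] == gm.markers.loc[30, "chrom"])
            & (np.abs(comp.table["cM"] - gm.markers.loc[30, "cM"]) <= 10.0)
        ]
        assert near["lrs"].isna().all()

    def test_unknown_background_marker_rejected(self, family_genotypes):
        y = pd.Series(np.arange(30.0), index=family_genotypes.strains)
        with pytest.raises(ValueError, match="background"):
            composite_scan(y, family_genotypes, ["nope"])


class TestSexByGenotype:
    def _means(self, gm, female, male):
        rows = []
        for i, s in enumerate(gm.strains):
            rows.append((s, "F", female[i]))
            rows.append((s, "M", male[i]))
        return pd.DataFrame(rows, columns=["strain", "sex", "value"])

    def test_identical_sex_profiles_no_interaction(self, family_genotypes):
        rng = np.random.default_rng(7)
        prof = rng.normal(size=30)
        df = self._means(family_genotypes, prof, prof)
        t = sex_by_genotype(df, family_genotypes, family_genotypes.markers.loc[0, "locus"])
        assert t.p_value > 0.99

    def test_female_restricted_effect_detected(self):
        cfg = SimulationConfig(seed=29, n_strains=60, unknown_rate=0.0)
        gm = simulate_genotypes(cfg)
        code = gm.numeric()[:, 30]
        rng = np.random.default_rng(1)
        f = 1.0 * code + rng.normal(0, 0.1, 60)
        m = rng.normal(0, 0.1, 60)
        t = sex_by_genotype(self._means(gm, f, m), gm, gm.markers.loc[30, "locus"])
        assert t.p_value < 0.01

    def test_single_sex_rejected(self, family_genotypes):
        df = pd.DataFrame(
            {"strain": family_genotypes.strains, "sex": "F", "value": np.arange(30.0)}
        )
        with pytest.raises(ValueError, match="both sexes"):
            sex_by_genotype(df, family_genotypes, family_genotypes.markers.loc[0, "locus"])
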