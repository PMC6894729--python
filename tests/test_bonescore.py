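"""Coexpression neighborhoods, hypergeometric enrichment, bone scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoqtl import bonescore
from osteoqtl.bonescore import (
    classify_ignorome,
    eigengenes,
    gene_scores,
    hypergeom_enrichment,
    reference_calibration,
    top_covariates,
)
from osteoqtl.containers import GeneSetCollection


def enumeration_tail(N, k, m, M):
    """Exhaustive oracle: fraction of N-subsets of M with >= k marked genes."""
    marked = set(range(m))
    hits = total = 0
    for draw in itertools.combinations(range(M), N):
        total += 1
        hits += len(marked & set(draw)) >= k
    return hits / total


class TestHypergeom:
    def test_zero_overlap_is_one(self):
        assert hypergeom_enrichment(5, 0, 3, 20) == 1.0

    def test_worked_example(self):
        # M=10, N=3, m=4, k=2: P(X>=2) = (36 + 4)/120 = 1/3
        assert hypergeom_enrichment(3, 2, 4, 10) == pytest.approx(1 / 3, abs=1e-12)

    def test_exhaustive_draw_forces_full_overlap(self):
        assert hypergeom_enrichment(10, 4, 4, 10) == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_small_universes(self):
        for M in (4, 7, 10):
            for N in range(M + 1):
                for m in range(M + 1):
                    for k in range(min(m, N) + 1):
                        got = hypergeom_enrichment(N, k, m, M)
                        want = enumeration_tail(N, k, m, M)
                        assert got == pytest.approx(want, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30))
    def test_monotone_nonincreasing_in_k(self, M, N, m):
        N, m = min(N, M), min(m, M)
        ps = [hypergeom_enrichment(N, k, m, M) for k in range(min(m, N) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(5, 6, 3, 10)


class TestTopCovariates:
    def test_duplicate_probe_ranks_first(self, small_expression):
        probes, genes = top_covariates("P1", small_expression, top_k=3)
        assert probes[0] == "P2"  # the planted near-duplicate
        assert "G2" in genes and "G1" not in genes  # seed probe excluded

    def test_topk_overflow_warns_and_returns_all(self, small_expression):
        with pytest.warns(UserWarning, match="top_k"):
            probes, _ = top_covariates("P1", small_expression, top_k=100)
        assert len(probes) == 7

    def test_constant_probe_rejected(self, small_expression):
        expr = small_expression
        expr.values.loc["P3"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            top_covariates("P3", expr)


class TestBoneScore:
    def test_arithmetic_identities(self):
        # average of -log10 p over terms: all p=1e-3 -> 3.0; half 1e-4,
        # half 1 -> average 2.0, max 4.0
        logp = {f"T{i}": 3.0 for i in range(34)}
        assert np.mean(list(logp.values())) == pytest.approx(3.0)
        logp = {f"T{i}": (4.0 if i < 17 else 0.0) for i in range(34)}
        vals = np.array(list(logp.values()))
        assert vals.mean() == pytest.approx(2.0)
        assert vals.max() == pytest.approx(4.0)

    def test_module_member_scores_higher_than_background(self):
        from osteoqtl.pipeline import default_gene_sets
        from osteoqtl.simulate import SimulationConfig, simulate_expression, simulate_genotypes

        cfg = SimulationConfig(seed=14, n_probes=120, module_loading=0.9)
        gm = simulate_genotypes(cfg)
        sets = default_gene_sets(2, 12)
        expr, _ = simulate_expression(gm, sets, cfg)
        table = bonescore.bone_score_table(expr, sets, top_k=20)
        g = gene_scores(table)
        inside = g.loc[g["gene"].isin(sets.all_genes), "average"]
        outside = g.loc[~g["gene"].isin(sets.all_genes), "average"]
        from scipy.stats import mannwhitneyu

        assert mannwhitneyu(inside, outside, alternative="greater").pvalue < 0.01

    def test_average_never_exceeds_max(self, small_expression, gene_sets):
        table = bonescore.bone_score_table(small_expression, gene_sets, top_k=4)
        assert (table["average"] <= table["maximum"] + 1e-12).all()
        assert (table["average"] >= 0).all()

    def test_invariant_under_joint_strain_permutation(self, small_expression, gene_sets):
        base = bonescore.bone_score_table(small_expression, gene_sets, top_k=4)
        perm = small_expression.values[list(small_expression.strains[::-1])]
        from osteoqtl.containers import ExpressionMatrix

        shuffled = ExpressionMatrix(perm, small_expression.probe_to_gene)
        again = bonescore.bone_score_table(shuffled, gene_sets, top_k=4)
        pd.testing.assert_frame_equal(base, again)


class TestReferenceCalibration:
    def test_single_reference_gene(self):
        scores = pd.DataFrame({"gene": ["A", "B"], "average": [2.0, 1.0], "maximum": [3.0, 2.0]})
        ref_mean, flagged = reference_calibration(["A"], scores)
        assert ref_mean == 2.0
        assert flagged.set_index("gene")["meets_reference"].to_dict() == {
            "A": True, "B": False,
        }

    def test_missing_reference_rejected(self):
        scores = pd.DataFrame({"gene": ["A"], "average": [2.0], "maximum": [2.0]})
        with pytest.raises(ValueError):
            reference_calibration(["ZZZ"], scores)


class TestEigengenes:
    def test_two_identical_genes_single_component(self, small_expression):
        comps, explained = eigengenes(["G1", "G2"], small_expression)
        assert explained[0] > 0.99

    def test_single_gene_matches_standardized_profile(self, small_expression):
        comps, _ = eigengenes(["G3"], small_expression, n_components=1)
        row = small_expression.values.loc["P3"].to_numpy()
        z = (row - row.mean()) / row.std()
        corr = np.corrcoef(comps[0], z)[0, 1]
        assert abs(corr) == pytest.approx(1.0)
        assert corr > 0  # oriented with the member-mean profile

    def test_recovers_planted_factor(self):
        from osteoqtl.pipeline import default_gene_sets
        from osteoqtl.simulate import SimulationConfig, simulate_expression, simulate_genotypes

        sets = default_gene_sets(1, 15)
        cfg = SimulationConfig(seed=17, n_probes=60, module_loading=0.9)
        gm = simulate_genotypes(cfg)
        expr, _ = simulate_expression(gm, sets, cfg)
        comps, explained = eigengenes(sets.all_genes, expr)
        member_mean = expr.values[expr.probe_to_gene.isin(sets.all_genes).to_numpy()].mean()
        assert abs(np.corrcoef(comps[0], member_mean)[0, 1]) > 0.9

    def test_fewer_genes_than_components_warns(self, small_expression):
        with pytest.warns(UserWarning, match="components"):
            comps, _ = eigengenes(["G1"], small_expression, n_components=3)
        assert comps.shape[0] == 1


class TestIgnorome:
    def test_threshold_and_known_exclusion(self):
        scores = pd.DataFrame(
            {"gene": ["a", "b", "c"], "average": [3.2, 3.2, 2.9], "maximum": [5, 5, 5]}
        )
        groups = classify_ignorome(scores, known_bone_genes={"b"}, threshold=3.0)
        assert groups["ignorome"] == {"a"}
        assert groups["known"] == {"b"}
        assert groups["other"] == {"c"}
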