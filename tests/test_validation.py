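import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cofitval.cofitness import corrected_cofitness_profile
from cofitval.data_io import AssociationMatrix
from cofitval.validation import (
    UntestableError,
    estimate_fdr,
    fisher_pvalue,
    rank_pvalue,
    significant_phenotype,
    validate_from_association,
    validate_tf,
)


class TestSignificantPhenotype:
    def test_one_qualifying_experiment_suffices(self):
        assert significant_phenotype([-0.6, 0.1], [-5, 1])

    def test_t_never_large_enough(self):
        assert not significant_phenotype([-0.6, 0.9], [-3.9, 3.9])

    def test_thresholds_are_strict(self):
        assert not significant_phenotype([0.5, 0.2], [10, 1])
        assert not significant_phenotype([0.9, 0.2], [4.0, 1])
        assert significant_phenotype([0.5000001, 0.2], [4.0001, 1])

    def test_missing_values_do_not_qualify(self):
        assert not significant_phenotype([np.nan, 0.9], [5.0, np.nan])


class TestRankPvalue:
    def test_boundary_at_18_targets_in_ecoli_sized_genome(self):
        # with N = 3789 genes with fitness data and a top rank of 1, the
        # test crosses 0.01 exactly between 18 and 19 targets
        assert rank_pvalue(1, 18, 3789) == pytest.approx(0.009482, abs=1e-6)
        assert rank_pvalue(1, 19, 3789) == pytest.approx(0.010008, abs=1e-6)
        assert rank_pvalue(1, 18, 3789) <= 0.01 < rank_pvalue(1, 19, 3789)

    def test_worst_rank_caps_at_one(self):
        assert rank_pvalue(3788, 5, 3789) == 1.0

    def test_no_targets_is_untestable(self):
        with pytest.raises(UntestableError):
            rank_pvalue(1, 0, 100)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(1, 98), st.integers(1, 30))
    def test_monotone_in_rank_and_targets(self, R, T):
        N = 100
        assert rank_pvalue(R, T, N) <= rank_pvalue(min(R + 1, N - 1), T, N) + 1e-12
        assert rank_pvalue(R, T, N) <= rank_pvalue(R, T + 1, N) + 1e-12

    def test_monte_carlo_top_rank_distribution(self):
        # closed form P(top <= R) = 1 - (1 - R/(N-1))^T for T draws with
        # replacement from 1..N-1
        rng = np.random.default_rng(12345)
        N, T, reps = 100, 5, 100_000
        tops = rng.integers(1, N, size=(reps, T)).min(axis=1)
        for R in (1, 3, 10):
            emp = float(np.mean(tops <= R))
            expected = -math.expm1(T * math.log1p(-R / (N - 1)))
            se = math.sqrt(expected * (1 - expected) / reps)
            assert abs(emp - expected) <= 3 * se


class TestFisherPvalue:
    def test_zero_correlation_is_uninformative(self):
        assert fisher_pvalue(0.0, 50, 1, "positive") == 1.0

    def test_hand_computed_example(self):
        # z = sqrt(100) * atanh(0.5) = 5.4931; 2 * sf(z) ~ 3.95e-8
        p = fisher_pvalue(0.5, 103, 1, "positive")
        assert p == pytest.approx(3.95e-8, rel=0.01)

    def test_sign_symmetry(self):
        assert fisher_pvalue(-0.5, 60, 3, "negative") == pytest.approx(
            fisher_pvalue(0.5, 60, 3, "positive")
        )

    def test_perfect_correlation_underflows_not_errors(self):
        p = fisher_pvalue(1.0, 50, 2, "positive")
        assert 0 < p < 1e-200

    def test_too_few_experiments_untestable(self):
        with pytest.raises(UntestableError):
            fisher_pvalue(0.5, 3, 1, "positive")

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.0, 0.95), st.integers(5, 300))
    def test_monotone_in_correlation_and_m(self, r, M):
        assert fisher_pvalue(r + 0.04, M, 2, "positive") <= fisher_pvalue(
            r, M, 2, "positive"
        ) + 1e-15
        assert fisher_pvalue(r, M + 10, 2, "positive") <= fisher_pvalue(
            r, M, 2, "positive"
        ) + (1e-15 if r > 0 else 1.0)


def _planted_table(sign: str, n_genes=800, n_exps=100, coupling=0.9, seed=0):
    from cofitval.synthetic import SimulationConfig, TfSpec, simulate_fitness, simulate_genome

    cfg = SimulationConfig(
        n_genes=n_genes, n_experiments=n_exps,
        tf_specs=(TfSpec(sign, 2, coupling),), make_sequence=False, seed=seed,
    )
    ann, _, _, truth = simulate_genome(cfg)
    return simulate_fitness(ann, truth, cfg), truth.tfs[0]


class TestValidateTf:
    @pytest.mark.parametrize("sign", ["activator", "repressor"])
    def test_planted_coupling_is_validated_with_correct_sign(self, sign):
        table, tf = _planted_table(sign, seed=5)
        prof = corrected_cofitness_profile(tf.tf_locus, table)
        res = validate_tf(tf.tf_locus, list(tf.targets), prof, table)
        assert res.validated
        assert res.sign == sign
        assert res.T == 2
        assert res.p_activator == max(res.p_fisher_act, res.p_rank_act)
        assert res.p_repressor == max(res.p_fisher_rep, res.p_rank_rep)

    def test_anticorrelated_targets_give_ambiguous_call(self, table_from_rows):
        rng = np.random.default_rng(8)
        v = rng.standard_normal(100)
        rows = {f"g{i}": rng.standard_normal(100) for i in range(600)}
        rows["tf"] = v + 0.1 * rng.standard_normal(100)
        rows["t_pos"] = v + 0.1 * rng.standard_normal(100)
        rows["t_neg"] = -v + 0.1 * rng.standard_normal(100)
        table = table_from_rows(rows)
        prof = corrected_cofitness_profile("tf", table)
        res = validate_tf("tf", ["t_pos", "t_neg"], prof, table)
        assert res.validated
        assert res.sign == "ambiguous"
        assert res.top_target_act == "t_pos"
        assert res.top_target_rep == "t_neg"

    def test_targets_without_data_are_dropped_with_warning(self, caplog):
        table, tf = _planted_table("activator", seed=6)
        prof = corrected_cofitness_profile(tf.tf_locus, table)
        res = validate_tf(
            tf.tf_locus, list(tf.targets) + ["ghost_gene"], prof, table
        )
        assert res.T == 2
        assert "ghost_gene" in res.dropped_targets

    def test_tf_itself_removed_from_targets(self):
        table, tf = _planted_table("activator", seed=7)
        prof = corrected_cofitness_profile(tf.tf_locus, table)
        res = validate_tf(tf.tf_locus, [tf.tf_locus] + list(tf.targets), prof, table)
        assert res.T == 2

    def test_no_usable_targets_is_untestable(self):
        table, tf = _planted_table("activator", seed=8)
        prof = corrected_cofitness_profile(tf.tf_locus, table)
        with pytest.raises(UntestableError):
            validate_tf(tf.tf_locus, ["ghost"], prof, table)


class TestAssociationMode:
    def test_reproduces_cofitness_path_on_complete_data(self, table_from_rows):
        rng = np.random.default_rng(9)
        rows = {f"g{i}": rng.standard_normal(60) for i in range(50)}
        v = rows["g0"]
        rows["g1"] = v + 0.3 * rng.standard_normal(60)
        table = table_from_rows(rows)
        prof = corrected_cofitness_profile("g0", table)
        res_cof = validate_tf("g0", ["g1", "g2"], prof, table, gate_phenotype=False)

        ids = table.gene_ids
        corr = np.corrcoef(table.fitness.to_numpy())
        assoc = AssociationMatrix(pd.DataFrame(corr, index=ids, columns=ids))
        res_as = validate_from_association("g0", ["g1", "g2"], assoc, M=60)
        assert res_as.p_rank_act == pytest.approx(res_cof.p_rank_act)
        assert res_as.p_fisher_act == pytest.approx(res_cof.p_fisher_act, rel=1e-6)
        assert res_as.R == res_cof.R

    def test_planted_coexpressed_target_validates(self):
        rng = np.random.default_rng(10)
        n = 500
        corr = np.eye(n)
        noise = rng.uniform(-0.15, 0.15, size=(n, n))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        corr = corr + noise
        np.fill_diagonal(corr, 1.0)
        corr[0, 1] = corr[1, 0] = 0.8
        ids = [f"g{i}" for i in range(n)]
        assoc = AssociationMatrix(pd.DataFrame(corr, index=ids, columns=ids))
        res = validate_from_association("g0", ["g1"], assoc, M=200)
        assert res.validated
        assert res.sign == "activator"

    def test_null_associations_do_not_validate(self):
        n = 300
        ids = [f"g{i}" for i in range(n)]
        assoc = AssociationMatrix(pd.DataFrame(np.eye(n), index=ids, columns=ids))
        res = validate_from_association("g0", ["g5", "g6"], assoc, M=100)
        assert not res.validated
        assert res.p_activator == 1.0


class TestFdr:
    @pytest.mark.parametrize(
        "alpha,tested,validated,expected",
        [(0.01, 479, 158, 0.030), (0.01, 89, 17, 0.052), (0.01, 50, 5, 0.100),
         (0.01, 100, 100, 0.01)],
    )
    def test_plugin_estimates(self, alpha, tested, validated, expected):
        assert estimate_fdr(alpha, tested, validated) == pytest.approx(expected, abs=5e-4)

    def test_zero_validated_undefined(self):
        with pytest.raises(ValueError):
            estimate_fdr(0.01, 10, 0)
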